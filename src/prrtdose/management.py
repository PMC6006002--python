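"""Cumulative-dose tracking and the treatment-withholding rule.

After each treatment cycle the expected cumulative dose after one further
cycle is formed for every risk organ as the cumulative dose plus the mean
dose of the completed cycles (cumulative * (p+1)/p over p cycles).  Therapy
is withheld when that expectation strictly exceeds the safety limit plus a
10% margin: 23 Gy -> 25.3 Gy for the kidneys, 2 Gy -> 2.2 Gy for the bone
marrow.  Other organs receive doses but do not influence management.

The module also models the CT-acquisition schedule of the two imaging
protocols: the classical protocol acquires a CT with every SPECT (three
scans after the first cycle, one per later cycle), while the single-CT
protocol registers the first CT to every subsequent SPECT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError, InputError, InsufficientDataError
from .dose_engine import (DoseFactorTable, ResidenceTimeSet,
                          organ_dose, marrow_dose, tumor_dose)
from .kinetics import (TimedSample, MonoExpFit, fit_monoexp, rescale_to_cycle,
                       residence_time)

__all__ = [
    "DEFAULT_LIMITS_GY",
    "DEFAULT_MARGIN",
    "CycleRecord",
    "ManagementConfig",
    "Decision",
    "PatientCourse",
    "expected_after_next",
    "decide",
    "ct_count",
    "ct_reduction",
    "run_course",
    "course_report_json",
    "course_summary_frame",
]

#: Safety limits, Gy, for the dose-limiting organs.
DEFAULT_LIMITS_GY = {"kidneys": 23.0, "bone_marrow": 2.0}
#: Margin on the limits tolerated before withholding further cycles.
DEFAULT_MARGIN = 0.10


@dataclass(frozen=True)
class CycleRecord:
    """Doses delivered in one cycle: mapping organ -> total dose, mGy."""

    cycle: int
    a_adm: float
    dose_mGy: dict[str, float]

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise DomainError(f"cycle must be >= 1, got {self.cycle}")
        if any(v < 0 for v in self.dose_mGy.values()):
            raise DomainError("cycle doses must be >= 0")


@dataclass
class ManagementConfig:
    """Withholding rule parameters.

    ``limit_Gy`` maps each decision organ to its safety limit; ``margin`` is
    the tolerated fractional excess.  The effective withholding threshold per
    organ is limit * (1 + margin).  ``allow_override`` exposes the clinical
    escape hatch for specific setups; it is never applied automatically.
    """

    limit_Gy: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS_GY))
    margin: float = DEFAULT_MARGIN
    allow_override: bool = False

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.limit_Gy.values()):
            raise DomainError("safety limits must be > 0")
        if self.margin < 0:
            raise DomainError("margin must be >= 0")

    def threshold_Gy(self, organ: str) -> float:
        return self.limit_Gy[organ] * (1.0 + self.margin)


@dataclass(frozen=True)
class Decision:
    """Outcome of one continue/withhold evaluation."""

    action: str  # "continue" | "withhold"
    triggering_organs: tuple[str, ...] = ()
    expected_Gy: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientCourse:
    """Completed course: per-cycle records plus the decision after each."""

    patient_id: str
    sex: str
    cycles: list[CycleRecord] = field(default_factory=list)
    decisions: list[Decision] = field(default_factory=list)

    def cumulative_mGy(self, organ: str) -> float:
        return sum(rec.dose_mGy.get(organ, 0.0) for rec in self.cycles)

    @property
    def final_decision(self) -> str:
        return self.decisions[-1].action if self.decisions else "continue"


def expected_after_next(cycle_doses: list[float]) -> float:
    """Expected cumulative dose after one further cycle, same unit as input.

    Over p completed cycles: cumulative + mean = cumulative * (p+1)/p.
    """
    if not cycle_doses:
        raise InsufficientDataError("need >= 1 completed cycle")
    p = len(cycle_doses)
    return sum(cycle_doses) * (p + 1) / p


def decide(expected_Gy: dict[str, float], config: ManagementConfig) -> Decision:
    """Apply the withholding rule to expected cumulative doses (Gy).

    Withhold iff the expectation strictly exceeds limit*(1+margin) for any
    configured organ ("will exceed"); boundary equality continues.
    """
    missing = set(config.limit_Gy) - set(expected_Gy)
    if missing:
        raise InputError(f"expected doses missing for organs {sorted(missing)}")
    triggering = tuple(
        organ for organ in config.limit_Gy
        if expected_Gy[organ] > config.threshold_Gy(organ))
    action = "withhold" if triggering else "continue"
    return Decision(action=action, triggering_organs=triggering,
                    expected_Gy={k: expected_Gy[k] for k in config.limit_Gy})


def ct_count(protocol: str, n_cycles: int) -> int:
    """CT acquisitions over a course: classical 3+(n-1), single-CT always 1."""
    if n_cycles < 1:
        raise DomainError(f"n_cycles must be >= 1, got {n_cycles}")
    if protocol == "classical":
        return 3 + (n_cycles - 1)
    if protocol == "single_ct":
        return 1
    raise DomainError(f"unknown protocol {protocol!r}")


def ct_reduction(n_cycles: int) -> float:
    """Fraction of CT acquisitions saved by the single-CT protocol."""
    return 1.0 - ct_count("single_ct", n_cycles) / ct_count("classical", n_cycles)


def _fits_for_cycle(samples: list[TimedSample],
                    reference: dict[str, MonoExpFit] | None,
                    ) -> dict[str, MonoExpFit]:
    by_organ: dict[str, list[TimedSample]] = {}
    for s in samples:
        by_organ.setdefault(s.organ, []).append(s)
    fits: dict[str, MonoExpFit] = {}
    for organ, organ_samples in by_organ.items():
        if reference is None:
            fits[organ] = fit_monoexp(organ_samples)
        else:
            if organ not in reference:
                raise InputError(
                    f"no cycle-1 fit to propagate for organ {organ!r}")
            # later cycles carry a single time point; re-anchor the cycle-1 curve
            anchor = organ_samples[0]
            fits[organ] = rescale_to_cycle(reference[organ], anchor)
    return fits


def run_course(samples_by_cycle: dict[int, list[TimedSample]],
               voi_mass_by_cycle: dict[int, dict[str, float]],
               a_adm_by_cycle: dict[int, float],
               table: DoseFactorTable,
               config: ManagementConfig | None = None,
               *, patient_id: str = "patient", sex: str | None = None,
               ) -> PatientCourse:
    """Run the full per-cycle dosimetry pipeline for one patient.

    Cycle 1 measurements are fitted per organ (>= 2 time points); later
    cycles re-anchor the cycle-1 curves on their single sample assuming an
    unchanged effective half-life.  Doses to all table targets are computed
    each cycle, and the withholding rule is evaluated after every cycle;
    processing stops at the first withhold.
    """
    config = config or ManagementConfig()
    sex = sex or table.phantom_sex
    course = PatientCourse(patient_id=patient_id, sex=sex)
    cycle_numbers = sorted(samples_by_cycle)
    if not cycle_numbers or cycle_numbers[0] != 1:
        raise InputError("course must start at cycle 1")
    reference_fits: dict[str, MonoExpFit] | None = None
    for cyc in cycle_numbers:
        a_adm = a_adm_by_cycle[cyc]
        fits = _fits_for_cycle(samples_by_cycle[cyc],
                               None if cyc == 1 else reference_fits)
        if cyc == 1:
            reference_fits = fits
        rts = ResidenceTimeSet(
            residence_times={organ: residence_time(fit, a_adm, cycle=cyc)
                             for organ, fit in fits.items()},
            voi_mass_kg=voi_mass_by_cycle.get(cyc, {}),
            cycle=cyc)
        doses: dict[str, float] = {}
        for target in rts.residence_times:
            if target == "blood":
                continue
            if target == "tumor":
                doses["tumor"] = tumor_dose(
                    a_adm, rts.residence_times["tumor"], table)
            elif table.get(target, target) is not None:
                doses[target] = organ_dose(a_adm, target, rts, table).total_mGy
        if "blood" in rts.residence_times:
            doses["bone_marrow"] = marrow_dose(
                a_adm, rts.residence_times["blood"], rts, table).total_mGy
        course.cycles.append(CycleRecord(cycle=cyc, a_adm=a_adm, dose_mGy=doses))
        expected = {
            organ: expected_after_next(
                [rec.dose_mGy.get(organ, 0.0) for rec in course.cycles]) / 1000.0
            for organ in config.limit_Gy}
        decision = decide(expected, config)
        course.decisions.append(decision)
        if decision.action == "withhold":
            break
    return course


# ---------------------------------------------------------------------------
# Course reports
# ---------------------------------------------------------------------------

def course_report_json(course: PatientCourse, path: str | Path | None = None,
                       ) -> dict:
    """Nested JSON report: per-cycle doses, cumulative, expected, decision."""
    organs = sorted({o for rec in course.cycles for o in rec.dose_mGy})
    report = {
        "patient_id": course.patient_id,
        "sex": course.sex,
        "n_cycles": len(course.cycles),
        "final_decision": course.final_decision,
        "cycles": [],
    }
    running: dict[str, float] = {o: 0.0 for o in organs}
    for rec, dec in zip(course.cycles, course.decisions):
        for o in organs:
            running[o] += rec.dose_mGy.get(o, 0.0)
        report["cycles"].append({
            "cycle": rec.cycle,
            "a_adm_MBq": rec.a_adm,
            "dose_mGy": dict(rec.dose_mGy),
            "cumulative_mGy": dict(running),
            "expected_Gy": dict(dec.expected_Gy),
            "decision": dec.action,
            "triggering_organs": list(dec.triggering_organs),
        })
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report


def course_summary_frame(course: PatientCourse) -> pd.DataFrame:
    """Flat one-row-per-cycle summary (doses in both mGy and Gy)."""
    rows = []
    for rec, dec in zip(course.cycles, course.decisions):
        row = {"patient_id": course.patient_id, "cycle": rec.cycle,
               "a_adm_MBq": rec.a_adm, "decision": dec.action}
        for organ, mgy in sorted(rec.dose_mGy.items()):
            row[f"{organ}_mGy"] = mgy
            row[f"{organ}_Gy"] = mgy / 1000.0
        rows.append(row)
    return pd.DataFrame(rows)
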