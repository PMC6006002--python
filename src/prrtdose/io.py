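"""File formats: measurement CSVs, VOI-mass CSVs, cohort export.

CSV carries flat tabular exchange data; JSON carries nested reports and the
dose-factor table (see :mod:`prrtdose.dose_engine`).  All files are UTF-8
with a mandatory header; validation errors name the offending row/column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError
from .kinetics import ORGAN_LABELS, TimedSample
from .synthetic import TruePatient, simulate_course_samples

__all__ = [
    "SAMPLE_COLUMNS",
    "PatientSamples",
    "read_samples",
    "write_samples",
    "read_voi_masses",
    "write_voi_masses",
    "export_cohort",
]

SAMPLE_COLUMNS = ("patient_id", "sex", "cycle", "organ", "time_h",
                  "conc_MBq_per_kg", "source")
VOI_COLUMNS = ("patient_id", "cycle", "organ", "mass_kg")


@dataclass
class PatientSamples:
    """All measurements of one patient, grouped per cycle."""

    patient_id: str
    sex: str
    samples_by_cycle: dict[int, list[TimedSample]] = field(default_factory=dict)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...],
                     path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_samples(path: str | Path) -> dict[str, PatientSamples]:
    """Read a measurement CSV into per-patient, per-cycle sample sets.

    Row numbers in error messages are 1-based data rows (header excluded).
    Rejects unknown organ labels, non-positive times, negative
    concentrations and duplicate (patient, cycle, organ, time) keys.
    """
    df = pd.read_csv(path)
    _require_columns(df, SAMPLE_COLUMNS, path)
    patients: dict[str, PatientSamples] = {}
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        organ = str(row.organ)
        if organ not in ORGAN_LABELS:
            raise ParseError(f"{path}: row {i}: unknown organ {organ!r}")
        if row.conc_MBq_per_kg < 0:
            raise ParseError(
                f"{path}: row {i}: negative concentration "
                f"{row.conc_MBq_per_kg}")
        if row.time_h <= 0:
            raise ParseError(f"{path}: row {i}: time_h must be > 0")
        key = (row.patient_id, int(row.cycle), organ, float(row.time_h))
        if key in seen:
            raise ParseError(
                f"{path}: row {i}: duplicate (patient, cycle, organ, time) "
                f"{key}")
        seen.add(key)
        try:
            sample = TimedSample(organ=organ, time_h=float(row.time_h),
                                 conc=float(row.conc_MBq_per_kg),
                                 cycle=int(row.cycle), source=str(row.source))
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
        pid = str(row.patient_id)
        patient = patients.setdefault(
            pid, PatientSamples(patient_id=pid, sex=str(row.sex)))
        patient.samples_by_cycle.setdefault(int(row.cycle), []).append(sample)
    return patients


def write_samples(patients: dict[str, PatientSamples], path: str | Path) -> None:
    """Write per-patient samples back to the measurement CSV format."""
    rows = []
    for patient in patients.values():
        for cycle in sorted(patient.samples_by_cycle):
            for s in patient.samples_by_cycle[cycle]:
                rows.append({"patient_id": patient.patient_id,
                             "sex": patient.sex, "cycle": cycle,
                             "organ": s.organ, "time_h": s.time_h,
                             "conc_MBq_per_kg": s.conc, "source": s.source})
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(path, index=False)


def read_voi_masses(path: str | Path) -> dict[str, dict[int, dict[str, float]]]:
    """Read VOI masses: patient_id -> cycle -> organ -> mass (kg)."""
    df = pd.read_csv(path)
    _require_columns(df, VOI_COLUMNS, path)
    out: dict[str, dict[int, dict[str, float]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.mass_kg <= 0:
            raise ParseError(f"{path}: row {i}: mass_kg must be > 0")
        out.setdefault(str(row.patient_id), {}).setdefault(
            int(row.cycle), {})[str(row.organ)] = float(row.mass_kg)
    return out


def write_voi_masses(masses: dict[str, dict[int, dict[str, float]]],
                     path: str | Path) -> None:
    rows = [{"patient_id": pid, "cycle": cyc, "organ": organ, "mass_kg": m}
            for pid, by_cycle in masses.items()
            for cyc, by_organ in sorted(by_cycle.items())
            for organ, m in sorted(by_organ.items())]
    pd.DataFrame(rows, columns=list(VOI_COLUMNS)).to_csv(path, index=False)


def export_cohort(cohort: list[TruePatient], out_dir: str | Path, *,
                  protocol: str = "classical", seed: int = 0,
                  noise_sd: float = 0.05, blood_noise_sd: float = 0.01,
                  perturbation_sd: float = 0.06,
                  ) -> dict[str, Path]:
    """Simulate and write a cohort as the CSVs the pipeline consumes.

    Emits ``samples.csv`` and ``voi_masses.csv`` in the pipeline's input
    formats plus ``truth.json`` holding the generating parameters for
    oracle comparisons.  Per-patient simulation seeds are ``seed + index``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients: dict[str, PatientSamples] = {}
    masses: dict[str, dict[int, dict[str, float]]] = {}
    truth = []
    for idx, patient in enumerate(cohort):
        samples = simulate_course_samples(
            patient, protocol, seed + idx,
            noise_sd=noise_sd, blood_noise_sd=blood_noise_sd,
            perturbation_sd=perturbation_sd)
        patients[patient.patient_id] = PatientSamples(
            patient_id=patient.patient_id, sex=patient.sex,
            samples_by_cycle=samples)
        masses[patient.patient_id] = {
            cyc: dict(patient.voi_mass_kg)
            for cyc in range(1, patient.n_cycles + 1)}
        truth.append({
            "patient_id": patient.patient_id, "sex": patient.sex,
            "a_adm_MBq": patient.a_adm_MBq,
            "voi_mass_kg": patient.voi_mass_kg,
            "kinetics": {o: {"c0": k.c0, "lambda_eff": k.lambda_eff}
                         for o, k in patient.kinetics.items()},
        })
    paths = {"samples": out_dir / "samples.csv",
             "voi_masses": out_dir / "voi_masses.csv",
             "truth": out_dir / "truth.json"}
    write_samples(patients, paths["samples"])
    write_voi_masses(masses, paths["voi_masses"])
    paths["truth"].write_text(json.dumps(
        {"protocol": protocol, "seed": seed, "noise_sd": noise_sd,
         "perturbation_sd": perturbation_sd, "patients": truth}, indent=2))
    return paths
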