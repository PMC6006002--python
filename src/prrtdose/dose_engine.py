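"""MIRD-formalism absorbed-dose engine.

Absorbed dose to a target region r_t is

    D(r_t) = A_adm * [ t_rt * DF(r_t <- r_t) + sum_s t_rs * DF(r_t <- r_s) ],

with A_adm the administered activity (MBq), t_r concentration residence
times in (MBq*s)/(MBq*kg), and DF dose factors tabulated on a reference
anthropomorphic phantom.  Two factor kinds close the units:

* ``organ_level`` factors, mGy/(MBq*s), pair with a source *mass*: the
  concentration residence time of the source is multiplied by its VOI mass
  (time-integrated activity), except in the self term where mass rescaling of
  the self S-value by phantom/VOI mass cancels the VOI mass and leaves the
  phantom organ mass (density 1.0 g/cm^3 assumed for VOIs).
* ``concentration`` factors, mGy*kg/(MBq*s), multiply a concentration
  residence time directly (blood-borne marrow self-dose, remainder of body,
  tumor DCF).

Special cases mirror clinical practice for [177Lu]-DOTA-TATE: bone-marrow
kinetics are taken from blood (marrow concentration equals blood
concentration); the remainder->marrow cross factor is replaced by
30.3 nGy*kg/(MBq*s) (male) / 35.8 (female) because the phantom value
overestimates it when there is no skeletal uptake; tumor self-dose uses a
dose concentration factor DCF_tumor = 0.0236 mGy*g/(MBq*s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigurationError, DomainError, InputError
from .kinetics import ResidenceTime

__all__ = [
    "TARGET_ORGANS",
    "DCF_TUMOR_DEFAULT",
    "DF_REMAINDER_TO_MARROW",
    "MBQ_PER_MCI",
    "mbq_to_mci",
    "DoseFactor",
    "DoseFactorTable",
    "ResidenceTimeSet",
    "OrganDoseResult",
    "organ_dose",
    "marrow_dose",
    "tumor_dose",
    "load_dose_factor_table",
    "save_dose_factor_table",
    "synthetic_dose_factor_table",
]

log = logging.getLogger(__name__)

#: Organs the engine can target (sampled organs plus the blood-derived marrow).
TARGET_ORGANS = ("kidneys", "liver", "spleen", "remainder", "tumor",
                 "bone_marrow")
_SOURCE_ORGANS = ("kidneys", "liver", "spleen", "remainder", "tumor", "blood",
                  "bone_marrow")
#: Sources whose factors are concentration-kind and hence need no VOI mass.
_CONCENTRATION_SOURCES = frozenset({"blood", "remainder"})

#: Tumor self-dose concentration factor, mGy*g/(MBq*s).
DCF_TUMOR_DEFAULT = 0.0236
#: Replacement remainder-of-body -> bone-marrow dose factors, mGy*kg/(MBq*s)
#: (30.3 and 35.8 nGy*kg/(MBq*s)).
DF_REMAINDER_TO_MARROW = {"male": 3.03e-5, "female": 3.58e-5}

#: 1 mCi = 37 MBq exactly.
MBQ_PER_MCI = 37.0


def mbq_to_mci(activity_mbq: float) -> float:
    """Convert an activity from MBq to mCi (1 mCi = 37 MBq)."""
    return activity_mbq / MBQ_PER_MCI


@dataclass(frozen=True)
class DoseFactor:
    """One source->target dose factor entry."""

    source: str
    target: str
    value: float
    kind: str  # "organ_level" [mGy/(MBq*s)] or "concentration" [mGy*kg/(MBq*s)]

    def __post_init__(self) -> None:
        if self.source not in _SOURCE_ORGANS:
            raise ConfigurationError(f"unknown source organ {self.source!r}")
        if self.target not in TARGET_ORGANS:
            raise ConfigurationError(f"unknown target organ {self.target!r}")
        if self.kind not in ("organ_level", "concentration"):
            raise ConfigurationError(f"unknown factor kind {self.kind!r}")
        if self.value < 0:
            raise ConfigurationError(f"dose factor must be >= 0, got {self.value}")


@dataclass
class DoseFactorTable:
    """Dose factors and phantom organ masses for one phantom sex.

    ``phantom_mass_g`` maps organ -> reference phantom mass in grams.
    ``factors`` hold source->target entries; (source, target) pairs are
    unique.  ``dcf_tumor`` and ``df_remainder_to_marrow`` carry the two
    special-case concentration factors.
    """

    phantom_sex: str
    phantom_mass_g: dict[str, float]
    factors: list[DoseFactor]
    dcf_tumor: float = DCF_TUMOR_DEFAULT
    df_remainder_to_marrow: float | None = None
    _index: dict[tuple[str, str], DoseFactor] = field(
        default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.phantom_sex not in ("male", "female"):
            raise ConfigurationError(
                f"phantom_sex must be 'male' or 'female', got {self.phantom_sex!r}")
        for organ, mass in self.phantom_mass_g.items():
            if organ not in TARGET_ORGANS:
                raise ConfigurationError(f"unknown organ in phantom masses: {organ!r}")
            if mass <= 0:
                raise ConfigurationError(f"phantom mass for {organ} must be > 0")
        if self.df_remainder_to_marrow is None:
            self.df_remainder_to_marrow = DF_REMAINDER_TO_MARROW[self.phantom_sex]
        index: dict[tuple[str, str], DoseFactor] = {}
        for f in self.factors:
            key = (f.source, f.target)
            if key in index:
                raise ConfigurationError(f"duplicate dose factor for {key}")
            index[key] = f
        self._index = index

    def get(self, source: str, target: str) -> DoseFactor | None:
        return self._index.get((source, target))

    def phantom_mass_kg(self, organ: str) -> float:
        try:
            return self.phantom_mass_g[organ] / 1000.0
        except KeyError:
            raise ConfigurationError(f"no phantom mass for organ {organ!r}") from None


@dataclass
class ResidenceTimeSet:
    """Residence times and VOI masses for one cycle.

    Every organ that acts as an organ-level source must have a VOI mass
    (tissue density 1.0 g/cm^3); blood and remainder use concentration-kind
    factors and need none.
    """

    residence_times: dict[str, ResidenceTime]
    voi_mass_kg: dict[str, float] = field(default_factory=dict)
    cycle: int = 1

    def __post_init__(self) -> None:
        for organ, mass in self.voi_mass_kg.items():
            if mass <= 0:
                raise DomainError(f"VOI mass for {organ} must be > 0, got {mass}")

    def value(self, organ: str) -> float:
        return self.residence_times[organ].value

    def voi_mass(self, organ: str) -> float:
        try:
            return self.voi_mass_kg[organ]
        except KeyError:
            raise ConfigurationError(
                f"organ-level source {organ!r} has no VOI mass") from None


@dataclass(frozen=True)
class OrganDoseResult:
    """Self + cross dose breakdown for one target organ, mGy."""

    target: str
    self_dose_mGy: float
    cross_dose_mGy: dict[str, float]
    total_mGy: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total_mGy",
            self.self_dose_mGy + sum(self.cross_dose_mGy.values()))


def _cross_terms(a_adm: float, target: str, rts: ResidenceTimeSet,
                 table: DoseFactorTable,
                 skip_sources: frozenset[str]) -> dict[str, float]:
    cross: dict[str, float] = {}
    for source in rts.residence_times:
        if source == target or source in skip_sources:
            continue
        factor = table.get(source, target)
        if factor is None:
            log.warning("no dose factor for %s -> %s; contribution set to 0",
                        source, target)
            continue
        t_r = rts.value(source)
        if factor.kind == "organ_level":
            cross[source] = a_adm * t_r * rts.voi_mass(source) * factor.value
        else:
            cross[source] = a_adm * t_r * factor.value
    return cross


def organ_dose(a_adm: float, target: str, rts: ResidenceTimeSet,
               table: DoseFactorTable) -> OrganDoseResult:
    """Absorbed dose to a solid organ with self- and cross-dose terms.

    The self term for an organ-level self factor is
    ``A_adm * t_r(target) * DF_self * m_phantom(target)``: rescaling the self
    S-value by m_phantom/m_voi while the time-integrated activity carries
    m_voi cancels the VOI mass, so the self-dose depends on the delineated
    volume only through the measured concentration.
    """
    if a_adm <= 0:
        raise DomainError(f"administered activity must be > 0, got {a_adm}")
    if target not in rts.residence_times:
        raise InputError(f"no residence time for target organ {target!r}")
    self_factor = table.get(target, target)
    if self_factor is None:
        raise ConfigurationError(f"table has no self factor for {target!r}")
    t_r = rts.value(target)
    if self_factor.kind == "organ_level":
        self_dose = a_adm * t_r * self_factor.value * table.phantom_mass_kg(target)
    else:
        self_dose = a_adm * t_r * self_factor.value
    cross = _cross_terms(a_adm, target, rts, table, frozenset({"blood"}))
    return OrganDoseResult(target=target, self_dose_mGy=self_dose,
                           cross_dose_mGy=cross)


def marrow_dose(a_adm: float, blood_rt: ResidenceTime, rts: ResidenceTimeSet,
                table: DoseFactorTable) -> OrganDoseResult:
    """Absorbed dose to the bone marrow.

    The self term assumes marrow activity concentration equals the blood
    concentration: ``A_adm * t_r(blood) * DF_marrow_self`` with a
    concentration-kind self factor.  The remainder-of-body contribution uses
    the sex-specific replacement factor; other organs contribute cross terms
    as in :func:`organ_dose`.
    """
    if a_adm <= 0:
        raise DomainError(f"administered activity must be > 0, got {a_adm}")
    if blood_rt is None:
        raise InputError("marrow dose requires the blood residence time")
    self_factor = table.get("bone_marrow", "bone_marrow")
    if self_factor is None or self_factor.kind != "concentration":
        raise ConfigurationError(
            "table needs a concentration-kind bone_marrow self factor")
    self_dose = a_adm * blood_rt.value * self_factor.value
    cross = _cross_terms(a_adm, "bone_marrow", rts, table,
                         frozenset({"blood", "remainder"}))
    if "remainder" in rts.residence_times:
        cross["remainder"] = (a_adm * rts.value("remainder")
                              * table.df_remainder_to_marrow)
    return OrganDoseResult(target="bone_marrow", self_dose_mGy=self_dose,
                           cross_dose_mGy=cross)


def tumor_dose(a_adm: float, tumor_rt: ResidenceTime,
               table: DoseFactorTable) -> float:
    """Tumor self-dose, mGy: A_adm * t_r(tumor) * DCF_tumor / 1000.

    The dose concentration factor is tabulated in mGy*g/(MBq*s); dividing by
    1000 converts grams to kilograms so the product with the (MBq*s)/(MBq*kg)
    residence time lands in mGy.  Cross-dose from other organs to the tumor
    is not modelled (self-dose dominates in high-uptake lesions).
    """
    if a_adm <= 0:
        raise DomainError(f"administered activity must be > 0, got {a_adm}")
    if tumor_rt.value < 0:
        raise DomainError("tumor residence time must be >= 0")
    return a_adm * tumor_rt.value * table.dcf_tumor * 1e-3


# ---------------------------------------------------------------------------
# Table I/O (JSON) and the synthetic fixture table
# ---------------------------------------------------------------------------

def save_dose_factor_table(table: DoseFactorTable, path: str | Path) -> None:
    """Write a dose-factor table as JSON."""
    payload = {
        "phantom_sex": table.phantom_sex,
        "phantom_mass_g": table.phantom_mass_g,
        "dcf_tumor": table.dcf_tumor,
        "df_remainder_to_marrow": table.df_remainder_to_marrow,
        "factors": [
            {**asdict(f),
             "units": ("mGy/(MBq*s)" if f.kind == "organ_level"
                       else "mGy*kg/(MBq*s)")}
            for f in table.factors
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_dose_factor_table(path: str | Path) -> DoseFactorTable:
    """Load and validate a dose-factor table from JSON.

    Unknown top-level keys, unknown organs, duplicate (source, target) pairs
    and malformed entries are rejected.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc
    allowed = {"phantom_sex", "phantom_mass_g", "dcf_tumor",
               "df_remainder_to_marrow", "factors"}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("phantom_sex", "phantom_mass_g", "factors"):
        if key not in payload:
            raise ConfigurationError(f"{path}: missing key {key!r}")
    factors = []
    for i, entry in enumerate(payload["factors"]):
        try:
            factors.append(DoseFactor(source=entry["source"],
                                      target=entry["target"],
                                      value=float(entry["value"]),
                                      kind=entry["kind"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: factors[{i}]: {exc}") from exc
    return DoseFactorTable(
        phantom_sex=payload["phantom_sex"],
        phantom_mass_g={k: float(v) for k, v in payload["phantom_mass_g"].items()},
        factors=factors,
        dcf_tumor=float(payload.get("dcf_tumor", DCF_TUMOR_DEFAULT)),
        df_remainder_to_marrow=payload.get("df_remainder_to_marrow"),
    )


def synthetic_dose_factor_table(sex: str = "male") -> DoseFactorTable:
    """A synthetic dose-factor table with plausible 177Lu magnitudes.

    These are NOT reference phantom values: self S-values and cross factors
    are invented fixtures with realistic orders of magnitude for a beta/gamma
    emitter (self-dose dominated by the ~0.15 MeV mean beta, cross-dose two
    to three orders smaller, via the 208 keV gamma).  The tumor source reuses
    the liver factors (lesions predominantly hepatic), scaled by the tumor
    VOI mass at dose time.  Phantom masses follow adult reference anatomy.
    """
    if sex not in ("male", "female"):
        raise ConfigurationError(f"sex must be 'male' or 'female', got {sex!r}")
    masses = {
        "male": {"kidneys": 299.0, "liver": 1910.0, "spleen": 183.0},
        "female": {"kidneys": 275.0, "liver": 1400.0, "spleen": 150.0},
    }[sex]
    # organ_level self S-values, mGy/(MBq*s); concentration factors otherwise
    scale = 1.0 if sex == "male" else 1.15  # smaller phantom -> larger S
    f = []
    self_s = {"kidneys": 2.1e-4, "liver": 3.3e-5, "spleen": 3.4e-4}
    for organ, s in self_s.items():
        f.append(DoseFactor(organ, organ, s * scale, "organ_level"))
    cross_pairs = {
        ("liver", "kidneys"): 2.5e-7,
        ("spleen", "kidneys"): 4.0e-7,
        ("tumor", "kidneys"): 2.5e-7,      # liver factors stand in for tumors
        ("kidneys", "liver"): 2.5e-7,
        ("spleen", "liver"): 6.0e-8,
        ("tumor", "liver"): 1.1e-6,
        ("kidneys", "spleen"): 4.0e-7,
        ("liver", "spleen"): 6.0e-8,
        ("tumor", "spleen"): 6.0e-8,
        ("kidneys", "bone_marrow"): 1.5e-7,
        ("liver", "bone_marrow"): 6.0e-8,
        ("spleen", "bone_marrow"): 1.0e-7,
        ("tumor", "bone_marrow"): 6.0e-8,
    }
    for (src, tgt), v in cross_pairs.items():
        f.append(DoseFactor(src, tgt, v * scale, "organ_level"))
    # concentration-kind factors: marrow self (blood-borne) and remainder crosses
    f.append(DoseFactor("bone_marrow", "bone_marrow", 1.1e-5 * scale,
                        "concentration"))
    f.append(DoseFactor("remainder", "kidneys", 1.0e-5 * scale, "concentration"))
    f.append(DoseFactor("remainder", "liver", 1.0e-5 * scale, "concentration"))
    f.append(DoseFactor("remainder", "spleen", 1.0e-5 * scale, "concentration"))
    return DoseFactorTable(phantom_sex=sex, phantom_mass_g=masses, factors=f)
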