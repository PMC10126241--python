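"""Cohort data model, CSV I/O, derived clinical quantities and eligibility filtering.

The analysis population is hospitalized heart-failure patients who were screened
for iron deficiency and are not anaemic by the WHO definition (haemoglobin below
13 g/dl in men or 12 g/dl in women).  The screening target is impaired iron
transport (IIT), defined as transferrin saturation (TSAT) below 20% irrespective
of ferritin.  Renal function is summarized by the 4-variable IDMS-traceable MDRD
estimate of the glomerular filtration rate (eGFR) and binned into four strata.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "EgfrStratum",
    "PatientRecord",
    "CohortTable",
    "WHO_ANAEMIA_HB",
    "IIT_TSAT_THRESHOLD",
    "read_cohort",
    "write_cohort",
    "egfr_mdrd",
    "tsat_from_iron",
    "is_anaemic",
    "label_iit",
    "label_id_guideline",
    "apply_eligibility",
    "assign_egfr_stratum",
    "stratum_counts",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


#: WHO haemoglobin thresholds (g/dl); anaemia is *strictly below* these.
WHO_ANAEMIA_HB: dict[Sex, float] = {Sex.MALE: 13.0, Sex.FEMALE: 12.0}

#: IIT is TSAT strictly below this percentage, irrespective of ferritin.
IIT_TSAT_THRESHOLD: float = 20.0


class EgfrStratum(enum.Enum):
    """Renal-function strata; half-open bins in ml/min/1.73 m²."""

    G_LT30 = (0.0, 30.0)
    G_30_60 = (30.0, 60.0)
    G_60_90 = (60.0, 90.0)
    G_GE90 = (90.0, math.inf)

    @property
    def lower(self) -> float:
        return self.value[0]

    @property
    def upper(self) -> float:
        return self.value[1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Strata ordered from best to worst renal function.
STRATA_BEST_TO_WORST = (
    EgfrStratum.G_GE90,
    EgfrStratum.G_60_90,
    EgfrStratum.G_30_60,
    EgfrStratum.G_LT30,
)

#: Canonical cohort CSV headers, in column order.
CANONICAL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "weight_kg",
    "height_m",
    "hb",
    "hct",
    "rdw",
    "mcv",
    "mchc",
    "serum_iron",
    "ferritin",
    "transferrin",
    "tsat",
    "tibc",
    "creatinine",
    "egfr",
    "lvef",
    "excluded_reason",
)

_NUMERIC_COLUMNS = tuple(
    c for c in CANONICAL_COLUMNS if c not in ("patient_id", "sex", "excluded_reason")
)

MISSING_TOKENS = ("", "NA")


@dataclass
class PatientRecord:
    """One patient's demographics, haematology, iron panel, renal function and LVEF.

    Laboratory fields are optional (NaN when missing).  Units: age years,
    weight kg, height m, hb/mchc g/dl, hct/rdw/tsat/lvef %, mcv fl,
    serum_iron/tibc µg/dl, ferritin µg/L, transferrin mg/dl, creatinine mg/dl,
    egfr ml/min/1.73 m².
    """

    patient_id: str
    sex: Sex
    age: float = math.nan
    weight_kg: float = math.nan
    height_m: float = math.nan
    hb: float = math.nan
    hct: float = math.nan
    rdw: float = math.nan
    mcv: float = math.nan
    mchc: float = math.nan
    serum_iron: float = math.nan
    ferritin: float = math.nan
    transferrin: float = math.nan
    tsat: float = math.nan
    tibc: float = math.nan
    creatinine: float = math.nan
    egfr: float = math.nan
    lvef: float = math.nan
    excluded_reason: str = ""


@dataclass
class CohortTable:
    """Ordered patient table with provenance and an exclusion log.

    ``df`` holds one row per retained patient with the canonical columns;
    ``exclusion_log`` lists (patient_id, reason) pairs for removed records and
    ``parse_log`` lists (patient_id, column, raw_value) for cells that failed
    to parse and were set to missing.
    """

    df: pd.DataFrame
    provenance: str = ""
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)
    parse_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate patient_id {dup!r}")
        excluded = {pid for pid, _ in self.exclusion_log}
        overlap = excluded.intersection(ids)
        if overlap:
            raise ValueError(f"excluded ids still present: {sorted(overlap)[:3]}")

    @property
    def n(self) -> int:
        return len(self.df)

    def records(self) -> list[PatientRecord]:
        out = []
        names = {f.name for f in dc_fields(PatientRecord)}
        for _, row in self.df.iterrows():
            kw = {k: row[k] for k in self.df.columns if k in names}
            kw["sex"] = Sex(kw["sex"])
            kw["excluded_reason"] = kw.get("excluded_reason") or ""
            out.append(PatientRecord(**kw))
        return out


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS})


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    ``column_map`` maps file headers to canonical field names; headers already
    canonical need no entry.  Unparseable numeric cells become NaN and are
    recorded in ``parse_log``.  ``patient_id`` and ``sex`` are mandatory.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    raw = raw.loc[:, [c for c in raw.columns if c in CANONICAL_COLUMNS]]
    for col in ("patient_id", "sex"):
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    if len(raw) == 0:
        raise ValueError("empty cohort")

    parse_log: list[tuple[str, str, str]] = []
    df = _empty_frame()
    df["patient_id"] = raw["patient_id"].astype(str)
    sex = raw["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin([s.value for s in Sex])
    if bad_sex.any():
        raise ValueError(
            f"unrecognized sex value {raw['sex'][bad_sex].iloc[0]!r}; expected male/female"
        )
    df["sex"] = sex
    df["excluded_reason"] = (
        raw["excluded_reason"].fillna("").astype(str).str.strip()
        if "excluded_reason" in raw.columns
        else ""
    )
    for col in _NUMERIC_COLUMNS:
        if col not in raw.columns:
            df[col] = np.nan
            continue
        cell = raw[col].str.strip()
        parsed = pd.to_numeric(cell, errors="coerce")
        bad = parsed.isna() & ~cell.isin(MISSING_TOKENS)
        for i in np.flatnonzero(bad.to_numpy()):
            parse_log.append((df["patient_id"].iloc[i], col, cell.iloc[i]))
        df[col] = parsed.astype(float)
    return CohortTable(
        df=df.reset_index(drop=True),
        provenance=provenance if provenance is not None else f"read from {path}",
        parse_log=parse_log,
    )


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort table (canonical columns) as CSV, NaN as empty cells."""
    cohort.df.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False, na_rep="")


def egfr_mdrd(
    creatinine: float | np.ndarray,
    age: float | np.ndarray,
    sex: Sex | str | np.ndarray,
    black: bool | np.ndarray = False,
) -> float | np.ndarray:
    """4-variable IDMS-traceable MDRD eGFR in ml/min/1.73 m².

    175 · creatinine^(−1.154) · age^(−0.203) · 0.742 (if female) · 1.212 (if black),
    with creatinine in mg/dl and age in years (adults only).
    """
    scalar = np.isscalar(creatinine) and np.isscalar(age) and isinstance(sex, (Sex, str))
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be positive")
    if np.any(age < 18):
        raise ValueError("MDRD is defined for adults (age >= 18)")
    sex_arr = np.asarray([s.value if isinstance(s, Sex) else str(s) for s in np.atleast_1d(sex)])
    female = sex_arr == Sex.FEMALE.value
    out = 175.0 * creatinine ** -1.154 * age ** -0.203
    out = out * np.where(female, 0.742, 1.0) * np.where(np.asarray(black), 1.212, 1.0)
    return float(out[0]) if scalar else out


def creatinine_from_egfr(
    egfr: float | np.ndarray,
    age: float | np.ndarray,
    sex: Sex | str | np.ndarray,
    black: bool | np.ndarray = False,
) -> np.ndarray:
    """Invert the MDRD formula: creatinine (mg/dl) that yields the given eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("egfr must be positive")
    base = egfr / egfr  # ones, broadcast shape
    unit_egfr = egfr_mdrd(base, age, sex, black)
    return (egfr / unit_egfr) ** (-1.0 / 1.154)


def tsat_from_iron(serum_iron: float, tibc: float) -> float:
    """Transferrin saturation (%) from serum iron and TIBC (both µg/dl).

    Values above TIBC are clipped to 100% (laboratory rounding can push the
    ratio slightly past saturation).
    """
    if tibc <= 0:
        raise ValueError("tibc must be positive")
    if serum_iron < 0:
        raise ValueError("serum_iron must be non-negative")
    return min(100.0 * serum_iron / tibc, 100.0)


def is_anaemic(hb: float, sex: Sex | str) -> bool:
    """WHO anaemia: Hb strictly below 13 g/dl (men) or 12 g/dl (women)."""
    if hb is None or (isinstance(hb, float) and math.isnan(hb)):
        raise ValueError("haemoglobin is required for anaemia screening")
    return hb < WHO_ANAEMIA_HB[Sex(sex)]


def label_iit(tsat: float) -> bool:
    """Impaired iron transport: TSAT strictly below 20%, irrespective of ferritin."""
    if tsat is None or (isinstance(tsat, float) and math.isnan(tsat)):
        raise ValueError("tsat is required for the IIT label")
    return tsat < IIT_TSAT_THRESHOLD


def label_id_guideline(ferritin: float, tsat: float) -> bool:
    """Guideline iron deficiency: ferritin < 100 µg/L, or 100–299 µg/L with TSAT < 20%."""
    for name, v in (("ferritin", ferritin), ("tsat", tsat)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{name} is required for the guideline ID label")
    return ferritin < 100.0 or (100.0 <= ferritin <= 299.0 and tsat < 20.0)


def assign_egfr_stratum(egfr: float) -> EgfrStratum:
    """Map an eGFR to its half-open stratum: [0,30), [30,60), [60,90), [90,∞)."""
    if egfr is None or (isinstance(egfr, float) and math.isnan(egfr)):
        raise ValueError("egfr is required for stratification")
    if egfr < 0:
        raise ValueError("egfr must be non-negative")
    for stratum in EgfrStratum:
        if stratum.lower <= egfr < stratum.upper:
            return stratum
    raise AssertionError("unreachable: strata partition [0, inf)")


def stratum_counts(egfr: Sequence[float] | np.ndarray) -> dict[EgfrStratum, int]:
    """Count records per eGFR stratum, best-to-worst order."""
    out = {s: 0 for s in STRATA_BEST_TO_WORST}
    for v in np.asarray(egfr, dtype=float):
        out[assign_egfr_stratum(float(v))] += 1
    return out


def apply_eligibility(cohort: CohortTable) -> CohortTable:
    """Apply the study's eligibility filter and resolve TSAT.

    Retains adults (age ≥ 18) who are non-anaemic and have a resolvable TSAT
    (measured, or derived from serum iron and TIBC when missing).  Records
    carrying a non-empty ``excluded_reason`` flag (pregnancy, transfusion,
    inflammation, cardiogenic shock, ...) are removed first.  Every removal is
    logged with its reason; the operation is idempotent.
    """
    df = cohort.df.copy().reset_index(drop=True)
    log = list(cohort.exclusion_log)
    keep = np.ones(len(df), dtype=bool)

    def drop(mask: np.ndarray, reason: str) -> None:
        for pid in df.loc[mask & keep, "patient_id"]:
            log.append((str(pid), reason))
        keep[mask & keep] = False

    flagged = df["excluded_reason"].fillna("").astype(str).str.strip() != ""
    for i in np.flatnonzero(flagged.to_numpy() & keep):
        log.append((str(df["patient_id"].iloc[i]), df["excluded_reason"].iloc[i]))
    keep[flagged.to_numpy()] = False

    age = df["age"].to_numpy(dtype=float)
    drop(np.isnan(age) | (age < 18), "age < 18 or missing")

    hb = df["hb"].to_numpy(dtype=float)
    drop(np.isnan(hb), "missing haemoglobin")
    thresh = df["sex"].map({s.value: WHO_ANAEMIA_HB[s] for s in Sex}).to_numpy(dtype=float)
    drop(hb < thresh, "anaemia")

    # resolve TSAT: measured preferred, else derived from iron/TIBC
    tsat = df["tsat"].to_numpy(dtype=float)
    iron = df["serum_iron"].to_numpy(dtype=float)
    tibc = df["tibc"].to_numpy(dtype=float)
    derivable = np.isnan(tsat) & ~np.isnan(iron) & ~np.isnan(tibc) & (tibc > 0)
    derived = np.where(derivable, np.minimum(100.0 * iron / np.where(tibc > 0, tibc, 1.0), 100.0), tsat)
    df["tsat"] = derived
    drop(np.isnan(derived), "no resolvable TSAT")

    retained = df.loc[keep].reset_index(drop=True)
    return CohortTable(
        df=retained,
        provenance=cohort.provenance + " | eligibility applied",
        exclusion_log=log,
        parse_log=list(cohort.parse_log),
    )


def iit_labels(cohort: CohortTable) -> np.ndarray:
    """Boolean IIT label (TSAT < 20%) per retained record."""
    tsat = cohort.df["tsat"].to_numpy(dtype=float)
    if np.isnan(tsat).any():
        raise ValueError("unresolved TSAT present; run apply_eligibility first")
    return tsat < IIT_TSAT_THRESHOLD
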