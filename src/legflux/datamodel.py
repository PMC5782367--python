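"""Domain types, cohort tables, validation and occasion averaging.

A cohort is five long-format CSV tables:

======================  ======================================================
patients.csv            patient_id, sex, age, bmi, admission_weight,
                        diagnosis_class
occasions.csv           patient_id, icu_day, hematocrit, sofa,
                        kcal_per_kg_day, aa_g_per_kg_day
samples.csv             patient_id, icu_day, minute, site, phe_ttr, mh3_ttr,
                        mh3, plus one column per amino acid (3-letter code)
                        holding the plasma concentration in umol/L
biopsies.csv            patient_id, icu_day, phe_ttr_muscle
plethysmography.csv     patient_id, icu_day, phase, reading_index,
                        slope_pct_per_min
======================  ======================================================

Concentrations are plasma concentrations in umol/L (identically nmol/ml, so
no numeric conversion is ever applied); enrichments are tracer-to-tracee
ratios (TTR). All kinetic equations consume the per-occasion means over the
four plateau timepoints (135/140/145/150 min), assembled here into
:class:`OccasionAverages`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import PROTEINOGENIC, SAMPLE_MINUTES, Config
from .errors import (
    IncompleteOccasionError,
    IntegrityError,
    SchemaError,
    ValidationError,
)

SITES = ("artery", "vein")
PHASES = ("pre", "post")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age: float
    bmi: float
    admission_weight: float
    diagnosis_class: str  # "medical" | "surgical"


@dataclass(frozen=True)
class StudyOccasion:
    patient_id: str
    icu_day: int
    hematocrit: float
    sofa: int | None = None
    kcal_per_kg_day: float | None = None
    aa_g_per_kg_day: float | None = None


@dataclass(frozen=True)
class TimedSample:
    patient_id: str
    icu_day: int
    minute: int
    site: str  # "artery" | "vein"
    conc: Mapping[str, float]  # amino acid -> umol/L (includes "mh3")
    phe_ttr: float
    mh3_ttr: float


@dataclass(frozen=True)
class BiopsyMeasurement:
    patient_id: str
    icu_day: int
    phe_ttr_muscle: float  # intracellular free-phenylalanine TTR (E_M)


@dataclass(frozen=True)
class PlethysmographySet:
    patient_id: str
    icu_day: int
    phase: str  # "pre" | "post"
    slopes: tuple[float, ...]  # % limb-volume change per minute


@dataclass
class OccasionAverages:
    """Per-occasion means feeding every kinetic equation.

    Ca/Cv: arterial/venous phenylalanine tracee concentration (nmol/ml);
    Ea/Ev: arterial/venous phenylalanine TTR; Em: muscle free-phe TTR from
    the biopsy (None when no biopsy was taken); Ca3..Ev3 the
    3-methylhistidine analogues; PF: plasma flow (ml/min/100 ml leg).
    aa_arterial/aa_venous carry the per-amino-acid concentration means used
    by the amino-acid flux stage.
    """

    Ca: float
    Cv: float
    Ea: float
    Ev: float
    Em: float | None
    Ca3: float
    Cv3: float
    Ea3: float
    Ev3: float
    PF: float
    aa_arterial: dict[str, float] = field(default_factory=dict)
    aa_venous: dict[str, float] = field(default_factory=dict)
    n_timepoints: int = 4


# ---------------------------------------------------------------------------
# enrichment-scale helpers
# ---------------------------------------------------------------------------

def ttr_to_mpe(ttr):
    """Tracer-to-tracee ratio -> mole percent excess (as a fraction)."""
    ttr = np.asarray(ttr, dtype=float)
    return ttr / (1.0 + ttr)


def mpe_to_ttr(mpe):
    """Mole percent excess (fraction) -> tracer-to-tracee ratio."""
    mpe = np.asarray(mpe, dtype=float)
    return mpe / (1.0 - mpe)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "patients": "patients.csv",
    "occasions": "occasions.csv",
    "samples": "samples.csv",
    "biopsies": "biopsies.csv",
    "pleth": "plethysmography.csv",
}

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "sex", "age", "bmi", "admission_weight",
                 "diagnosis_class"],
    "occasions": ["patient_id", "icu_day", "hematocrit"],
    "samples": ["patient_id", "icu_day", "minute", "site", "phe_ttr",
                "mh3_ttr", "mh3", "phe"],
    "biopsies": ["patient_id", "icu_day", "phe_ttr_muscle"],
    "pleth": ["patient_id", "icu_day", "phase", "reading_index",
              "slope_pct_per_min"],
}


@dataclass
class Cohort:
    """Validated in-memory cohort, one DataFrame per input table."""

    patients: pd.DataFrame
    occasions: pd.DataFrame
    samples: pd.DataFrame
    biopsies: pd.DataFrame
    pleth: pd.DataFrame

    def occasion_keys(self) -> list[tuple[str, int]]:
        df = self.occasions.sort_values(["patient_id", "icu_day"])
        return list(zip(df["patient_id"], df["icu_day"].astype(int)))

    def samples_for(self, patient_id: str, icu_day: int) -> pd.DataFrame:
        s = self.samples
        return s[(s["patient_id"] == patient_id) & (s["icu_day"] == icu_day)]

    def biopsy_ttr_for(self, patient_id: str, icu_day: int) -> float | None:
        b = self.biopsies
        row = b[(b["patient_id"] == patient_id) & (b["icu_day"] == icu_day)]
        if row.empty:
            return None
        return float(row["phe_ttr_muscle"].iloc[0])

    def pleth_slopes_for(self, patient_id: str, icu_day: int,
                         phase: str) -> np.ndarray:
        p = self.pleth
        rows = p[(p["patient_id"] == patient_id) & (p["icu_day"] == icu_day)
                 & (p["phase"] == phase)].sort_values("reading_index")
        return rows["slope_pct_per_min"].to_numpy(dtype=float)

    def hematocrit_for(self, patient_id: str, icu_day: int) -> float:
        o = self.occasions
        row = o[(o["patient_id"] == patient_id) & (o["icu_day"] == icu_day)]
        if row.empty:
            raise IntegrityError(
                f"no occasion row for ({patient_id!r}, day {icu_day})")
        return float(row["hematocrit"].iloc[0])

    def aa_columns(self) -> list[str]:
        skip = set(REQUIRED_COLUMNS["samples"]) - {"phe"}
        return [c for c in self.samples.columns if c not in skip
                and c not in ("patient_id", "icu_day", "minute", "site")]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the five CSV tables; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for attr, fname in TABLE_FILES.items():
            path = outdir / fname
            getattr(self, attr).to_csv(path, index=False)
            paths[attr] = path
        return paths


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}.csv is missing mandatory column '{col}'")


def _check_unique(df: pd.DataFrame, keys: list[str], table: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise IntegrityError(f"duplicated {tuple(keys)} in {table}.csv: {first}")


def validate_cohort(cohort: Cohort) -> Cohort:
    """Enforce every datamodel invariant; raises on the first violation."""
    for table in TABLE_FILES:
        _require_columns(getattr(cohort, table), table)

    pt = cohort.patients
    _check_unique(pt, ["patient_id"], "patients")
    if (pt["age"] <= 0).any():
        raise ValidationError("patients.csv: age must be > 0")
    if (pt["bmi"] <= 0).any():
        raise ValidationError("patients.csv: bmi must be > 0")

    occ = cohort.occasions
    _check_unique(occ, ["patient_id", "icu_day"], "occasions")
    if (occ["icu_day"] < 1).any():
        raise ValidationError("occasions.csv: icu_day must be >= 1")
    bad_hct = ~((occ["hematocrit"] > 0) & (occ["hematocrit"] < 1))
    if bad_hct.any():
        v = float(occ.loc[bad_hct, "hematocrit"].iloc[0])
        raise ValidationError(
            f"occasions.csv: hematocrit {v} outside the open interval (0, 1)")

    s = cohort.samples
    bad_min = ~s["minute"].isin(SAMPLE_MINUTES)
    if bad_min.any():
        v = s.loc[bad_min, "minute"].iloc[0]
        raise ValidationError(
            f"samples.csv: minute {v} not in allowed set {SAMPLE_MINUTES}")
    bad_site = ~s["site"].isin(SITES)
    if bad_site.any():
        v = s.loc[bad_site, "site"].iloc[0]
        raise ValidationError(f"samples.csv: site {v!r} not in {SITES}")
    _check_unique(s, ["patient_id", "icu_day", "minute", "site"], "samples")
    for col in ("phe_ttr", "mh3_ttr"):
        bad = ~((s[col] >= 0) & (s[col] < 1))
        if bad.any():
            raise ValidationError(
                f"samples.csv: {col} value {float(s.loc[bad, col].iloc[0])} "
                "outside [0, 1)")
    conc_cols = [c for c in s.columns
                 if c not in ("patient_id", "icu_day", "minute", "site",
                              "phe_ttr", "mh3_ttr")]
    for col in conc_cols:
        if (s[col] < 0).any():
            raise ValidationError(
                f"samples.csv: negative concentration in column '{col}'")

    b = cohort.biopsies
    _check_unique(b, ["patient_id", "icu_day"], "biopsies")
    bad = ~((b["phe_ttr_muscle"] >= 0) & (b["phe_ttr_muscle"] < 1))
    if bad.any():
        raise ValidationError("biopsies.csv: phe_ttr_muscle outside [0, 1)")

    pl = cohort.pleth
    bad_phase = ~pl["phase"].isin(PHASES)
    if bad_phase.any():
        raise ValidationError(
            f"plethysmography.csv: phase {pl.loc[bad_phase, 'phase'].iloc[0]!r} "
            f"not in {PHASES}")
    _check_unique(pl, ["patient_id", "icu_day", "phase", "reading_index"],
                  "plethysmography")
    if not np.isfinite(pl["slope_pct_per_min"]).all():
        raise ValidationError("plethysmography.csv: non-finite slope reading")

    # referential integrity: every occasion's patient exists; every sample,
    # biopsy and plethysmography row points at an occasion
    known_patients = set(pt["patient_id"])
    if not set(occ["patient_id"]).issubset(known_patients):
        missing = set(occ["patient_id"]) - known_patients
        raise IntegrityError(f"occasions reference unknown patients: {missing}")
    occ_keys = set(zip(occ["patient_id"], occ["icu_day"].astype(int)))
    for name, df in (("samples", s), ("biopsies", b), ("plethysmography", pl)):
        keys = set(zip(df["patient_id"], df["icu_day"].astype(int)))
        if not keys.issubset(occ_keys):
            missing = sorted(keys - occ_keys)[:3]
            raise IntegrityError(
                f"{name}.csv rows reference unknown occasions, e.g. {missing}")
    return cohort


def load_cohort(path: str | Path | Mapping[str, str | Path],
                config: Config | None = None) -> Cohort:
    """Read and validate a cohort from a directory (or a table->path map)."""
    if isinstance(path, Mapping):
        paths = {k: Path(v) for k, v in path.items()}
    else:
        d = Path(path)
        paths = {k: d / f for k, f in TABLE_FILES.items()}
    frames = {}
    for table, p in paths.items():
        if not p.exists():
            raise SchemaError(f"missing input file: {p}")
        frames[table] = pd.read_csv(p)
    cohort = Cohort(**frames)
    if config is not None and config.units.enrichment_scale == "mpe":
        for col in ("phe_ttr", "mh3_ttr"):
            cohort.samples[col] = mpe_to_ttr(cohort.samples[col])
        cohort.biopsies["phe_ttr_muscle"] = mpe_to_ttr(
            cohort.biopsies["phe_ttr_muscle"])
    return validate_cohort(cohort)


# ---------------------------------------------------------------------------
# per-occasion averaging and steady-state QC
# ---------------------------------------------------------------------------

def _site_means(samples: pd.DataFrame, site: str, columns: Iterable[str],
                min_timepoints: int, allow_partial: bool) -> tuple[dict, int]:
    rows = samples[samples["site"] == site]
    n = len(rows)
    if n < min_timepoints:
        if not (allow_partial and n >= 2):
            raise IncompleteOccasionError(
                f"site '{site}' has {n} timepoints; "
                f"{min_timepoints} required")
        warnings.warn(
            f"averaging only {n} timepoints for site '{site}'", stacklevel=3)
    return {c: float(rows[c].mean()) for c in columns}, n


def average_occasion(samples: pd.DataFrame,
                     biopsy_ttr: float | None,
                     plasma_flow: float,
                     config: Config | None = None) -> OccasionAverages:
    """Arithmetic means over the plateau timepoints for one occasion.

    Concentrations and enrichments are averaged separately (never their
    products); the biopsy enrichment and the plasma flow are copied through
    from their own stages.
    """
    cfg = config or Config()
    aa_cols = [c for c in samples.columns
               if c not in ("patient_id", "icu_day", "minute", "site",
                            "phe_ttr", "mh3_ttr", "mh3")]
    cols = ["phe", "phe_ttr", "mh3", "mh3_ttr"] + [c for c in aa_cols
                                                   if c != "phe"]
    art, n_a = _site_means(samples, "artery", cols,
                           cfg.qc.min_timepoints, cfg.qc.allow_partial)
    ven, n_v = _site_means(samples, "vein", cols,
                           cfg.qc.min_timepoints, cfg.qc.allow_partial)
    return OccasionAverages(
        Ca=art["phe"], Cv=ven["phe"],
        Ea=art["phe_ttr"], Ev=ven["phe_ttr"], Em=biopsy_ttr,
        Ca3=art["mh3"], Cv3=ven["mh3"],
        Ea3=art["mh3_ttr"], Ev3=ven["mh3_ttr"],
        PF=plasma_flow,
        aa_arterial={c: art[c] for c in aa_cols},
        aa_venous={c: ven[c] for c in aa_cols},
        n_timepoints=min(n_a, n_v),
    )


def steady_state_qc(samples: pd.DataFrame,
                    cv_threshold: float = 0.15,
                    analytes: Iterable[str] = ("phe", "phe_ttr",
                                               "mh3", "mh3_ttr")) -> pd.DataFrame:
    """Coefficient of variation across timepoints per site and analyte.

    The primed-continuous infusion is assumed to have reached an isotopic
    plateau by the first sampling minute; a large CV across the four
    plateau samples flags that assumption. CV uses the sample SD (ddof=1).
    A zero mean makes the CV undefined; such series are flagged degenerate.
    """
    records = []
    for site in SITES:
        rows = samples[samples["site"] == site]
        if len(rows) < 2:
            raise IncompleteOccasionError(
                f"site '{site}' has {len(rows)} timepoints; >=2 required for QC")
        for col in analytes:
            x = rows[col].to_numpy(dtype=float)
            mean = x.mean()
            if mean == 0.0:
                records.append({"site": site, "analyte": col, "mean": 0.0,
                                "cv": np.nan, "flag": True, "degenerate": True})
                continue
            cv = x.std(ddof=1) / mean
            records.append({"site": site, "analyte": col, "mean": mean,
                            "cv": cv, "flag": bool(cv > cv_threshold),
                            "degenerate": False})
    return pd.DataFrame.from_records(records)
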