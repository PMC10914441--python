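"""Subject-table I/O, preprocessing and training-set construction.

This module turns raw per-subject volumetric tables (one row per MRI, raw
structure volumes in mm^3 plus total intracranial volume, TIV) into the
z-scored normalized series the lifespan models are fitted on:

1. left/right volumes of symmetric structures are summed into one total;
2. volumes are normalized to head size as a percentage of TIV;
3. normalized volumes are z-scored against a reference population
   (by default the healthy controls) so structures of different sizes
   are comparable;
4. normality of each normalized volume is checked with a one-sample
   Kolmogorov-Smirnov test (recorded, never used to drop data);
5. the disease training set is built by pooling all cases with every
   control strictly younger than the youngest case, which anchors the
   disease trajectory to the healthy one over the unobserved early life.

Model-based quality flags (residuals beyond 2 SD of a fitted trajectory)
are reported for human review; subjects are never auto-removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

#: columns every subject table must provide, in canonical order
REQUIRED_COLUMNS = ("subject_id", "cohort_id", "group", "sex", "age", "tiv_mm3")

VALID_GROUPS = ("control", "case")


class DataValidationError(ValueError):
    """A subject table violates the input contract (missing columns, bad values)."""


# ---------------------------------------------------------------------------
# structure metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureMetadata:
    """Declares which structures are bilateral and how they group anatomically.

    Parameters
    ----------
    symmetric
        Structure names stored as two columns ``<name>_L`` / ``<name>_R``.
    midline
        Structure names stored as a single column (brainstem, vermis...).
    groups
        Map structure name -> anatomical group label, used by staging.
    """

    symmetric: tuple[str, ...] = ()
    midline: tuple[str, ...] = ()
    groups: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "StructureMetadata":
        """Load metadata from a YAML or JSON file with keys symmetric/midline/groups."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(
            symmetric=tuple(raw.get("symmetric", ())),
            midline=tuple(raw.get("midline", ())),
            groups=dict(raw.get("groups", {})),
        )

    @classmethod
    def infer(cls, columns: Iterable[str]) -> "StructureMetadata":
        """Infer symmetric/midline structures from column names.

        A base name with both ``_L`` and ``_R`` columns is symmetric; a base
        name with exactly one hemisphere column is an error; anything else
        is midline.
        """
        cols = [c for c in columns if c not in REQUIRED_COLUMNS]
        bases: dict[str, set[str]] = {}
        midline = []
        for c in cols:
            if c.endswith(("_L", "_R")):
                bases.setdefault(c[:-2], set()).add(c[-1])
            else:
                midline.append(c)
        for base, sides in bases.items():
            if sides != {"L", "R"}:
                missing = ({"L", "R"} - sides).pop()
                raise DataValidationError(
                    f"structure '{base}' is missing its {missing} hemisphere column"
                )
        return cls(symmetric=tuple(sorted(bases)), midline=tuple(midline))

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(self.symmetric) + tuple(self.midline)


# ---------------------------------------------------------------------------
# subject table I/O
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a CSV/TSV subject table.

    The dialect is comma by default; tab is accepted (auto-detected from the
    extension or ``sep``).  A header row is required.  Missing age/TIV cells
    are rejected; missing individual structure volumes are kept as NaN with
    a warning.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataValidationError(f"cannot read subject table {path}: {exc}") from exc
    validate_subject_table(df)
    return df


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a subject table as CSV (or TSV if the path ends in .tsv)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def validate_subject_table(df: pd.DataFrame) -> None:
    """Check the subject-table contract, raising DataValidationError on breach."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing required columns: {missing}")
    bad_group = set(df["group"].unique()) - set(VALID_GROUPS)
    if bad_group:
        raise DataValidationError(f"invalid group labels: {sorted(bad_group)}")
    if df["age"].isna().any():
        raise DataValidationError("age has missing values")
    if df["tiv_mm3"].isna().any():
        raise DataValidationError("tiv_mm3 has missing values")
    age = df["age"].to_numpy(float)
    if np.any(age <= 0) or np.any(age > 120):
        raise DataValidationError("age must be in (0, 120] years")
    if np.any(df["tiv_mm3"].to_numpy(float) <= 0):
        raise DataValidationError("tiv_mm3 must be positive")
    vol_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    for c in vol_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            logger.warning("structure column %s has %d missing values", c, int(vals.isna().sum()))
        if (vals.dropna() < 0).any():
            raise DataValidationError(f"negative volumes in column {c}")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def combine_lr(df: pd.DataFrame, metadata: StructureMetadata | None = None) -> pd.DataFrame:
    """Sum left and right volumes of symmetric structures into one column.

    Symmetric structures stored as ``<name>_L``/``<name>_R`` become a single
    column ``<name>`` holding L+R; midline structures pass through unchanged.
    If *metadata* is omitted it is inferred from the column names.  A
    symmetric structure with one hemisphere column missing is a hard error.
    """
    if metadata is None:
        metadata = StructureMetadata.infer(df.columns)
    out = df[list(REQUIRED_COLUMNS)].copy()
    for name in metadata.symmetric:
        left, right = f"{name}_L", f"{name}_R"
        for col in (left, right):
            if col not in df.columns:
                raise DataValidationError(
                    f"symmetric structure '{name}' is missing column '{col}'"
                )
        out[name] = df[left].to_numpy(float) + df[right].to_numpy(float)
    for name in metadata.midline:
        if name not in df.columns:
            raise DataValidationError(f"midline structure '{name}' not found in table")
        out[name] = df[name].to_numpy(float)
    return out


def normalize_to_tiv(raw, tiv):
    """Normalize raw volume (mm^3) to percent of total intracranial volume.

    Returns ``100 * raw / tiv``; invariant to any common rescaling of both
    arguments (unit changes cancel).
    """
    raw = np.asarray(raw, float)
    tiv = np.asarray(tiv, float)
    if np.any(tiv <= 0):
        raise DataValidationError("TIV must be strictly positive")
    return 100.0 * raw / tiv


@dataclass
class StructureSeries:
    """Z-scored normalized volumes of one structure, with subject ages/groups.

    ``reference_mean``/``reference_sd`` are in normalized-volume units
    (% of TIV) and allow the inverse transform back to normalized volume.
    """

    structure_name: str
    ages: np.ndarray
    values: np.ndarray          # z-scores of normalized volume
    groups: np.ndarray          # 'control' / 'case' per subject
    reference_mean: float
    reference_sd: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.values = np.asarray(self.values, float)
        self.groups = np.asarray(self.groups)
        if not (len(self.ages) == len(self.values) == len(self.groups)):
            raise ValueError("ages, values and groups must have equal length")
        if not self.reference_sd > 0:
            raise ValueError("reference_sd must be positive")

    def subset(self, mask: np.ndarray) -> "StructureSeries":
        return StructureSeries(
            self.structure_name, self.ages[mask], self.values[mask],
            self.groups[mask], self.reference_mean, self.reference_sd,
        )


def zscore(values, reference, structure_name: str = "") -> StructureSeries | np.ndarray:
    """Z-score values against a reference sample's mean and SD.

    ``z = (v - mean(reference)) / sd(reference)`` (SD with ddof=1).  The
    reference needs at least two subjects and nonzero variance.  Returns a
    bare array; use :func:`build_structure_series` for the full series object.
    """
    values = np.asarray(values, float)
    reference = np.asarray(reference, float)
    if reference.size < 2:
        raise DataValidationError("z-score reference needs at least 2 subjects")
    mean = float(np.mean(reference))
    sd = float(np.std(reference, ddof=1))
    if sd == 0:
        raise DataValidationError("z-score reference has zero variance")
    return (values - mean) / sd


def build_structure_series(
    df: pd.DataFrame,
    structure: str,
    reference_group: str = "control",
) -> StructureSeries:
    """Normalize one combined structure column to TIV and z-score it.

    The z-score reference is, by default, every control across the lifespan,
    so the healthy chart is centred and case z-scores read as deviation from
    normal.  Rows with a missing volume for this structure are dropped.
    """
    ok = df[structure].notna().to_numpy()
    sub = df.loc[ok]
    norm = normalize_to_tiv(sub[structure].to_numpy(float), sub["tiv_mm3"].to_numpy(float))
    ref = norm[(sub["group"] == reference_group).to_numpy()]
    if ref.size < 2:
        raise DataValidationError(
            f"structure {structure}: reference group '{reference_group}' too small"
        )
    mean = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise DataValidationError(f"structure {structure}: zero reference variance")
    return StructureSeries(
        structure_name=structure,
        ages=sub["age"].to_numpy(float),
        values=(norm - mean) / sd,
        groups=sub["group"].to_numpy(),
        reference_mean=mean,
        reference_sd=sd,
    )


# ---------------------------------------------------------------------------
# normality check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """One-sample Kolmogorov-Smirnov normality check for one structure."""

    structure_name: str
    statistic: float
    pvalue: float
    reject: bool      # True when normality is rejected at alpha
    tested: bool      # False when n < 8 or the sample is degenerate


def ks_normality(values, alpha: float = 0.05, structure_name: str = "") -> KSResult:
    """Kolmogorov-Smirnov test of normality at the given level (default 5%).

    The sample is standardized by its own mean/SD and compared against the
    standard normal law.  Samples with n < 8 or zero variance are flagged
    untested rather than judged.  Failing structures are flagged in the run
    report, never dropped.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if values.size < 8 or sd == 0:
        return KSResult(structure_name, float("nan"), float("nan"), False, False)
    z = (values - values.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return KSResult(structure_name, float(stat), float(p), bool(p < alpha), True)


# ---------------------------------------------------------------------------
# training sets and model-based QC flags
# ---------------------------------------------------------------------------

def build_disease_training_set(df: pd.DataFrame) -> pd.DataFrame:
    """Pool all cases with controls strictly younger than the youngest case.

    Neurodegeneration is assumed continuous and progressive, so before any
    patient is observed the disease trajectory coincides with the healthy
    one; controls younger than the youngest case therefore constrain the
    disease model over early life.  "Younger than" is a strict inequality
    on decimal age.
    """
    cases = df[df["group"] == "case"]
    if len(cases) == 0:
        raise DataValidationError("disease training set requires at least one case")
    youngest = float(cases["age"].min())
    controls = df[(df["group"] == "control") & (df["age"] < youngest)]
    out = pd.concat([controls, cases], ignore_index=True)
    return out


def flag_model_outliers(series: StructureSeries, model) -> np.ndarray:
    """Flag subjects whose residual from the fitted curve exceeds 2 residual SD.

    Mirrors a segmentation-QC recheck: flagged subjects are reported for
    human re-inspection, not removed.  *model* is a fitted TrajectoryModel.
    """
    resid = series.values - model.predict(series.ages)
    sd = model.residual_sd
    if sd == 0:
        return np.zeros(series.values.shape, dtype=bool)
    return np.abs(resid) > 2.0 * sd
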