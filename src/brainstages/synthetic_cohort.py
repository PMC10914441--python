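"""Synthetic multi-cohort volumetric datasets with known ground truth.

Real lifespan brain charts are fitted on thousands of control MRIs pooled
from many cohorts with heterogeneous age windows, plus a small patient
group confined to older ages.  This module emulates that situation from
known ground truth so every downstream stage (normalization, fitting,
divergence detection, staging) can be validated by parameter recovery:

* controls follow a smooth polynomial age trajectory per structure,
  expressed in z-units of the structure's normalized volume;
* cases follow the *same* trajectory until a structure-specific onset age,
  then fall below it linearly (a hinge) at ``deviation_rate`` z-units per
  year — neurodegeneration modelled as continuous and progressive;
* homoscedastic Gaussian observation noise is added in z-units;
* z-trajectories are mapped back to raw mm^3 through per-structure
  reference statistics (% of TIV) and per-subject TIV drawn from each
  cohort's own normal law, so TIV normalization is genuinely exercised;
* symmetric structures are emitted as left/right columns that sum to the
  intended total, so hemisphere summation is exercised too.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_table import REQUIRED_COLUMNS

#: smallest raw volume emitted (mm^3); lower draws are clamped and counted
VOLUME_FLOOR = 1.0


@dataclass(frozen=True)
class TrajectoryTruth:
    """Ground truth for one structure: healthy curve + disease kinetics.

    healthy_coeffs are polynomial coefficients in ascending order, degree
    <= 3, giving the z-of-normalized-volume trajectory against age in
    years.  onset_age is the age at which cases start deviating (None for
    a non-diverging structure); deviation_rate is the z-units lost per year
    past onset.  norm_mean / norm_sd are the structure's reference
    normalized-volume statistics (% of TIV) used to invert z into raw mm^3.
    lr_split_fraction is the fraction of the total assigned to the left
    hemisphere, or None for a midline structure (single column).
    """

    structure_name: str
    healthy_coeffs: tuple[float, ...]
    onset_age: float | None = None
    deviation_rate: float = 0.0
    noise_sd: float = 0.8
    lr_split_fraction: float | None = 0.5
    norm_mean: float = 1.0
    norm_sd: float = 0.1

    def __post_init__(self) -> None:
        if len(self.healthy_coeffs) > 4:
            raise ValueError("healthy trajectory degree must be <= 3")
        if self.deviation_rate < 0:
            raise ValueError("deviation_rate must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.onset_age is not None and not (0 < self.onset_age <= 120):
            raise ValueError("onset_age must be in (0, 120] years or None")
        if self.lr_split_fraction is not None and not (0 <= self.lr_split_fraction <= 1):
            raise ValueError("lr_split_fraction must be in [0, 1] or None")
        if not (self.norm_mean > 0 and self.norm_sd > 0):
            raise ValueError("norm_mean and norm_sd must be positive")

    def healthy_z(self, ages) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ages, float),
                                                np.asarray(self.healthy_coeffs, float))

    def case_z(self, ages) -> np.ndarray:
        """Healthy curve minus the post-onset hinge deviation (noise-free)."""
        ages = np.asarray(ages, float)
        z = self.healthy_z(ages)
        if self.onset_age is not None and self.deviation_rate > 0:
            z = z - self.deviation_rate * np.maximum(0.0, ages - self.onset_age)
        return z


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort: group, size, age window, TIV law."""

    cohort_id: str
    group: str               # 'control' or 'case'
    n_subjects: int
    age_range: tuple[float, float]
    tiv_mean: float = 1.45e6  # mm^3
    tiv_sd: float = 1.3e5

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be control|case, got {self.group!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if not self.tiv_mean > 0:
            raise ValueError("tiv_mean must be positive")


def _truth_columns(truth: TrajectoryTruth) -> list[str]:
    if truth.lr_split_fraction is None:
        return [truth.structure_name]
    return [f"{truth.structure_name}_L", f"{truth.structure_name}_R"]


def generate_cohort(
    specs: Sequence[CohortSpec],
    truths: Sequence[TrajectoryTruth],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cross-sectional subject table plus its truth table.

    Ages are uniform within each cohort's window; TIV is normal, truncated
    positive.  For every structure the noisy z-trajectory is converted to a
    normalized volume (norm_mean + z * norm_sd, in % of TIV) and then to raw
    mm^3 via the subject's TIV; symmetric structures are split left/right by
    lr_split_fraction.  Raw volumes below a small positive floor are clamped
    and counted in ``subjects.attrs['n_clamped']``.

    Returns (subject table, truth table); identical inputs and seed yield
    identical tables.
    """
    if not specs:
        raise ValueError("need at least one cohort spec")
    names = [t.structure_name for t in truths]
    if len(set(names)) != len(names):
        raise ValueError("structure names must be unique")
    rng = np.random.default_rng(seed)
    frames = []
    n_clamped = 0
    for spec in specs:
        n = spec.n_subjects
        ages = rng.uniform(*spec.age_range, size=n)
        tiv = rng.normal(spec.tiv_mean, spec.tiv_sd, size=n)
        while np.any(tiv <= 0):  # truncate the TIV law at zero by redraw
            bad = tiv <= 0
            tiv[bad] = rng.normal(spec.tiv_mean, spec.tiv_sd, size=int(bad.sum()))
        sex = rng.choice(["F", "M"], size=n)
        row = {
            "subject_id": [f"{spec.cohort_id}_{i:05d}" for i in range(n)],
            "cohort_id": spec.cohort_id,
            "group": spec.group,
            "sex": sex,
            "age": ages,
            "tiv_mm3": tiv,
        }
        for truth in truths:
            z = truth.case_z(ages) if spec.group == "case" else truth.healthy_z(ages)
            z = z + rng.normal(0.0, truth.noise_sd, size=n)
            normalized = truth.norm_mean + z * truth.norm_sd       # % of TIV
            raw = normalized / 100.0 * tiv                          # mm^3
            clip = raw < VOLUME_FLOOR
            n_clamped += int(clip.sum())
            raw = np.maximum(raw, VOLUME_FLOOR)
            if truth.lr_split_fraction is None:
                row[truth.structure_name] = raw
            else:
                row[f"{truth.structure_name}_L"] = raw * truth.lr_split_fraction
                row[f"{truth.structure_name}_R"] = raw * (1.0 - truth.lr_split_fraction)
        frames.append(pd.DataFrame(row))
    subjects = pd.concat(frames, ignore_index=True)
    order = list(REQUIRED_COLUMNS) + [c for t in truths for c in _truth_columns(t)]
    subjects = subjects[order]
    subjects.attrs["n_clamped"] = n_clamped
    return subjects, truth_table(truths)


def truth_table(truths: Sequence[TrajectoryTruth]) -> pd.DataFrame:
    """Echo every TrajectoryTruth as one row (coefficients JSON-encoded)."""
    return pd.DataFrame(
        {
            "structure_name": [t.structure_name for t in truths],
            "healthy_coeffs": [json.dumps(list(t.healthy_coeffs)) for t in truths],
            "onset_age": [t.onset_age for t in truths],
            "deviation_rate": [t.deviation_rate for t in truths],
            "noise_sd": [t.noise_sd for t in truths],
            "lr_split_fraction": [t.lr_split_fraction for t in truths],
            "norm_mean": [t.norm_mean for t in truths],
            "norm_sd": [t.norm_sd for t in truths],
        }
    )


def truths_from_table(df: pd.DataFrame) -> list[TrajectoryTruth]:
    out = []
    for _, r in df.iterrows():
        out.append(
            TrajectoryTruth(
                structure_name=r["structure_name"],
                healthy_coeffs=tuple(json.loads(r["healthy_coeffs"])),
                onset_age=None if pd.isna(r["onset_age"]) else float(r["onset_age"]),
                deviation_rate=float(r["deviation_rate"]),
                noise_sd=float(r["noise_sd"]),
                lr_split_fraction=(None if pd.isna(r["lr_split_fraction"])
                                   else float(r["lr_split_fraction"])),
                norm_mean=float(r["norm_mean"]),
                norm_sd=float(r["norm_sd"]),
            )
        )
    return out


def save_truth_table(truths: Sequence[TrajectoryTruth], path: str | Path) -> None:
    path = Path(path)
    df = truth_table(truths)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preset study conditions
# ---------------------------------------------------------------------------

def _peaked_quadratic(peak_age: float, peak_z: float, z_at_100: float) -> tuple[float, ...]:
    """Quadratic z-trajectory with a maximum at peak_age, hitting z_at_100 at 100y."""
    c = (peak_z - z_at_100) / (100.0 - peak_age) ** 2
    return (peak_z - c * peak_age**2, 2.0 * c * peak_age, -c)


def default_control_specs(n_controls: int = 2000) -> list[CohortSpec]:
    """Multiple control cohorts with distinct, overlapping age windows (1-100 y).

    The split mimics the real situation where paediatric, young-adult,
    mid-life and ageing cohorts with different head-size distributions are
    pooled to cover the lifespan.
    """
    weights = {"paediatric": (0.15, (1.0, 18.0), 1.30e6, 1.4e5),
               "young_adult": (0.35, (18.0, 45.0), 1.47e6, 1.3e5),
               "midlife": (0.25, (35.0, 70.0), 1.45e6, 1.2e5),
               "ageing": (0.15, (55.0, 95.0), 1.43e6, 1.2e5),
               "lifespan": (0.10, (1.0, 100.0), 1.44e6, 1.3e5)}
    specs = []
    assigned = 0
    items = list(weights.items())
    for i, (name, (w, rng_, tm, ts)) in enumerate(items):
        n = n_controls - assigned if i == len(items) - 1 else int(round(w * n_controls))
        assigned += n
        specs.append(CohortSpec(f"ctrl_{name}", "control", n, rng_, tm, ts))
    return specs


def default_case_spec(n_cases: int = 60) -> CohortSpec:
    """One patient cohort restricted to ages 55-86, as in 4RTNI-like designs."""
    return CohortSpec("cases", "case", n_cases, (55.0, 86.0), 1.42e6, 1.2e5)


def psp_like_truths(noise_sd: float = 0.8) -> list[TrajectoryTruth]:
    """Nine structures whose onset order, grouping and severities emulate the
    published PSP-RS atrophy cascade: ventral diencephalon first, then
    pallidum, then brainstem + striatum + amygdala, then thalamus (most
    severe at 90 y), then frontal, then occipital cortex."""
    def t(name, peak, z100, onset, d90, mean, midline=False, coeffs=None):
        rate = d90 / (90.0 - onset)
        return TrajectoryTruth(
            structure_name=name,
            healthy_coeffs=coeffs or _peaked_quadratic(peak, 0.7, z100),
            onset_age=onset,
            deviation_rate=rate,
            noise_sd=noise_sd,
            lr_split_fraction=None if midline else 0.5,
            norm_mean=mean,
            norm_sd=0.1 * mean,
        )

    growth_cubic = (-1.5, 0.14, -0.0025, 1.1e-5)  # rise to ~0.75 at 30, slow fall
    return [
        t("ventral_diencephalon", 30, -1.6, 48.0, 2.3, 0.55),
        t("pallidum", 28, -1.5, 52.0, 2.9, 0.22),
        t("brainstem", 35, -1.4, 55.0, 2.4, 1.55, midline=True, coeffs=growth_cubic),
        t("putamen", 25, -1.8, 55.5, 1.8, 0.65),
        t("caudate", 26, -1.7, 56.0, 1.7, 0.52),
        t("amygdala", 32, -1.3, 56.5, 1.6, 0.20),
        t("thalamus", 30, -1.6, 60.0, 4.0, 1.00),
        t("precentral_gyrus", 24, -1.9, 64.0, 1.45, 1.90),
        t("occipital_pole", 27, -1.5, 68.0, 1.25, 0.45),
    ]


def recovery_truths(
    onsets: Sequence[float] = (48, 52, 56, 60, 64, 68, 72, 76),
    deviation_rate: float = 0.08,
    noise_sd: float = 0.8,
) -> list[TrajectoryTruth]:
    """Eight structures with well-separated onsets (>= 4 years apart) and a
    common deviation rate, used for ordering/onset parameter-recovery runs."""
    names = ["ventral_diencephalon", "pallidum", "brainstem", "amygdala",
             "thalamus", "hippocampus", "precentral_gyrus", "occipital_pole"]
    means = [0.55, 0.22, 1.55, 0.20, 1.00, 0.35, 1.90, 0.45]
    out = []
    for name, onset, mean in zip(names, onsets, means):
        out.append(
            TrajectoryTruth(
                structure_name=name,
                healthy_coeffs=_peaked_quadratic(30, 0.7, -1.6),
                onset_age=float(onset),
                deviation_rate=deviation_rate,
                noise_sd=noise_sd,
                lr_split_fraction=None if name == "brainstem" else 0.5,
                norm_mean=mean,
                norm_sd=0.1 * mean,
            )
        )
    return out


def null_truths(n_structures: int = 4, noise_sd: float = 0.8) -> list[TrajectoryTruth]:
    """Structures with zero disease deviation, for false-positive control runs."""
    return [
        TrajectoryTruth(
            structure_name=f"null_structure_{i:02d}",
            healthy_coeffs=_peaked_quadratic(25 + 3 * i, 0.7, -1.4 - 0.1 * i),
            onset_age=None,
            deviation_rate=0.0,
            noise_sd=noise_sd,
            lr_split_fraction=0.5 if i % 2 == 0 else None,
            norm_mean=0.3 + 0.3 * i,
            norm_sd=0.03 + 0.03 * i,
        )
        for i in range(n_structures)
    ]
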