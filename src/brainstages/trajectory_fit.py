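"""Lifespan trajectory fitting: candidate polynomials, gates, BIC selection.

For each brain structure and group, candidate ordinary-least-squares
polynomial models of z-scored normalized volume against age are fitted from
the simplest to the most complex (linear, quadratic, cubic).  A candidate is
*eligible* only when the F test against the constant model is significant
(P < 0.05) and every non-intercept coefficient passes a two-sided t test
(P < 0.05).  Among eligible candidates the one with the lowest BIC wins; if
no candidate is eligible the trajectory falls back to the constant model
(degree 0), i.e. no credible age effect.

BIC is computed under the Gaussian likelihood as

    BIC = n * ln(RSS / n) + k * ln(n),      k = degree + 2

(counting the intercept and the residual variance).  Any affine-equivalent
variant would select identically; this one is fixed and documented.

Numerical note: ages are rescaled internally by a fixed factor of 100 (pure
scaling, no centering) so the Vandermonde design stays well conditioned up
to age 100; coefficients and their covariance are reported back in the
raw-age basis through the exact diagonal transform.  A pure scaling leaves
every per-coefficient t statistic, the F statistic, RSS and BIC unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

#: internal age rescaling (years); pure scaling keeps raw-basis inference exact
AGE_SCALE = 100.0

#: candidate polynomial degrees, simplest first
CANDIDATE_DEGREES = (1, 2, 3)

_TINY_RSS = 1e-300  # guards log(0) for exact interpolation


class FitError(ValueError):
    """Raised for degenerate fitting inputs (too few points, no age spread...)."""


@dataclass
class FitCandidate:
    """One polynomial degree's OLS fit with its significance gates and BIC.

    Coefficients are in the raw-age basis, ascending order (intercept first).
    """

    degree: int
    coefficients: np.ndarray
    coefficient_se: np.ndarray
    coefficient_p: np.ndarray
    f_p: float
    rss: float
    n: int
    k_params: int
    bic: float
    eligible: bool
    cov: np.ndarray = field(repr=False)


def _bic(rss: float, n: int, k_params: int) -> float:
    return n * np.log(max(rss, _TINY_RSS) / n) + k_params * np.log(n)


def fit_polynomial(
    ages,
    values,
    degree: int,
    alpha: float = 0.05,
    include_intercept_gate: bool = False,
) -> FitCandidate:
    """OLS fit of a polynomial in age, with t/F gates and BIC.

    Parameters
    ----------
    ages, values
        Training sample; z-scores of normalized volume against age in years.
    degree
        Polynomial degree, 1-3.
    alpha
        Significance level for the eligibility gates.
    include_intercept_gate
        When True the intercept's t test also enters the eligibility gate.
        Off by default: on z-scored data the intercept is not a shape
        parameter and requiring its significance would spuriously reject
        centred trajectories.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if degree not in CANDIDATE_DEGREES:
        raise FitError(f"degree must be one of {CANDIDATE_DEGREES}, got {degree}")
    n = ages.size
    p = degree + 1
    if n < degree + 2:
        raise FitError(f"need at least degree+2 = {degree + 2} points, got {n}")
    if np.ptp(ages) == 0:
        raise FitError("ages have zero spread; design is rank deficient")

    X = np.vander(ages / AGE_SCALE, p, increasing=True)
    if np.linalg.matrix_rank(X) < p:
        raise FitError("rank-deficient design matrix")
    res = sm.OLS(values, X).fit()

    scale = AGE_SCALE ** -np.arange(p)  # exact back-transform to raw-age basis
    coefficients = res.params * scale
    cov = res.cov_params() * np.outer(scale, scale)
    se = np.sqrt(np.diag(cov))
    pvals = np.asarray(res.pvalues, float)  # invariant under pure scaling
    f_p = float(res.f_pvalue)
    rss = float(res.ssr)
    k_params = degree + 2
    gate = pvals if include_intercept_gate else pvals[1:]
    eligible = bool(f_p < alpha and np.all(gate < alpha))
    return FitCandidate(
        degree=degree,
        coefficients=np.asarray(coefficients, float),
        coefficient_se=np.asarray(se, float),
        coefficient_p=pvals,
        f_p=f_p,
        rss=rss,
        n=int(n),
        k_params=k_params,
        bic=float(_bic(rss, n, k_params)),
        eligible=eligible,
        cov=np.asarray(cov, float),
    )


def fit_constant(ages, values) -> FitCandidate:
    """Intercept-only fallback (degree 0): sample mean with its covariance."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    n = values.size
    if n < 2:
        raise FitError("need at least 2 points for the constant model")
    mean = float(values.mean())
    rss = float(np.sum((values - mean) ** 2))
    sigma2 = rss / (n - 1)
    se = float(np.sqrt(sigma2 / n))
    t = mean / se if se > 0 else np.inf
    pval = 2.0 * stats.t.sf(abs(t), n - 1)
    return FitCandidate(
        degree=0,
        coefficients=np.array([mean]),
        coefficient_se=np.array([se]),
        coefficient_p=np.array([pval]),
        f_p=float("nan"),
        rss=rss,
        n=int(n),
        k_params=2,
        bic=float(_bic(rss, n, 2)),
        eligible=False,
        cov=np.array([[sigma2 / n]]),
    )


def select_model(candidates: Sequence[FitCandidate]) -> FitCandidate | None:
    """Pick the lowest-BIC eligible candidate; ties go to the lower degree.

    Returns None when no candidate is eligible (callers fall back to the
    constant model).  Never returns an ineligible candidate.
    """
    eligible = [c for c in candidates if c.eligible]
    if not eligible:
        return None
    return min(eligible, key=lambda c: (c.bic, c.degree))


@dataclass
class TrajectoryModel:
    """The selected lifespan model for one structure in one group."""

    structure_name: str
    group: str
    selected: FitCandidate
    age_min: float
    age_max: float
    design_note: str = ""

    @property
    def degree(self) -> int:
        return self.selected.degree

    @property
    def training_n(self) -> int:
        return self.selected.n

    @property
    def df_resid(self) -> int:
        # standard OLS residual df: n minus number of regression coefficients
        return self.selected.n - (self.selected.degree + 1)

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.selected.rss / self.df_resid))

    def predict(self, ages) -> np.ndarray:
        ages = np.asarray(ages, float)
        return np.polynomial.polynomial.polyval(ages, self.selected.coefficients)

    def mean_se(self, ages) -> np.ndarray:
        """Standard error of the fitted mean curve at each age."""
        ages = np.atleast_1d(np.asarray(ages, float))
        X = np.vander(ages, self.selected.degree + 1, increasing=True)
        var = np.einsum("ij,jk,ik->i", X, self.selected.cov, X)
        return np.sqrt(np.maximum(var, 0.0))

    def to_dict(self) -> dict:
        c = self.selected
        return {
            "structure_name": self.structure_name,
            "group": self.group,
            "degree": c.degree,
            "coefficients": c.coefficients.tolist(),
            "coefficient_se": c.coefficient_se.tolist(),
            "coefficient_p": c.coefficient_p.tolist(),
            "cov": c.cov.tolist(),
            "f_p": c.f_p,
            "rss": c.rss,
            "n": c.n,
            "k_params": c.k_params,
            "bic": c.bic,
            "eligible": c.eligible,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "design_note": self.design_note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModel":
        cand = FitCandidate(
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], float),
            coefficient_se=np.asarray(d["coefficient_se"], float),
            coefficient_p=np.asarray(d["coefficient_p"], float),
            f_p=float(d["f_p"]) if d["f_p"] is not None else float("nan"),
            rss=float(d["rss"]),
            n=int(d["n"]),
            k_params=int(d["k_params"]),
            bic=float(d["bic"]),
            eligible=bool(d["eligible"]),
            cov=np.asarray(d["cov"], float),
        )
        return cls(
            structure_name=d["structure_name"],
            group=d["group"],
            selected=cand,
            age_min=float(d["age_min"]),
            age_max=float(d["age_max"]),
            design_note=d.get("design_note", ""),
        )


def fit_trajectory(
    ages,
    values,
    structure_name: str = "",
    group: str = "control",
    degrees: Sequence[int] = CANDIDATE_DEGREES,
    alpha: float = 0.05,
    include_intercept_gate: bool = False,
    design_note: str = "",
) -> TrajectoryModel:
    """Fit all candidate degrees, gate, select by BIC, fall back to constant."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    candidates = [
        fit_polynomial(ages, values, d, alpha=alpha,
                       include_intercept_gate=include_intercept_gate)
        for d in degrees
    ]
    best = select_model(candidates)
    if best is None:
        best = fit_constant(ages, values)
    return TrajectoryModel(
        structure_name=structure_name,
        group=group,
        selected=best,
        age_min=float(ages.min()),
        age_max=float(ages.max()),
        design_note=design_note,
    )


# ---------------------------------------------------------------------------
# confidence bands
# ---------------------------------------------------------------------------

@dataclass
class Band:
    """Pointwise two-sided band around a fitted trajectory on an age grid."""

    ages: np.ndarray
    lower: np.ndarray
    mean: np.ndarray
    upper: np.ndarray
    level: float
    mode: str


def confidence_band(
    model: TrajectoryModel,
    age_grid,
    level: float = 0.95,
    mode: str = "mean",
    extrapolation: float = 0.0,
) -> Band:
    """Pointwise band for the trajectory at the given confidence level.

    mode='mean' (default) gives confidence bounds for the mean curve:
    fitted value +/- t_{df,(1+level)/2} * SE(mean at age); mode='observation'
    additionally folds in the residual SD, bounding a new observation.
    The grid must stay within [age_min - extrapolation, age_max +
    extrapolation] of the training ages; extrapolation is off by default.
    """
    if mode not in ("mean", "observation"):
        raise ValueError(f"unknown band mode {mode!r}")
    grid = np.atleast_1d(np.asarray(age_grid, float))
    lo, hi = model.age_min - extrapolation, model.age_max + extrapolation
    outside = grid[(grid < lo) | (grid > hi)]
    if outside.size:
        raise ValueError(
            f"{model.structure_name or 'model'} ({model.group}): grid ages outside "
            f"allowed window [{lo:g}, {hi:g}]: {np.round(outside, 3).tolist()[:10]}"
        )
    mean = model.predict(grid)
    se = model.mean_se(grid)
    if mode == "observation":
        se = np.sqrt(se**2 + model.residual_sd**2)
    tq = stats.t.ppf(0.5 + level / 2.0, model.df_resid)
    half = tq * se
    return Band(ages=grid, lower=mean - half, mean=mean, upper=mean + half,
                level=level, mode=mode)


def default_age_grid(age_min: float, age_max: float, step: float = 0.5) -> np.ndarray:
    """Half-year grid from age_min to age_max inclusive (within float rounding)."""
    n = int(np.floor((age_max - age_min) / step + 1e-9)) + 1
    return age_min + step * np.arange(n)


def save_models(models: Sequence[TrajectoryModel], path: str | Path) -> None:
    """Serialize fitted models to JSON so downstream stages need no refit."""
    payload = [m.to_dict() for m in models]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_models(path: str | Path) -> list[TrajectoryModel]:
    return [TrajectoryModel.from_dict(d) for d in json.loads(Path(path).read_text())]
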