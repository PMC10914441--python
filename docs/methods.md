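# Methods

## Model and assumptions

`brainstages` models the volume of each brain structure as a smooth
function of age over the whole lifespan, separately for healthy controls
and for a disease group, and reads disease progression off the divergence
between the two curves.

The analysed quantity is the z-score of the TIV-normalized volume,
`z = (100·volume/TIV − μ_ref) / σ_ref`, where the reference statistics
μ_ref, σ_ref are computed per structure over all controls across the
lifespan. Using controls as the reference keeps the healthy chart centred
and makes patient z-scores directly interpretable as deviation from
normal; the reference population is configurable.

Trajectories are ordinary least-squares polynomials in age of degree 1–3,
fitted from the simplest to the most complex. A candidate degree is
eligible only when (i) the F test against the intercept-only model is
significant at P < 0.05 and (ii) every non-intercept coefficient passes a
two-sided t test at P < 0.05; among eligible candidates the one with the
lowest BIC is selected, ties going to the lower degree, and the
intercept-only model (degree 0) is the fallback when nothing is eligible.
The intercept is excluded from gate (ii) by default because on z-scored
data it is a location, not a shape, parameter; requiring its significance
would spuriously reject well-centred trajectories (a flag restores the
stricter gate). BIC is computed under the Gaussian likelihood as
`n·ln(RSS/n) + k·ln(n)` with `k = degree + 2`, counting the intercept and
the residual variance; any affine-equivalent variant would rank candidates
identically.

Three substantive assumptions are inherited from the underlying staging
approach:

1. **Continuity of neurodegeneration.** The disease trajectory coincides
   with the healthy one before disease onset. Operationally, the disease
   model is trained on all patients plus every control strictly younger
   than the youngest patient, which anchors it over the unobserved early
   life.
2. **Cross-section as surrogate for progression.** Older patients stand in
   for later disease; the models are functions of age, not of disease
   duration.
3. **Atrophy means "case smaller".** Only case-below-healthy divergence
   enters staging; case-above-healthy divergence is logged as an anomaly
   (it usually signals model misfit, e.g. an underfitted disease
   trajectory straightening out a concave decline).

## Divergence and staging

Both models are evaluated on a common age grid (default 0.5-year steps)
spanning the ages where *both* training sets have data. Pointwise
two-sided 95% confidence bounds for the mean curve are
`ŷ(a) ± t_{df,0.975}·SE(ŷ(a))`, with the standard error from the
coefficient covariance and df = n − (degree + 1). An observation-level
(prediction-interval) mode is available but not the default: the
divergence criterion compares the *models*, and new-observation intervals
would almost never separate at realistic patient sample sizes.

A structure diverges at the smallest grid age a\* such that the disease
upper bound stays below the healthy lower bound at every grid age ≥ a\*
(sustained separation; a "first crossing" rule is available). Confining
the scan to ages with training support on both sides avoids judging
non-overlap on extrapolated bands, which are artefacts of the polynomial
tails. Band non-overlap is deliberately conservative: whenever two 95%
intervals fail to overlap, the corresponding two-sided Welch comparison of
the fitted means rejects at the 5% level, which compensates for testing
many structures without an explicit multiplicity correction (the test
suite verifies the zero-exception property on 1000 random model pairs).

Severity is the signed difference of model *means* at a reference age
(default 90 years), which may extend up to `extrapolation_window`
(default 8) years past the last disease-training age — model means
extrapolate meaningfully where bands do not. Diverging structures are
ordered by onset (ties: larger severity first, then name) and merged into
stages when consecutive onsets are within `gap_threshold` (default
2 years) or when a structure shares an anatomical family (e.g.
putamen/caudate/accumbens = striatum) with a member of the current stage
within that threshold. The published stagings of this kind involve expert
judgment; the (grouping map, threshold) parameterization is an explicit,
reproducible stand-in, and both are recorded in every output.

## Synthetic cohorts

The generator emulates the data situation of multi-cohort lifespan
studies: several control cohorts with distinct, overlapping age windows
(paediatric through ageing, defaults spanning 1–100 years) and one patient
cohort confined to 55–86 years; ages uniform within each window; TIV
normal per cohort (truncated positive) so normalization is non-trivial;
symmetric structures emitted as left/right columns that sum to the
intended total. Disease kinetics are a hinge: cases follow the healthy
polynomial until a structure-specific onset age, then lose
`deviation_rate` z-units per year. Observation noise is homoscedastic
Gaussian in z-units (default 0.8 z), consistent with the pipeline's
normality check. Truth z-trajectories are mapped to raw mm³ through
per-structure reference statistics (`norm_mean`, `norm_sd`, in % of TIV),
which the truth table echoes so recovery tests can invert the mapping.

Presets: `psp_like_truths` (nine structures whose onset order, grouping
and distance-at-90 severities emulate the PSP-RS atrophy cascade:
ventral diencephalon first, thalamus most severe), `recovery_truths`
(eight structures, onsets 48–76 in 4-year steps, common rate 0.08 z/yr)
and `null_truths` (zero deviation, for false-positive control).

What the generator does **not** emulate: scanner/site effects beyond
cohort TIV differences, segmentation error, heteroscedastic or skewed
residuals, asymmetric atrophy, covariate structure (sex is carried through
but not modelled), and non-hinge deficit shapes. Passing recovery tests
therefore demonstrate correctness of the machinery under the stated
generative assumptions, not robustness to the full messiness of pooled
MRI data.

## Numerical choices

- Ages are rescaled internally by a fixed factor of 100 (pure scaling, no
  centering) so the cubic Vandermonde design stays well conditioned up to
  age 100; coefficients and covariance are reported in the raw-age basis
  via the exact diagonal transform, under which every t statistic, the F
  statistic, RSS and BIC are invariant. The fit agrees with an exact
  rational-arithmetic normal-equations oracle to better than 1e-10
  relative on all reported fields.
- Exact interpolation (RSS = 0) is guarded by a floor inside the BIC
  logarithm.
- The KS normality check standardizes each sample by its own mean/SD and
  compares against the standard normal (n ≥ 8 required; degenerate
  samples are flagged "untested"). Failures are logged and reported,
  never used to drop structures, since marginal non-normality is expected
  when a strong age trend is integrated over a wide age window.
- Model-based quality flags mark subjects whose residual exceeds 2
  residual SD; they are reported for human review and never auto-removed.
- Onsets are reported at grid precision; the grid origin is the youngest
  common training age.
- Outputs contain no timestamps, so reruns on identical inputs and
  configuration are byte-identical; the manifest records the config hash,
  seed and library versions.

## Known limitations

- **Early-onset bias.** Degree-≤3 polynomials cannot represent a hinge.
  The fitted disease curve starts bending below the healthy curve well
  before the true deficit onset, and with thousands of controls the
  healthy band is narrow, so band separation triggers early: in the
  20-seed recovery study at the default conditions the recovered onsets
  are systematically 8–15 years earlier than the true hinge ages (median
  absolute error ≈ 11 years), while the *ordering* of onsets is recovered
  reliably (Kendall tau ≥ 0.8 in all seeds). This is the same mechanism
  that lets the approach infer divergence before the youngest observed
  patient; recovered onset ages should be read as "age at which the
  models become statistically distinguishable", which precedes — and
  ranks like — the underlying biological onset. For the same reason a
  noise-free, large-sample limit does not drive the onset error to zero.
- The all-coefficients t gate interacts with the collinearity of raw age
  powers: on lifespan designs the cubic's lower-order coefficients often
  lose individual significance even when the cubic shape is real, so
  selected disease models are usually quadratic. This is inherent to
  gating on per-coefficient t tests in the raw basis.
- Severity distances at the reference age are attenuated relative to the
  generative hinge for the same smoothing reason; they are comparable
  across structures, which is what the ranking uses.
- Only age-only, single-population models are supported — no mixed
  effects, site harmonization, GAMs, or covariates.

## Problem sizes used in validation

The shipped validation suite uses cohorts of 2000 controls and 60 patients
(the canonical configuration for all stochastic checks), 200 replicates
for the null and degree-selection studies, 1000 refits for band
calibration, 1000 random model pairs for the conservativeness property and
20 seeds for the recovery study; these sizes make every property estimate
stable (binomial SEs well inside the asserted margins) while keeping the
full suite fast.
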