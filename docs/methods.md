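# Methods

## Statistical model

### AE variance components

For a per-subject scalar phenotype y (a connection's Fisher-z, an area's
thickness or volume), the model is

    y = Xβ + g + e,    Cov(y) = Ω = 2Φ σ²_g + I σ²_e,

where Φ is the kinship matrix of the twin cohort (2Φ = 1 for MZ co-twins,
0.5 for DZ co-twins, 0 between families, 1 on the diagonal), X is the fixed
covariate design (always including an intercept), and heritability is
h² = σ²_g / (σ²_g + σ²_e). Only additive genetic and unique-environment
components are modelled; a shared-environment (C) component is a deliberate
extension point, not implemented, because the covariance model above
contains exactly two variance terms.

**Fitting.** The covariance is block diagonal in families, so the
likelihood factorises over 2×2 blocks with within-pair correlation
ρ = h²·2φ. For a fixed h², the GLS covariate solution β̂(h²) and the total
variance σ̂²_p(h²) are available in closed form from per-zygosity-group
cross products, reducing the fit to a one-dimensional bounded optimisation
of the profile likelihood over h² ∈ [0, 1−10⁻⁶]. The profile is scanned on
a 26-point grid and refined by bounded Brent search around the grid
maximum (tolerance 10⁻⁸); this dominates a small fixed set of starting
values and is deterministic.

**REML.** The restricted likelihood is used by default (`reml=False`
recovers plain ML). With five fixed effects at n = 380, ML residuals lose
enough within-pair covariance to push clearly more than half of the null
LRT mass onto the boundary point (≈ 0.57 measured); REML restores the
asymptotic 50:50 behaviour and α-level rejection. REML likelihood-ratio
comparisons are valid here because the null (σ²_g = 0) and alternative
share the same fixed-effect design.

**Significance.** The statistic 2(L_e − L_0) against the σ²_g = 0 model is
referred to a 50:50 mixture of a point mass at zero and χ²₁, the boundary
asymptotics for a single variance component. A statistic of exactly zero
(below 10⁻⁸) is reported as p = 1, the conservative convention; some
packages report 0.5, available via `p_at_zero`. Confidence intervals are
profile-likelihood intervals at the χ²₁ cutoff, clipped to [0, 1].

**Preprocessing.** Connection phenotypes are rank-based inverse-normal
transformed (Blom constants, (r − 3/8)/(n + 1/4), average ranks for ties)
before fitting; anatomical phenotypes the same. Connection phenotypes use
covariates age, sex, mean framewise displacement and reconstruction
version; anatomical phenotypes use age and sex only.

### Connection screening

The group statistic per connection is the mean Fisher-z over subjects. Its
null distribution flips the sign of all members of a family jointly
(whole-block sign flips), which preserves within-family dependence while
testing the symmetric "no connectivity" null; p = (1 + #{|null| ≥
|obs|})/(n_perm + 1), with optional exhaustive enumeration of all 2^F flip
patterns for small cohorts. BH step-up FDR (default q = 0.05) selects the
kept-connection set used by every downstream per-area average.

### Reliability

ICC(3,1) — two-way mixed, single rater, consistency:
(BMS − EMS)/(BMS + EMS) for k = 2 session days; invariant to a constant
offset between days, undefined (error) when between-subject variance is
zero. The Mantel test correlates the off-diagonal entries of two symmetric
matrices restricted to the kept-connection mask (the mask belongs to the
analysis frame and is not permuted) and permutes row+column labels of the
second matrix jointly; 5000 permutations by default, exhaustive below 8
areas.

### Hierarchy

η(area) = shortest-path edge count to the hemisphere's V1 on the
area-adjacency graph (Dijkstra with unit weights; identical to BFS, which
is the test oracle). η(V1) = 0 by default; `level_offset` shifts the
convention. Levels are computed per hemisphere with that hemisphere's V1 as
root and are not merged across hemispheres.

### Gradient models

Per-area profiles average a connection-level quantity over the area's kept
connections (each connection contributes to both endpoints); areas with no
kept connection are excluded and logged. No distance correction is applied:
with full fingerprints the mean distance from an area to all others is the
same for every area. Fits are unweighted (per-area SEM is reported, not
used as weights).

Linear and quadratic OLS fits on η are compared by the partial F-ratio
F = (RSS₁ − RSS₂)/(RSS₂/(n−3)); a numerically zero RSS₂ maps to F = ∞,
p = 0. The early-visual test is the slope t-test of the linear fit
restricted to V1, V2v, V2d, V3v, V3d in both hemispheres (10 areas,
df = 8).

The two-component model h²(η) = h_max − a₁e^(−b₁η) − a₂e^(+b₂η) fixes
h_max (default 0.5, the assumed ceiling under measurement noise common to
all levels) and fits a₁, b₁, a₂, b₂ ≥ 0 by `least_squares` with soft-L1
loss (f_scale 0.05; plain least squares configurable) — "robust non-linear
least squares" names a family, and soft-L1 is the deterministic, smooth
member chosen here. Multi-start: all (b₁, b₂) pairs from {0.1, 0.5, 1, 2}²
with amplitudes initialised by non-negative linear least squares; best
final cost wins; R² is reported on raw residuals. Component-comparison
fits freeze the fitted component shapes and fit a single intercept
(β̂ = mean(y + c(η)) in closed form); AIC = n·ln(RSS/n) + 2k with k = 2,
and Akaike weights w_i = e^(−Δ_i/2)/Σe^(−Δ_j/2). Only AIC differences
matter, so the constant convention is harmless as long as it is applied to
both models, which it is.

## Synthetic cohorts

The generator emulates a young-adult twin imaging study:

- **Pedigree** — n_MZ + n_DZ families of exactly two; ages uniform on
  22–36 y and shared within a pair; MZ co-twins share sex, DZ sexes are
  independent; mean framewise displacement log-normal (median 0.12 mm,
  σ_log 0.35), independent across co-twins; a binary
  reconstruction-version indicator shared within a family. Defaults are
  123 MZ + 67 DZ pairs (380 subjects).
- **Phenotypes** — y = Xβ + u with u bivariate normal per family,
  variance σ²_p and within-pair covariance 2φ·h²·σ²_p, so empirical twin
  correlations are rMZ = h², rDZ = h²/2.
- **Time series** — multivariate Gaussian runs whose population
  correlation is the nearest positive-definite repair (eigenvalue clipping
  at 10⁻⁶, diagonal renormalised) of tanh(z_target); subjects needing a
  repair beyond a Frobenius tolerance are flagged. Motion regressors are
  12 columns (6 smoothed-noise parameters scaled by the subject's mean FD
  plus backward-difference derivatives, first row zero) and leak into the
  series so nuisance regression has something real to remove. Four runs of
  1200 time points by default, split 2+2 over session days.
- **Connection-level truth** — per-area target curves are mapped to
  per-connection h² by an exact affine construction
  (g = (h − H̄/(R−1))·(R−1)/(R−2); connection value g_i + g_j − H̄) whose
  per-area means reproduce the curve exactly. The default two-component
  truth (a₁, b₁, a₂, b₂, h_max) = (0.25, 1.5, 0.0085, 0.35, 0.5) is
  non-monotonic with its peak near η ≈ 2.5 on the packaged graph's 0–10
  level range and keeps every connection value inside [0, 1] (no
  clipping); the monotone alternative is 0.42 − 0.02η. Population mean
  Fisher-z per connection ~ N(0.30, 0.05²), between-subject variance 0.02,
  with a small negative mean-FD effect.
- **Anatomy** — per-area thickness/volume tables with a monotonically
  decreasing heritability profile 0.8 − 0.012·e^(0.35η).
- **Area graph** — a packaged 48-area fixture (24 per hemisphere, names
  from the standard retinotopic atlas vocabulary) with a plausible
  neighbour structure, connected within each hemisphere, V1 the designated
  root. The true atlas adjacency is not distributed with the package; real
  analyses must supply their own edge list.

What the generator does **not** emulate: physiological noise, scanner
drift, spatial autocorrelation, atlas misfit, shared-environment effects
and age-dependent heritability. Passing tests therefore validate the
statistical machinery — estimator bias and coverage, test calibration,
model selection — under the stated covariance model, not robustness to
fMRI artefacts.

## Problem sizes

Simulation studies use the full cohort size (123 + 67 pairs) throughout.
The end-to-end curvature studies use the 24-area single hemisphere (276
connections, 50 runs per generative profile) and skip the time-series
stage by generating connection tables directly — a supported input route —
since connectivity extraction is validated separately. The packaged demo
uses 40 + 20 pairs, 12 areas and 160-point runs so that the full
time-series route, including ICC and the Mantel control, runs in seconds.

## Known limitations

- Twin pairs only: no extended pedigrees, half-siblings or singletons in
  the kinship construction (singleton support in the likelihood exists but
  the pedigree validator requires pairs).
- AE only; no C/D components, no bivariate genetic correlations.
- The block-permutation statistic (mean z, whole-family sign flips) is one
  admissible choice of family-respecting scheme; the screening literature
  contains others.
- The two-component model's growing term is weakly identified at low
  noise-to-curvature ratios (a₂ and b₂ trade off); the fitted curve is
  stable (tested via curve RMSE) even when individual parameters are not.
- h_max is fixed, not estimated; profiles exceeding h_max force the
  nearest boundary fit.
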