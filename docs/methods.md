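# Methods

## Imaging conventions

Volumes are 3D arrays ordered `(x, y, z)` with the third axis axial; NIfTI
input is reoriented to closest-canonical (RAS) so this holds regardless of the
on-disk orientation, and NRRD input is transposed from SimpleITK's `(z, y, x)`
order. Spacing is `(dx, dy, dz)` in mm and must be present in the file
metadata — there is no default spacing, because every downstream quantity
(lung area, NC rate, ACS, ACA) carries physical units and a silently assumed
1 mm would corrupt them.

A voxel at 0-based index `i` has its physical centre at `(i + 0.5)·h`. Slice
point patterns use voxel *centres* (the corner convention would shift every
pattern by half a voxel relative to the rasterized window; centres keep
patterns and windows translation-consistent).

LAA masks are defined only inside the lung mask, with a strict inequality
(HU < −950): a voxel at exactly the threshold is not emphysema. Gas trapping
uses HU < −856 on expiratory scans. The slice filter for point-process
analysis counts *lung* voxels (≥ 100 by default), not LAA voxels: the filter
exists to exclude the unstable apical/basal slices where the observation
window itself is tiny, which is a property of the lung cross-section, not of
the disease burden.

## Cluster metrics

Connected components use face adjacency by default (6-neighbour in 3D),
matching the join definition; edge/corner connectivities are available and
recorded in every output. Adjacency is defined on the index lattice,
ignoring anisotropic spacing — a shared face is a join whether in-plane or
through-plane — which keeps 3D counts well defined and consistent with the
join-count construction. Joins crossing the lung boundary are not counted
(both endpoints must be lung), since out-of-lung air would inflate the
normal–normal class.

The power-law fit defaults to the discrete MLE (cluster sizes are integers):
α̂ maximises −n·ln ζ(α, x_min) − α·Σ ln sᵢ, solved by bounded scalar
optimisation on α ∈ (1, 30]. The continuous closed form
α̂ = 1 + n/Σ ln(sᵢ/x_min) is provided for cross-checks. x_min = 1 by default —
every cluster, singletons included, enters the fit — with an optional
KS-minimising x_min scan. The reported D uses the CCDF-slope convention
α − 1 by default because the empirical estimate it is compared against is the
negative slope of the log cumulative size distribution; the density
convention (D = α) is one flag away, and both values are always emitted. A
fit is flagged degenerate (D = NaN) when the tail has fewer than `min_tail`
(default 5) observations or fewer than two distinct sizes; goodness-of-fit
p-values (bootstrap KS) are out of scope.

## The shot-noise Cox process

Per slice, LAA voxel centres are one realization of an inhomogeneous Poisson
process on the lung window W with intensity
λ(x) = ε + Σⱼ wⱼ·φ(x; cⱼ, Σⱼ). The log-likelihood is
Σᵢ ln λ(xᵢ) − [ε|W| + Σⱼ wⱼ·mⱼ], where mⱼ is the Gaussian mass of cluster j
inside W. mⱼ is computed by mid-point quadrature over the window's voxel
grid (with a ±6σ bounding box); exact axis-aligned CDF products would be
wrong for non-rectangular lungs. At typical kernel scales (σ ≥ 2 voxel
widths) the quadrature agrees with a 0.1 mm Riemann sum to better than 1e−3
relative.

### Priors

The model's hierarchy requires priors the package must own:

- K ~ Poisson(5), truncated at K_max = 200. Weak; the likelihood dominates
  at realistic point counts.
- wⱼ ~ Gamma(shape 2, rate 2/w₀), with w₀ = n_points / max(K_init, 1) taken
  from the deterministic initialization. Prior mean w₀, so births propose
  clusters at the data's own scale.
- Σⱼ ~ inverse-Wishart(df 4, scale σ₀²·I), σ₀ = 2 × in-plane voxel size.
  Weak (df 4 is the minimum giving a finite mean for p = 2) and centred at
  small lesion scales.
- ε ~ Gamma(1, 1 mm²). The rate is deliberately tiny relative to any
  realistic window area, so the conditional mean is ≈ n_noise/|W| and the
  noise intensity is data-driven. A rate of |W| (one expected noise point per
  window) looks "weakly informative" but in fact adds a full window of
  pseudo-exposure: it halves the posterior noise intensity, drags %-Diffuse
  far below truth, and pushes the displaced noise points into spurious flat
  clusters. The vague rate removes that bias; simulation recovery of a 15%
  noise share is then within ~2 pp.

### Sampler

One sweep of the chain:

1. **Allocations.** By the Poisson superposition theorem the pattern is the
   union of independent sub-processes, so each point's component label is
   categorical with P(z = j) ∝ wⱼφⱼ(x) (noise ∝ ε).
2. **Conjugate Gibbs** for ε | n₀ ~ Gamma(a+n₀, b+|W|) and
   wⱼ | nⱼ ~ Gamma(a+nⱼ, b+mⱼ).
3. **Centres and kernels** by independence Metropolis–Hastings with conjugate
   proposals: cⱼ* ~ N(x̄ⱼ, Σⱼ/nⱼ) and Σⱼ* ~ IW(ν+nⱼ, Ψ+Sⱼ). Because the
   proposal equals the full conditional apart from window truncation, the
   acceptance probability collapses to exp(−wⱼ·Δmⱼ) (and the in-window
   indicator for centres). Empty clusters propose from the prior.
4. **Birth–death** (2 proposals per sweep): a birth draws the centre uniform
   on the window and marks from their priors, so the Hastings ratio reduces
   to the likelihood ratio times λ_K/(K+1); death is uniform over clusters
   with the reciprocal ratio. Per-cluster point densities and masses are
   cached so each move costs one vector operation.

Defaults: 5,000 iterations, 2,000 burn-in, thinning 5, all configurable;
acceptance counters are stored with the posterior. The chain is driven by a
single `numpy` Generator: identical seed ⇒ bit-identical draws. A
`prior_only` mode holds the likelihood constant, which must (and does, in
tests) return the truncated-Poisson prior for K — a direct correctness check
of the birth–death balance.

Initialization is deterministic: points are rasterized onto the window grid,
face-connected components with ≥ 5 cells become initial clusters (centroid,
sample covariance), remaining points set the initial ε. This puts the chain
near the mode without any stochastic preprocessing.

### Summaries

Per draw: NC = K/(lung area in cm²)·100; ACS = mean(wⱼ)·voxel area;
%-Diffuse = 100·ε|W|/(ε|W| + Σ wⱼmⱼ) — a smooth posterior functional of the
expected point share of the noise component, not a hard per-point
classification; ACA = mean(π·χ²₂(0.90)·√det Σⱼ). Reported values are
posterior means; draws with K = 0 are excluded from the ACS/ACA means only
(%-Diffuse is 100 there, NC counts the zero). Subject-level values are
unweighted means across analysed slices ("per-slice then average", matching
the slice-wise estimation strategy); empty-pattern slices contribute zeros to
NC and are excluded from ACS/ACA means. ACS uses the posterior expected
points per cluster wⱼ rather than a partition of the observed points — it is
the model parameter with the cleaner interpretation and no label-switching
sensitivity (all summaries are symmetric in cluster labels by construction).

## Synthetic data

The generator exists because linked CT/outcome/proteomic cohorts are
restricted. It emulates the *structure* the analysis assumes, not real lungs:

- **Patterns** come from the generative side of the fitted model itself
  (uniform Poisson noise + truncated-Gaussian clusters), so fitting them back
  is a genuine parameter-recovery test.
- **Windows** are ellipses (analytic area, trivial rasterization) rather
  than lung contours; **rasterized volumes** have piecewise-uniform HU chosen
  only to make thresholding exact — no texture, airways, vessels or scanner
  noise. Passing tests therefore demonstrate correctness of the estimators
  under the model's own assumptions, not robustness to real-lung deviations
  from them.
- **Cohorts** (default n = 300) draw three latent factors per subject:
  burden `s` (enters every metric), a shared clustering factor `g` (NJC, D,
  %-Diffuse, ACA, and partly ACS/NC), and a point-process-specific factor `h`
  carried only by ACS and NC. `h` encodes the scientific claim under test —
  that the point-process summaries hold spatial information unavailable to
  %LAA/NJC/D. Metric scales are calibrated to typical COPD-cohort values
  (%LAA ≈ 10, D ≈ 1.7, ACS ≈ 20 mm², NC ≈ 17 per 100 cm², %-Diffuse ≈ 29,
  ACA ≈ 60 mm²) and reproduce the expected correlation signs (%LAA–NJC > 0,
  %LAA–D < 0, %LAA–ACS > 0). Outcomes are linear in z-scaled log metrics
  with Gaussian noise, routed dominantly through ACS with a secondary D term;
  the absolute coefficient scales are placeholders giving R² broadly in
  0.2–0.8, clearly labelled in `CohortSpec`. Visual assessment is a 6-level
  ordinal discretization of noisy log-ACS; biomarkers are lognormal with
  effects routed through `s`, `g` or `h` and LLOQ thresholds set at target
  censoring quantiles.

## Association pipeline

- Metrics are natural-log transformed (they are strongly right-skewed) and
  centred/scaled; a zero-handling offset of half the smallest positive value
  is applied and recorded only when needed.
- Univariate models: OLS of each outcome on one z-scaled metric plus the
  demographic covariates; the metric coefficient is the standardized
  coefficient reported.
- Ridge models penalize all slopes but never the intercept (removed by
  centring; predictors standardized first). The ridge parameter comes from
  the Kibria/Muniz family computed in the canonical (SVD-rotated) form —
  Hoerl–Kennard, Hoerl–Kennard–Baldwin, and the arithmetic-mean,
  geometric-mean (default) and median forms of σ̂²/α̂ᵢ². The exact published
  estimator behind any given acronym varies across software, so the method
  tag is stored in every result. Standard errors use the sandwich form
  σ̂²(XᵀX+kI)⁻¹XᵀX(XᵀX+kI)⁻¹; adjusted R² uses the raw predictor count (not
  effective degrees of freedom) — the simplest defensible choice, recorded
  as such. In adjusted-R² comparisons the reduced model re-estimates its own
  k.
- LRTs use the Gaussian ML statistic n·ln(RSS_r/RSS_f) (deviance difference
  for logistic models) against χ² with df = parameter-count difference;
  visual-assessment categories are treatment-coded (reference "absent"),
  giving 5 df for the 6-level and 2 df for the 3-level scale.
- Biomarker preprocessing: below-LLOQ fraction > 0.95 ⇒ excluded;
  ∈ (0.10, 0.95] ⇒ binary present/absent; otherwise the empirical normal
  quantile transform Φ⁻¹((rank − 0.5)/n) with average ranks for ties and
  below-LLOQ values ranked lowest (rank-based handling makes any sub-LLOQ
  imputation constant equivalent).
- The EHP scan fits base (covariates + %LAA), base+EHP2 and base+EHP4 per
  marker and BH-adjusts the EHP2 and EHP4 p-value columns separately (they
  are reported as separate scans); complete-case rows per model, with n
  recorded.

## Problem sizes and numerical choices

Validation uses deliberately desk-scale problems: lattice oracles on masks up
to 20×20×10 against pure-Python union-find and pair enumeration; MLE oracles
against closed forms (1e−10) and exhaustive grid search (1e−4); likelihood
quadrature against a 0.1 mm Riemann sum (1e−3 relative); parameter recovery
on twenty 60×60 mm slices at truth K = 4, w = 150, σ = 3 mm, 15% noise with
5,000-iteration chains; and cohort-level directional checks on replicate
300-subject cohorts. Ties in discrete optimisation are resolved
deterministically (raster-order labelling, first-maximum argmax); degenerate
inputs (empty masks, empty patterns, all-equal sizes, all-K=0 posteriors)
return flagged results rather than raising wherever a flagged value is
representable.

## Known limitations

- Point-process fitting is 2D per slice; the model generalises to 3D but a
  full-lung 3D pattern has orders of magnitude more points and is out of
  scope here.
- No convergence machinery beyond acceptance counters and the prior-recovery
  check; chains on unusually multimodal slices may need longer runs.
- The power-law stage provides no goodness-of-fit test, and the percolation
  ("super cluster") behaviour of high-burden 3D masks is not modelled.
- The synthetic cohort reproduces relational structure, not the marginal
  distributions of any real population; absolute effect sizes in it are
  conventional placeholders.
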