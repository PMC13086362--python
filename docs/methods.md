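# Methods

This note documents the statistical procedures implemented in `paleoherd`,
the defaults they ship with, the synthetic data they are validated on, and
the choices made where the methodology was genuinely open.

## Seasonal cosine model (`paleoherd.seqmodel`)

### Model

The default intra-tooth δ¹⁸O model is the plain seasonal cosine

δ¹⁸O(x) = A·cos(2π(x − x₀)/X) + M

with `x` the distance from the enamel-root junction (mm), `X` the crown
length formed over one annual cycle (mm), `A` the amplitude (‰, half of
the max–min range), `M` the mean (‰) and `x₀` the position of the δ¹⁸O
maximum, folded into [0, X).  Two extensions are available behind the
`model` flag and are off by default:

- `drift`: an additive linear trend `p·x` (‰/mm), for sequences with a
  superimposed baseline shift;
- `damped`: an exponential amplitude envelope `A·e^{(x − X_B)/X_A}` with
  `X_B` pinned at the occlusal end and `X_A` (mm) fitted, representing
  attenuation of the seasonal signal toward the ERJ.

The plain cosine is the default because its four parameters are the ones
with unambiguous physical meaning; the extended terms are descriptive
conveniences, not a mineralisation forward model (no time-lag
deconvolution is attempted — a deliberate non-goal).

### Fitting

Sinusoid least squares is multimodal in phase and period, so the fit is a
deterministic two-stage procedure:

1. **Period profiling.** For any fixed `X` the model is linear in
   (A·cosφ₀, A·sinφ₀, M[, p]), so the profile SSE is evaluated exactly on
   a 200-point grid of `X` spanning [0.5, 2] × the sampled span.
2. **Polish.** The best grid point seeds a bounded trust-region
   (`scipy.optimize.least_squares`, TRF) refinement of all parameters,
   with A ∈ (0, 4×half-range], X within the grid bounds, and x₀
   unconstrained up to folding.

No random starts are involved; fits are bit-reproducible.  `rmse` is
√(SSE/n); `converged` reports the optimiser's own success flag.  Shifting
all distances by a constant shifts `x₀` by the same constant (mod X) and
leaves A, X, M and rmse unchanged (tested).

### Screening

Screening rules mirror standard practice — sequences are excluded for very
low amplitude, absence of a sinusoidal pattern, absence of a clear
maximum, or a missing ERJ — with these defaults (config-exposed, since the
field convention names the rules but not the numbers):

- `min_range` = 2.0‰: below this δ¹⁸O range a sequence is "low amplitude";
- `precision` = 0.12‰ (the 1 s.d. analytical precision of enamel δ¹⁸O): a
  *clear* extremum must be interior, with the series moving at least this
  far away from it on **both** sides.  The side-descent formulation is
  used instead of an adjacent-neighbour comparison because with fine
  sampling the two samples flanking a true optimum differ by less than
  analytical precision even for perfect cosines;
- a missing clear **minimum** does not exclude a sequence; it flags the
  downstream birth-season estimate as *tentative* (the maximum is then
  constrained from one side only).  Only a missing maximum excludes,
  because `x₀` is defined by the maximum;
- `max_mean_crossings` = 4: a ≤1.5-cycle annual record crosses its mean at
  most ~3 times; sequences crossing more (after a hysteresis filter of
  max(precision, 10% of the range)) are "not sinusoidal".  This is a
  heuristic with deliberately low power against smooth noise; its job is
  to reject obviously aperiodic series, not to be a periodicity test.

### Birth-season bands

`x₀/X` is classified circularly against named bands.  **The shipped
default bands are approximate, synthetic placeholders** (spring
0.30–0.52, summer 0.55–0.70, autumn 0.72–0.90, winter 0.95–0.25,
provenance `"approximate-synthetic"`): they are ordered and spaced
consistently with modern herds of known birth season (lower ratios in
spring, higher in autumn) but are *not* transcribed from any published
reference set, because those sources are external publications.  Analyses
intended for publication must supply bands transcribed from modern
reference populations appropriate to the region and species.  Values
falling in band gaps, or in more than one band, return `ambiguous`.

## Phase-shift model (`fit_phase_shift`)

Paired series are modelled as `A·sin(2πd/D + Ψ) + M` for each isotope with
one shared period `D`; the phase shift is `(Ψ_C − Ψ_O) mod 2π` in degrees.
For fixed `D` everything else is linear (per-isotope sin/cos coefficients
plus one mean per specimen), so `D` is profiled on a 400-point grid over
[0.5, 2] × span and polished with bounded scalar minimisation; amplitudes
and phases come from the final linear solve.  Pooling over a pattern
group shares `D`, amplitudes and phases and frees per-specimen means;
residuals of all specimens are concatenated.  A fitted amplitude below
`min_amplitude` (default 0.05‰) raises "no periodic signal" — a phase is
meaningless for a flat series.

Measured single-specimen precision at realistic sampling (31 increments,
noise 0.2‰, A_C 1.5‰) is ≈2° (1 s.d.); pooled 4-specimen groups reach
≈1°.  The recovery study in the acceptance script therefore uses pooled
4-specimen groups, matching how per-pattern angles are estimated in
practice.

## Diet mixing (`paleoherd.dietmix`)

End-members are built from modern plant δ¹³C as
`plant mean + 1.5‰ (Suess) + tissue transform`, with the enamel transform
either plain addition of ε* = +14.1‰ (default) or the exact form
`(δ+1000)(1+ε/1000)−1000`; the two differ by <0.5‰ over plant values in
[−30, −10]‰ (tested, not hidden).  Plain addition is the default because
the shipped enamel end-members are exactly plant mean + 1.5 + 14.1.
Defaults: enamel −11.58 ± 3.00‰ / +4.18 ± 1.17‰; collagen −20.3‰ / −6.3‰;
collagen diet offset +5.0‰; water-stressed-C₃ enamel ceiling −6.7‰ (an
enamel value above it is flagged as beyond what pure C₃ can explain).
All are configuration, not constants.

%C₄ is the affine interpolation `100·(δ − C₃)/(C₄ − C₃)`, clipped to
[0, 100] with a `clipped` flag rather than an error, since analytical
noise legitimately pushes near-end-member samples past the ends.  The
inverse mapping is exact on the unclipped region (round-trip tested to
1e-9).

Seasonal diet summaries label each increment from the **fitted δ¹⁸O
phase** (within ±0.25 cycle of the modelled maximum = summer, else
winter), never from raw extremes, so a noisy single sample cannot
reassign a season.

## Collagen statistics (`paleoherd.collagen`)

- C:N atomic ratio `(%C/12.011)/(%N/14.007)`; QC window 2.9–3.6 with a
  1 wt% minimum yield (DeNiro-style preservation criteria;
  config-exposed).
- Summaries use the sample sd (n−1); sd is `None` at n=1 rather than 0.
- Correlation: Pearson (t-distribution p) and Spearman, plus optional
  seeded permutation p-values for small n.  Computed on QC-passing
  samples; IQR screening is applied only for ellipse construction, since
  outlier removal is a display convention, not an inference step.
- IQR outliers: single-pass Tukey fences at Q1 − 1.5·IQR / Q3 + 1.5·IQR
  with type-7 (linear-interpolation) quartiles — stated because the
  outlier set depends on the quartile convention.
- 95% confidence ellipse: sample mean and covariance scaled by
  χ²₂(0.95) = 5.991; returned as (center, semi-axes, rotation), no
  graphics.
- One-way ANOVA: classical F and p; an all-identical input returns
  (F=0, p=1) by convention, and zero within-group variance with distinct
  means returns (∞, 0).

## Mortality and taphonomy (`paleoherd.herdprof`)

The posterior over Payne-class proportions is Dirichlet(counts + prior),
flat prior 1 per class by default (Jeffreys ½ selectable) — chosen because
the credibility-interval convention in the zooarchaeological literature
does not pin the prior.  Fractional counts are allowed as weights for
mandibles split across adjacent wear classes.  Intervals are equal-tailed
quantiles of 10⁴ seeded Monte-Carlo draws by default; class marginals are
cross-checkable against analytic Beta(α_k, α₀−α_k) quantiles, and the
survivorship curve S(k) = 1 − Σ_{j≤k} p_j gets its intervals from the
same draws (monotone non-increasing in every draw by construction).
Frequentist calibration, measured over 1000 seeded multinomial replicates
(7 classes, N=200), is ~95% — inside the 93–97% band the method claims.

Taphonomy proportions are flagged/NISP with Wilson 95% intervals;
completeness is the mean per-specimen completeness fraction of astragali
(×100); MAU% is count/expected-per-skeleton scaled to the best-represented
element; the attrition test reports both Spearman and Pearson against
reference bone-mineral densities (captions rarely say which was used) and
verdicts "attrition" only on a significant **positive** rank correlation.

## ZooMS (`paleoherd.zooms`)

Processing semantics (all config-exposed, defaults in parentheses):

- baseline: a low percentile (25) of the intensity in each of 15 windows,
  linearly interpolated — a two-tunable reimplementation of the
  "precision / relative offset" style of GUI baseline tools, whose exact
  semantics are not published;
- smoothing: Savitzky–Golay, window 0.3 m/z converted to an odd point
  count (min 5), order 2, applied 2 cycles;
- noise: 1.4826·MAD of the first differences /√2 — a robust estimator of
  the raw white-noise sd that is immune to peaks and baseline curvature;
- picking: local maxima above a lenient pre-threshold, then a final cut
  requiring the 3-point apex mean to reach S/N ≥ 3.5 **and** a
  relative-height floor of 75‰ of the base peak.  The 3-point apex mean
  is used because the raw local maximum is upward-biased by noise
  selection; even so, detection within ~±1 S/N unit of the threshold is
  inherently stochastic (documented in the tests);
- centroids: parabolic apex interpolation on the smoothed profile
  (measured accuracy ≈0.03 Da at S/N 100, grid 0.25 Da);
- calling: nearest peak within ±0.5 Da (linear-mode accuracy) of each
  diagnostic COL1α2 757(+16) marker; Ovis iff only sheep markers match,
  Capra iff only goat markers, both → Ambiguous, neither → Indeterminate.
  The COL1α2 375 masses (1154/2028/2044) are reported as supporting
  evidence only and never decide a call, since their per-taxon assignment
  is not established.

## Synthetic data (`paleoherd.synth`)

One master seed fans out to per-object child generators via
`SeedSequence(entropy=seed, spawn_key=...)`, so datasets are
byte-reproducible and extensible without reshuffling.  What the
generators emulate, and what they do not:

- **teeth**: exact cosine + iid Gaussian analytical noise (default σ
  0.12–0.3‰); δ¹³C from a seasonal C₄-fraction sinusoid pushed through
  the enamel mixing equation, in phase opposition to δ¹⁸O.  *Not*
  emulated: enamel-maturation time averaging (which damps and lags real
  signals), within-season dietary switching, sampling-depth geometry
  errors.  Passing recovery tests therefore demonstrates estimator
  correctness under the stated model, not robustness to mineralisation
  physics;
- **collagen**: correlated bivariate normal (δ¹³C, δ¹⁵N), %C uniform in
  42–45%, C:N uniform in 3.15–3.35 (then %N derived), yields 1.1–11 wt%;
- **mortality**: one multinomial draw from supplied class probabilities;
- **spectra**: Gaussian peaks at the taxon's two diagnostic masses
  (height = S/N × noise sd) plus five shared collagen peptides (1.3×),
  widths scaling as m/z/3000, exponentially decaying baseline, white
  noise, 0.25 Da grid over 900–4000 m/z.  *Not* emulated: isotopic
  envelopes, detector saturation, calibration drift.

Study problem sizes used by the test-suite and the acceptance script:
15-increment teeth on a 28 mm crown (2 mm steps), 100-tooth recovery
ensembles, 4-specimen phase groups of 31 increments, 18-sample collagen
sets, 1000-replicate calibration runs with 2000 posterior draws each
(10⁴ draws for single profiles), 200-spectrum ZooMS batches.  These sizes
give stable statistics while any single study stays in the seconds range.

## Known limitations

- Season calls depend entirely on the reference bands; the shipped
  defaults are placeholders (above) and real analyses must override them.
- The screening heuristics (mean-crossing count in particular) are
  intentionally permissive; borderline sequences should be inspected.
- The two-end-member mixing model attributes *all* δ¹³C variation to the
  C₃/C₄ balance; water-stressed C₃ enrichment aliases into a few percent
  apparent C₄ (the enamel ceiling flag marks the extreme case).
- Pooled phase fits assume one shared period and phase per group; mixing
  heterogeneous groups in one pool produces an uninterpretable average
  (the pipeline accepts a grouping column for this reason).
- ZooMS calls rest on the 757(+16) markers alone; collagen preservation
  poor enough to suppress those peptides returns Indeterminate rather
  than a guess.
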