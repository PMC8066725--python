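# Methods

## Design and coding

The three study factors (flow rate, %B at the start and at the end of the
gradient) are coded so the low/center/high levels map to −1/0/+1; coded
levels are stored as exact integers, so the design identities (Σxᵢ = 0,
Σxᵢxⱼ = 0, Σxᵢ² = 8 per column for the 15-run design) hold in integer
arithmetic rather than to rounding error. The 3-factor Box–Behnken
geometry is produced by direct enumeration: the twelve edge midpoints in
factor-pair blocks (1,2), (1,3), (2,3), each block ordered
(−,−), (−,+), (+,−), (+,+), followed by the center replicates. The
executed run order of the original experiment is unknown ("random"), so
the deterministic block order is the default and a shuffle seed is
opt-in; reproducibility wins over realism here. The center-point count is
a parameter (default 3).

## Response-surface fitting

Each response is fitted by OLS to the full ten-term quadratic on coded
factors. No term pruning is done: the study reports full models, and on a
15-run design the full model leaves 5 residual degrees of freedom.
Fitting is always on coded units; natural-unit output is a display
transform. R² is reported unadjusted. A response with (numerically) zero
variance gets R² = 0 by convention, with a warning.

For the effect tests, each of the nine non-intercept terms is tested with
its partial sum of squares, SSⱼ = bⱼ²/[(X′X)⁻¹]ⱼⱼ, against the residual
mean square — equivalent to the square of the coefficient's t statistic
(verified against statsmodels in the tests). For the linear and
interaction columns of the BBD this equals the sequential SS
(bⱼ²·Σcolumn²); the three quadratic columns are mutually correlated after
centering, so their partial SS are *not* exactly additive — the exact
orthogonal decomposition of the total SS holds for the sequential
(type-I) ordering, which is what the property tests assert. No
lack-of-fit/pure-error partition is computed: the source study does not
report one, and with 5 residual df (2 of them pure error) the partition
is fragile.

A note on reproducing the published resolution models: the printed
run-time equation is recovered exactly (its responses are printed to
3 decimals), while the four resolution equations — printed from a fit on
unrounded data — deviate from any fit of the published 2-dp response
table by more than rounding can explain (up to 0.04 on a quadratic term;
the worst-case propagation of ±0.005 response rounding into any
coefficient is ±0.01). The package reports what the published table
implies and does not attempt to reconcile those equations.

## Desirability optimization

Individual desirabilities are one-sided ramps: for a maximized response,
d = 0 below the low anchor, 1 above the high anchor, and
((y−low)/(high−low))^s between (mirrored for minimization). Shape s
defaults to 1 (no curvature settings are documented for the original
study). Anchors default to the observed response min/max over the design
runs — the common package default, user-overridable. Impacts (weights)
enter as exponents in a weighted geometric mean normalized by the weight
sum; with equal weights this reduces to the plain geometric mean. The
study's impacts are 4/3/3/4 for the four resolutions and 5 for run time.

The optimizer evaluates D on a 51³ lattice over the coded cube
(vectorized; ~10⁵ points in well under a second), takes the first argmax
in row-major order (a deterministic tie-break), and polishes with
Nelder–Mead under box bounds, accepting the polished point only if it
does not decrease D. D is computed from model predictions, not from
interpolated data. The flow upper bound is data, not a constant: the
original instrument's pressure ceiling capped flow at 0.6 mL min⁻¹, and
the optimizer pins flow there because flow benefits every response.

## Peaks and figures of merit

Integration follows the manual "valley-to-valley" convention: the
boundary between consecutive apexes is the minimum-intensity sample
between them (trace ends for the outermost boundaries), the baseline
under a peak is the straight segment joining its boundary points, and the
area is the trapezoidal integral of the baseline-subtracted signal
clipped at zero (manual valley baselines never yield negative area).
The base width W_b is the boundary-to-boundary span; this choice is
deliberate because the published width column cannot be reconciled with
its printed resolutions under any single unit convention, so no code
path depends on reproducing that column. Peak detection requires strict
local maxima above a height threshold that also clear the same threshold
in topographic prominence (rejecting noise ripples on peak flanks), with
greedy thinning of apexes closer than a minimum separation (keep the
taller). Times are minutes throughout. The dead time t_M is a user input
(the study never prints one); it can be back-calculated from a known
retention factor as t_M = t_R/(1+k).

## Calibration

Neutral masses are the observed [M−H]⁻ m/z plus the proton mass
(1.00728 Da). Whether the original authors used monoisotopic or average
masses is immaterial at the printed precision (the ratios agree to
<0.01 %), so the m/z-derived value is the single source of truth.
Mass-ratio transfer scales the slope by (reference mass)/(target mass),
keeps the intercept (the published table prints one shared intercept),
and scales LOD/LOQ inversely; the transfer is an involution and conserves
slope×mass and LOD×slope. LOQ/LOD is exactly 10/3 when both derive from
the same noise figure. Quantification converts extract concentration to
mg per 10 g dry weight with the extraction geometry (default 25 mL
volumetric flask, 0.2 g lyophilized material); below-LOD results report 0
with a flag rather than a negative back-calculation.

## Validation statistics

CVs use the n−1 standard deviation over the mean, in percent, judged
against the 10 % AOAC limit. Robustness uses plain pairwise
pooled-variance two-tailed t-tests at α = 0.05 with *no* multiplicity
correction — matching the original analysis — and the report carries a
`multiplicity_correction: none` field as the caveat. Letters are the
maximal cliques of the non-significance graph ordered by earliest member,
which reproduces bridging patterns such as a / ab / b. A zero pooled
variance yields p = 1 for equal means and p = 0 otherwise.

## The synthetic-data generator

The simulator is deliberately phenomenological — the aim is a generator
whose qualitative laws match gradient reversed-phase behavior (retention
falls with flow, with either %B setting, and with temperature), not a
physical solvent-strength calibration. Closed forms, with defaults:

| quantity | form | default |
|---|---|---|
| dead time | t_M = V₀/flow | V₀ = 0.2 mL (t_M = 0.4 min at 0.5 mL min⁻¹) |
| retention | k_i = K₀·exp(h_i − ss_i·%B_start − se_i·%B_end)·c(T) | K₀ = 0.5 |
| temperature | c(T) = exp(E_T(1/T_K − 1/328.15 K)) | E_T = 800 K |
| peak width | σ_i = t_R,i/√N(flow), N = N_ref(flow/0.5)^0.6 | N_ref = 3000 plates |
| sampling | uniform 40 points s⁻¹ | |
| noise | Gaussian, σ = 10⁻³ × tallest amplitude | |

The seven default compounds stand in for the seven flavonols; their
h values put the center-point chromatogram at roughly 1.3–2.4 min in
elution order, and their per-compound solvent slopes (ss_i, se_i)
alternate around the trend. That alternation is the scientifically
load-bearing choice: strengthening either end of the gradient widens some
adjacent-pair gaps while shrinking others — the selectivity changes a
method developer actually exploits — and the two %B factors act through
*different* spacing patterns. Without it (a single composite eluent
strength), all responses depend on one linear combination of the two %B
factors, the desirability surface develops an exact ridge, and the
optimum along the ridge is decided by noise. The mild growth of plate
count with flow makes higher flow favourable to resolution as well as to
run time, mirroring sub-2-µm column behaviour, and forces the optimizer's
flow coordinate to the +1 bound just as in the real study.

The generated 15-run studies land inside plausibility windows spanning
the real experiment's observed ranges (run time 1.5–5 min, resolutions
0.5–8), and the full pipeline (simulate → detect → integrate → fit →
optimize) recovers the generator's noise-free optimum to within 0.15
coded units at the default noise level. All stochastic paths are
seed-deterministic; the case-study bundle records its constants, true
retention times and noise-free optimum in `truth.json`.

What the simulator does **not** emulate: gradient dwell/delay volume,
peak tailing or fronting, detector saturation, spectral (3-D PDA) data,
pressure limits, column aging, and retention-order crossings. Passing
tests on synthetic data therefore demonstrate the statistical machinery
(design, fitting, optimization, extraction) and not the chromatographic
physics of any particular column.

## Numerical choices

- OLS via `numpy.linalg.lstsq` on the exact integer-coded model matrix;
  rank is checked first and rank-deficient designs are rejected.
- Constant-response detection treats a total SS at the rounding noise
  floor of the data's magnitude as zero (a hard `== 0` comparison misses
  constants whose mean accumulates O(ε) error).
- The grid argmax uses the first maximum in row-major order; the polish
  result is clamped to the cube and accepted only on improvement, so the
  optimizer is deterministic and never worse than its lattice.
- Valley boundaries are chosen on raw samples (no smoothing); the first
  minimum between apexes wins ties by `argmin`'s first-occurrence rule.
- Acceptance-facing simulations use the 15-run design as-is; the largest
  Monte-Carlo loops in the test suite (type-I error calibration, slope
  sampling distributions) are vectorized and sized at 200–2000
  replicates, which puts Monte-Carlo error comfortably inside the
  asserted bands.

## Known limitations

- The quadratic model is a local approximation over the design cube;
  predictions outside |coded| ≤ 1 are flagged as extrapolation.
- Valley-to-valley widths make Rs of well-separated peaks saturate near 1
  (boundaries track spacing, not peak width); this mirrors the manual
  integration convention the method used, but σ-based widths would be
  preferable for physical resolution claims.
- Desirability anchors at observed min/max make the optimum depend on the
  realized design responses; with other anchor conventions the reported D
  value (though rarely the argmax) shifts.
- The robustness letters inherit the uncorrected pairwise-test behaviour:
  with three levels, the family-wise false-alarm rate is ≈14 %.
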