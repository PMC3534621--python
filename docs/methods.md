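# Methods

## The SGT statistic

A well's Start Growth Time is the first time its OD600 reaches a threshold,
defined operationally as the first read `i` with `od[i] >= threshold` whose
next `consecutive − 1` reads are also at or above the threshold. The
confirmation run resists isolated read spikes; a run truncated by the end of
the series still counts, because a culture that ends above threshold has
unambiguously crossed it. The reported SGT is linearly interpolated between
the reads bracketing the crossing, which is strictly finer than the read
cadence and reduces to read-resolution behaviour on coarse grids. If the
first read is already at the threshold, SGT is the first read time
(uninterpolated). If the threshold is never reached, the result is
*censored*: it carries the last read time as a lower bound plus a flag, and
every downstream operation propagates the flag instead of manufacturing a
number.

Defaults: threshold 0.15 OD600 (low end of the conventional 0.15–0.2 band,
slightly above typical background at the start of log phase; configurable),
`consecutive = 2`, no smoothing (a window-3 moving median is available
behind a flag). Blank correction subtracts the per-timepoint median of
blank wells when the plate map defines any, does not clip at zero, and
refuses to run twice on the same curve; whether raw or blank-corrected ODs
are thresholded is an explicit user choice, and the interpolated-crossing
semantics keep results insensitive to it as long as the threshold sits
well above background either way.

## The relative-survival calculus

ΔSGT = SGT_treated − SGT_normalizer pairs each treated culture with an
untreated aliquot of itself diluted by the same factor, cancelling the
dilution and any shared condition effects. ΔΔSGT = ΔSGT_sample −
ΔSGT_calibrator references everything to one strain/condition, and relative
survival is 2^−ΔΔSGT — the ΔΔCt construction with SGT in place of Ct.

Units of the exponent are a genuine design fork: 2^−ΔΔSGT is a true
cell-count ratio only if ΔΔSGT is measured in doublings. `paper` mode (the
default) exponentiates hours verbatim; `doublings` mode divides by a
user-supplied doubling time first. The mode is recorded in every output row.
The doubling time can be estimated per well by OLS of ln(OD) on time over
the OD window [threshold, 4×threshold] (t_d = ln2/slope), or taken from the
calibration slope.

Replicate aggregation uses the sample sd (n−1); a single replicate reports
sd as missing rather than 0. Uncertainties propagate in quadrature
(sd_Δ = √(sd_t² + sd_n²), likewise for ΔΔ), the qPCR convention; the fold's
sd uses the delta method, sd_F = F·ln2·sd_ΔΔ. These sds describe replicate
spread, not standard errors of the mean — they do not shrink with
replication, while the estimate's seed-to-seed spread does.

## Calibration

SGT is regressed on log10(CFU/mL) — concentration is the known quantity in
a calibration series — by ordinary least squares, requiring ≥ 3 points.
Inversion is analytic: N = 10^((SGT − intercept)/slope); the interval
propagates the residual sd through the inverse map on the log10 scale
(delta method, normal quantile; default 95 %). A bootstrap is deliberately
omitted: for ≥ 6-point series the delta method is adequate and cheap.
Extrapolation outside the fitted SGT range raises unless explicitly
requested, and a non-negative slope is rejected as unusable. One model is
valid per growth condition only: media that lengthen the lag phase shift
the intercept and would masquerade as lower inocula, so models are never
mixed across conditions.

## The simulator

The generator emulates a 96/384-well plate reader watching regrowth:

* logistic growth N(t) = K·n0·e^{rt′}/(K + n0(e^{rt′}−1)), r = ln2/t_d,
  t′ = t − lag, with the population held at n0 (dormant, not absent) during
  the lag; pure exponential growth is the K→∞ limit used by the closed-form
  oracles;
* linear optics OD = background + od_per_cell·N, with defaults
  od_per_cell = 2.0/4.07×10⁹ (OD 2.0 ≈ 4.07×10⁹ cells/mL), background 0.05;
* reader noise: lognormal multiplicative factor (CV 5 %) times the clean
  OD plus additive Gaussian noise (sd 0.005 OD) — stated assumptions, the
  reader's true noise model being unknown — sampled every 0.25 h;
* inoculum granularity: dilution-series wells below 1000 cells/mL draw an
  integer per-mL count from a Poisson law, which reproduces the large
  relative errors real plating shows at tens of cells/mL; persister wells
  with < ~1 expected surviving cell in the 0.2 mL well volume draw a
  Poisson count in the well and may come up sterile (flat at background,
  hence censored);
* kill experiments: normalizer wells regrow from n0/dilution, treated
  wells from n0·f/dilution after an optional awakening delay, f being the
  sample's persister fraction. The delay adds itself to ΔSGT — the
  awakening bias — and is surfaced, not corrected: the pipeline warns when
  a sample's treated and normalizer arms differ in post-threshold doubling
  time by more than 1.5× (configurable). A pure time shift with identical
  growth rate is undetectable from the curves alone.

Seeds are mandatory; identical parameters and seed give bit-identical
output.

What the simulator does *not* model: mechanistic kill kinetics during
antibiotic exposure, stochastic birth–death growth, diauxic/biphasic
curves, media-dependent lag phases, condensation or edge-well artefacts.
Tests passing on simulated plates therefore validate the statistical
machinery — linearity, inversion, error propagation, censoring — under the
stated generative assumptions, not the optics or physiology of any real
reader or strain.

## Numerical choices and problem sizes

Interpolated crossings are linear in time; on a Δt grid the error against
the exponential truth is O(Δt²·ln2/t_d), ~10⁻⁵ h at Δt = 0.01 h, which is
why grid-free identities (the dilution-shift law) are checked on fine
(0.001 h) grids. Flat segments exactly at the threshold resolve to the
confirming read. Validation studies are sized to run in seconds on one
CPU: 10 seeded 8-point calibration series, a 60-combination closed-form
grid, 100 seeded survival assays (4 samples × 2 arms × 3 wells), and 100
paired 40-vs-400 cells/mL replicates; medians over seeds are compared at
the tolerances the underlying noise supports.

## Known limitations

* `paper`-mode folds are unit-ambiguous by construction; use `doublings`
  mode when a true cell-count ratio is needed.
* Calibrations do not transfer across growth conditions, and nothing
  corrects cross-condition lag differences.
* Censored wells bound survival from above but are excluded from means;
  heavily censored designs need longer observation windows, not wider
  error bars.
* No weighted or robust regression; single outlying calibration points
  move the fit.
* The awakening-bias warning only detects growth-rate mismatch, not pure
  delays.
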