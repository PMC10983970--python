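# Methods

This note documents the models, conventions and numerical choices behind
`adhesioquant`, in the spirit of a methods supplement: what each stage
assumes, which parameters matter, and what the synthetic benchmarks do and
do not demonstrate about real microscopy data.

## Coordinates, units, conventions

Image indices are 0-based `(row, col)`; the physical position of a pixel is
`(index + 0.5) · pixel_size_um` (pixel-center convention).  Frames are
0-based with times `t = frame · Δt` seconds.  Track files store physical
positions in μm; speeds are always reported in μm/min regardless of the
acquisition interval.  Intensities are unsigned integers with the dtype
maximum (65535 for 16-bit) serving as the upper thresholding limit.  CSV
output uses 6 significant digits, making identical runs byte-identical.

## Punctae detection

A cell image is segmented by Otsu's automatic threshold; the mask is the
largest connected foreground component with interior holes filled.  Otsu is
used as the standard parameter-free bimodal splitter; the exact
auto-threshold variant of interactive toolchains is not uniquely defined, so
the threshold function is a configuration point rather than a hard-coded
constant.

In-cell statistics (MFI = mean fluorescence intensity, SD) are computed
**over mask pixels only**.  "Background removal" is realized as
exclusion-from-statistics rather than zero-filling: setting out-of-cell
pixels to zero would corrupt MFI/SD, while exclusion makes detection
provably invariant to anything outside the mask (a tested property).  For
the same reason a second auto-threshold pass after background removal is
subsumed by mask-restricted statistics: segment once, then measure within
the mask.  SD uses the sample (n−1) denominator, the measurement convention
of common image-analysis tools.

Candidate punctae pixels are in-mask pixels with intensity in
`[MFI + k·SD, bit_max]`, both bounds inclusive (interval-threshold
convention).  `k = 3` by default; `k = 2` is the documented variant for
markers with unusually high or low signal-to-noise.  Candidates are grouped
by 8-connectivity (particle-analysis default; 4-connectivity available) and
kept when their area `n_pixels · pixel_size²` lies within
`[0.02, 0.5] μm²` inclusive.  At the default 0.1 μm/px this means 2–50
pixels: a single hot pixel (0.01 μm²) is rejected as noise, and large
contiguous regions (e.g. the whole cell when SD ≈ 0) are rejected as
non-punctate.

### Colocalization

Channel-to-channel matching is object-based: punctae pairs sharing at least
one pixel are candidates, resolved to a one-to-one matching greedily by
descending overlap area with deterministic tie-breaking (ascending id
pairs).  This replaces a manual overlap call with a reproducible rule; a
minimum-overlap-fraction criterion (relative to the smaller punctum) is
available where incidental single-pixel contact should not count.  The
double-positive count is symmetric in the two channels (tested), and the
matching equals an exhaustive all-pairs enumeration oracle on random
layouts (acceptance-tested on 100 layouts).

## Migration analysis

**Linking.**  Per-frame centroids are linked frame-to-frame by greedy
nearest-neighbour assignment (ascending distance, each endpoint used once)
with links beyond 25 μm forbidden; track ends are then re-joined to later
track starts within 5 frames and 10 μm (gap closing).  These defaults are
the standard simple-LAP settings for amoeboid cell tracking.  Greedy
assignment approximates the LAP tracker well in collision-sparse scenes; a
full minimal-total-cost (Hungarian) frame-to-frame assignment is available
via `LinkParams(method="hungarian")`.  Merging/splitting costs are out of
scope.

**Speed.**  Track speed is the unweighted mean of per-step speeds
(Euclidean displacement over elapsed time) in μm/min.  Steps across a
closed gap contribute one displacement over the gapped interval.  Note the
estimator is upward-biased by localization noise (adding i.i.d. positional
noise never decreases the mean measured speed — a tested property), which
is why speeds from different imaging conditions should not be compared
naively.

**MSD.**  The mean square displacement is time-averaged per track over all
overlapping interval pairs at each lag `τ = n·Δt`, up to half the track
duration (longer lags have too few intervals and dominate the variance);
the ensemble curve is the unweighted mean of per-track MSDs at each lag.
This matches the convention of the standard spreadsheet MSD tool for cell
trajectories.  The implementation reproduces a brute-force all-pairs
computation exactly and the ballistic closed form `MSD(τ) = (vτ)²` to
machine precision.

**Chemotaxis gate.**  A data set is usable for chemotaxis comparisons when
at least 80 % of control tracks moved toward the source.  A track counts
"toward" iff the projection of its net displacement (last − first
position) on the gradient axis is strictly positive — the end-point
reading of a spider plot; zero net displacement counts against.  The
gradient axis defaults to +x and the gradient itself can be validated with
`gradient_profile` (mean column/row intensity plus least-squares slope).

## Adhesion lifetime analysis

Time-lapse stacks (default 750 ms interval) are background-suppressed with
a per-frame **3×3 white top-hat** (image minus its grayscale opening).
This suppresses flat and slowly varying background to ~0 while retaining
local bright features, which is the stated purpose of the proprietary
"regional maxima" kernel operation it stands in for; a strict
regional-maxima *labeling* would instead return a binary mask and discard
the intensity information needed downstream.

Punctae are detected per frame and linked into tracks (greedy
nearest-neighbour, default 5 px).  Quality filters replace manual curation:

- tracks touching the first or last frame are removed (censored kinetics);
- tracks shorter than **8 frames** are removed — at 750 ms this is the
  6 s minimum duration, using the `frames · Δt` duration convention;
- tracks that skip frames or whose pixel sets ever overlap another track
  are removed (merge/skip artifacts).

Each surviving trace is the per-frame mean intensity over the punctum's
pixels with the first-frame value subtracted, then smoothed with a
centered 5-frame running average (windows truncate at the boundaries, so
trace length is preserved and the output never leaves the input range).

**Fitting.**  The smoothed trace is split at its maximum sample
(`t_peak`).  Assembly samples (up to and including the peak) are fitted
with the logistic `A/(1+e^{−r(t−t₀)})`; disassembly samples are fitted
with `A_d·e^{−k(t−t_peak)}`.  Initialization is deterministic and
derivative-free: `A` from the trace maximum, `t₀` from the first
half-maximum crossing, `r = ln(81)/(t₉₀ − t₁₀)` from the empirical
10–90 % rise, and `k` from a log-linear fit of the positive tail; bounded
least squares (`scipy.optimize.least_squares`, tolerances 1e-12) does the
rest.  The fits are time-shift equivariant and amplitude-scale equivariant
to optimizer precision (tested at 1e-6).

Two sample-selection details matter numerically.  First, the peak sample
itself lies at the junction of the two regimes; including it in the decay
fit biases `k` whenever the plateau-to-decay transition is sharp, so the
decay fit drops it when at least three later samples exist.  Second, after
a width-`w` running average, samples whose window straddles the junction
(up to a full window past the smoothed argmax, which can itself sit half a
window early) and the truncated-window samples at the trace end are
mixtures of the two regimes; the decay fit excludes both pads when enough
pure-decay samples remain, and falls back to the peak-inclusive fit for
short branches.  With these rules, noiseless synthetic traces are
recovered exactly and 5 %-noise traces give median errors ≈ 1 % (t₀) and
≈ 5 % (k) over 100 seeds.

**Lifetime.**  `t_half,asm = t₀` (logistic midpoint) and
`t_half,dis = t_peak + ln2/k`.  The default lifetime is the interval
`t_half,dis − t_half,asm` — the time the adhesion spends above half
assembly on one side and above half disassembly on the other; a sum
variant `(t₀ − t_start) + ln2/k` is available via
`lifetime_mode="sum"`, since "based on the t-half of both fits" admits
either reading and only the interval has a direct time-axis meaning.
Monotone traces (argmax at an endpoint) flag the missing branch as not
converged and report no lifetime.

Baseline subtraction (first-frame value) is part of the stack pipeline,
where frame one carries a true background level.  The trace-level
parameter-recovery benchmarks fit generated traces directly: the synthetic
model's baseline is exactly zero by construction, and subtracting a purely
stochastic first sample would inject an offset that the offset-free
exponential cannot absorb — a property of the benchmark, not of real
data.

## Bulk assays

**Spreading area** is `mask pixel count · pixel_size²`; masks are inputs
(machine-learned cell classification is out of scope).

**Detachment.**  Counts are referenced to the post-wash count N₀;
`pct_i = 100·(N₀ − N_i)/N₀` is cumulative per flow interval.  Counts
exceeding N₀ (cells drifting into view) are flagged and clamped with a
warning rather than silently accepted.

**Rear/front ratio.**  The cell is split by the line through its mask
centroid perpendicular to the instantaneous migration direction; the ratio
is mean in-mask intensity (rear) over mean in-mask intensity (front).
Pixels exactly on the divider belong to neither half, so reversing the
axis inverts the ratio exactly.  The half-plane split is the minimal
assumption; a thirds variant (leading/trailing thirds of the extent,
middle excluded) is available where a sharper polarity contrast is wanted.
The axis is undefined (error) for displacement below ε.

## ROUT outlier identification

Group measurements are univariate, so the robust "curve" is a constant:
the center is a Lorentzian-loss M-estimate computed by iteratively
reweighted averaging (`w = 1/(1+(res/RSDR)²)`), initialized at the median.
The robust scale RSDR is the 68.27th percentile of absolute residuals
times `n/(n−K)` with K = 1.  Residuals are then tested largest-first with
`t = |res|/RSDR` (df = n−1) against stepwise two-sided levels
`α_i = Q·(n−i+1)/n`; flagging stops at the first non-significant rank, so
the flag set is always a suffix of the residual-magnitude ordering, and is
capped at 30 % of the sample.  Q (default 1 %) is the maximum desired
false-discovery rate among flagged points.  Behaviour at the defaults: a
planted 15σ outlier in n = 20 is flagged in 100/100 seeds, while clean
normal samples of n = 1000 lose ≈ 1 % of points on average.

Small-sample critical-value interpolations of the commercial
implementation are proprietary; equivalence is asserted against the
published recipe (an independent step-by-step implementation serves as the
test oracle), not against the tool.

Groups in which more than half the values are exactly zero are never
outlier-filtered in `group_summary` — a heavy spike at zero is structure
(cells with no punctae at all), not contamination.  Standard hypothesis
tests (normality batteries, omnibus comparisons) are deliberately
delegated to scipy/statsmodels and not re-implemented.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis assumes:

- **Images** — one elliptical cell with a cytoplasmic offset over a noisy
  background, containing near-diffraction-limit Gaussian spots (σ 1–2 px,
  evaluated at pixel centers without supersampling — detection needs
  thresholded blobs, not PSF-accurate profiles) placed inside the cell
  with a minimum pairwise separation, rejection-sampled with a bounded
  retry budget.  Gaussian read noise by default; Poisson shot noise on the
  expected image as the alternative.  Defaults (16-bit, 200×200 px,
  0.1 μm/px, background 200 ± 20 counts, in-cell offset +300, spot
  amplitude 600) are fixtures chosen to resemble a clean confocal frame —
  the underlying study reports no image-noise statistics, so these are
  *not* reproductions of any real acquisition.
- **Tracks** — a persistent random walk with an Ornstein–Uhlenbeck
  heading (angular diffusion `√(2Δt/τ_p)`), deterministic step length
  `speed · Δt`, and optional chemotactic bias replacing a fraction of each
  step with +x drift.  Defaults: 6 μm/min, τ_p = 60 s, 5 s frames,
  5 min — the random-migration acquisition design.
- **Kinetic traces** — the logistic-rise/exponential-decay model sampled
  at 750 ms with i.i.d. Gaussian noise of SD `noise_sd_frac · A`.
- **Detachment** — a binomial survival chain (each interval removes each
  remaining cell independently), which guarantees non-increasing counts.

Passing tests on these inputs demonstrates that the *computational*
pipeline is correct under its stated assumptions — exact arithmetic,
oracle equivalence, parameter recovery at known ground truth.  They do not
validate the biological thresholds themselves (e.g. whether MFI + 3 SD is
the right cut for a given microscope), nor robustness to photobleaching,
uneven illumination beyond what the top-hat removes, cell-shape dynamics,
3-D PSF effects, or segmentation errors on low-contrast cells — none of
which the generators model.  The end-to-end stack benchmark shows one more
caveat: a trace measured through top-hat + detection is a *transformed*
readout of the underlying fluorophore amplitude (pixel-set growth
saturates the mean), so assembly timing is recovered faithfully while
rate constants carry a measurement-chain bias; tight parameter-recovery
claims are therefore made at the trace level.

## Problem sizes used in the shipped benchmarks

Grid recovery uses 270 images (3 amplitudes × 3 counts × 3 widths × 10
replicates); colocalization agreement 100 layouts; MSD oracles 50 random
tracks; lifetime recovery 100 noisy traces; ROUT specificity 200 samples
of n = 1000; detachment simulation 200 chains of n₀ = 1000; gating 20
track sets of 10 tracks.  These sizes keep the full suite and the
acceptance script fast on a single CPU while leaving Monte-Carlo error
well below the asserted tolerances.
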