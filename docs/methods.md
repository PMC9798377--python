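# Methods

This note documents the models, estimators and design choices behind
`trajmodes`, in the order the analysis runs. Units are μm and seconds
everywhere inside the package; conversions (pixels → μm) happen only at I/O
boundaries.

## Trajectories and MSDs

A trajectory is a sequence of 2D positions at strictly increasing integer
frame indices with frame interval Δt = 1/fps; the time of frame j is j·Δt
and the duration of N positions is (N−1)·Δt. Linking gaps (up to the
gap-closing limit of the upstream tracker) are preserved as missing frames,
never interpolated; all lag computations use true frame differences, so a
pair spanning a gap contributes to the lag it actually spans.

The time-averaged MSD (TA-MSD) at lag τ = kΔt averages the squared
displacement over all start frames of one trajectory; the ensemble-averaged
MSD is the unweighted mean of per-trajectory TA-MSDs at each common lag.
TA-MSD values at different lags are strongly correlated, and their relative
variance grows roughly like 2k/(3(N−k)) — the central fact behind most lag-
range and weighting choices below.

## Model fitting

Four 2D MSD models are fitted (see README for the forms). Choices:

* **Normal and active** — unweighted linear least squares on the MSD values;
  both are linear in their parameters (D, v²), solved in closed form with
  nonnegativity enforced by clipped refits.
* **Anomalous (power law)** — weighted least squares of log MSD on log τ with
  weights 1/k. Because Var[TA-MSD(k)] grows ~linearly in k at small k/N, 1/k
  approximates inverse-variance weighting of the log values. An unweighted
  fit on the *linear* MSD values lets the noisiest long lags dominate: on
  pure Brownian ensembles it biases the mean fitted exponent down to ≈0.96
  and spreads per-trajectory estimates to median |α−1| ≈ 0.19, while the
  weighted log-log fit gives mean ≈0.99 and median |α−1| ≈ 0.04 under the
  same conditions. Both forms are exact on noiseless power laws. α is
  clamped to [0.1, 2].
* **Confined** — nonlinear least squares in the identifiable parameterization
  (plateau P = r_c², amplitude A₁ ∈ (0, 2], rate B). D and A₂ enter the
  model only through B = 4·A₂·D/r_c², so D is reported under the convention
  A₂ = 1; the plateau and rate are what the data determine.

`fit_error` is always the residual 2-norm relative to the data 2-norm in
linear space, comparable across models. Fits are deterministic;
non-convergence is flagged on the result, not raised.

**Lag ranges.** The default whole-trajectory fit range is k = 1 to
max(3, ⌊0.25·(N−1)⌋): TA-MSD accuracy decays at large lags, and a quarter of
the lags balances range against variance for the exponent. For *parameter*
estimation the range follows where the parameter carries signal: D and α use
the first 10 lags (the diffusive signal lives at short lags, which also have
the smallest TA-MSD variance), while v and r_c use the quarter-range (the
ballistic τ² term and the plateau only emerge at long lags). With these
ranges, median recovery errors on 1000-step simulations are ≈3% for D, ≈0.03
absolute for α, ≈4% for v and ≈3% for r_c.

## Simulator

Each mode has an exact generative model: Brownian steps of per-axis variance
2·D·Δt; active motion adds a persistent drift v·Δt along a heading drawn
once per segment (the active MSD model assumes a persistent velocity over
the fitted window); subdiffusion is fractional Brownian motion with Hurst
exponent H = α/2, generated per axis by circulant embedding (Davies–Harte)
with exact covariance and a Cholesky fallback, scaled so the 2D MSD is
4·D·τ^α; confinement reflects Brownian steps radially at a circle of radius
r_c centered on the segment start, giving an MSD plateau at r_c² (the mean
squared separation of two uniform points in a disk). Localization error is
additive i.i.d. Gaussian noise per axis applied to the true path — the
standard static camera-error model; it inflates short-lag MSD and depresses
fitted exponents, which the test suite checks is monotone in the noise level.

Mode-switching trajectories are continuous in position and instantaneous in
parameters at switch points; each schedule entry of duration T contributes
round(T/Δt) positions and its own labels. The matched-Brownian control
reproduces an observed ensemble's size and trajectory lengths with a single
D — the reference for how much α/D spread finite length alone produces.

What the simulator does *not* emulate: photobleaching-driven intensity decay
(length censoring is imposed directly through trajectory lengths), detection
and linking errors other than i.i.d. localization noise, spatially varying
viscosity, and subdiffusion with a finite crossover time — fBm is scale-free.
Passing tests therefore validate the estimators and the segmentation logic,
not the upstream tracking, and real cytoplasmic subdiffusion (which
normalizes beyond a crossover scale) can deviate from the fBm idealization.

## Drift

Stage drift is modeled as one constant velocity per ensemble (per video),
estimated as the ensemble-mean displacement per unit time over all
trajectories and subtracted cumulatively. A per-frame nonparametric estimate
would overfit at typical track counts (~50). The estimator's noise floor is
√(2D/T_total); drift correction is therefore meaningful for slow
intracellular ensembles (D ~ 10⁻³ μm²/s, minutes of pooled data) and is
reported with a warning when attempted on a single short trajectory.

## Nonsegmented analysis

Per-trajectory anomalous fits give the α and D distributions; trajectories
are grouped fast/slow by relative displacement Δx = max(x)−min(x) (Δy alike)
scaled by √duration, which is duration-free for Brownian motion. The
automatic threshold is the kernel-density minimum between the two largest
modes of the pooled log score distribution and refuses to split a unimodal
distribution (a genuine dip of at least 20% below the smaller peak is
required). Displacement PDFs pool both axis displacements at one lag;
Gaussianity is summarized by the excess kurtosis (0 for a homogeneous
Brownian ensemble, strongly positive for mobility mixtures). The
Stokes–Einstein conversion η = k_B·T/(3π·D·d) uses T = 293.15 K by default,
overridable.

## Rolling-window segmentation

The window spans `window_s` seconds (L = window_s/Δt + 1 positions) and
slides one frame at a time; each window's TA-MSD is computed by sliding sums
and all windows are fitted at once by vectorized versions of the four model
fits (the batch fitters agree with the scalar API to solver tolerance;
covered by tests).

**Decision rule per window.** With the unweighted log-log slope α̂ of the
window MSD and its standard error SE:

1. α̂ > 1.3 and the active model halves the normal model's relative fit
   error → **active**;
2. α̂ + SE < 0.7 (a significance-gated subdiffusion call), then **confined**
   if the confined model halves the power law's fit error *and* its fitted
   plateau is reached within the fitted lags (rate·τ_max ≥ 3), else
   **anomalous**;
3. otherwise **normal**; a degenerate all-zero window is confined.

Three numerical details matter here:

* Classification uses lags up to half the window but at most 50 lags. At
  high frame rates the finite-window downward bias of the TA-MSD at lags
  approaching the window length mimics a confinement plateau; capping the
  lag count keeps k/L small where that bias is negligible.
* SE is the regression standard error floored by the analytic TA-MSD noise
  (relative variance 2k/(3(L−k)) propagated through the regression), because
  the regression residuals are correlated and underestimate the slope noise.
  The floor makes windows with few positions — low frame rates —
  conservative about subdiffusion claims, which is also the mechanism by
  which low-rate recordings recover less of the true subdiffusion.
* The fit-improvement margin is 50%: the extra parameters of the richer
  models fit window-scale noise well, and weaker margins (10%) let the
  confined model claim most noisy subdiffusive windows. True confined
  windows typically improve on the power law by ~65–70% and pass easily.
  The active branch carries no significance gate: a false active call would
  also have to halve the normal model's error, which noise alone rarely
  does.

All thresholds (0.7/1.3, margin, saturation, gate strength, lag cap) are
exposed in `SegmentationConfig`. On four-mode switching ensembles with
well-separated parameters this rule classifies 89–93% of positions correctly
and localizes switch points to well within one window length.

**From windows to segments.** Each position takes the majority mode over all
valid windows covering it, ties broken toward the previous position's label
(temporal continuity). Runs shorter than the minimum segment length (default
60% of the window) are merged into the flanking run whose mode fits the
run's own MSD with lower relative error (ties toward the earlier segment),
iterating shortest-first until all segments are long enough. Positions near
trajectory ends are covered by fewer windows but always by at least one;
positions with no valid covering window (possible only around large linking
gaps) stay unlabeled and are excluded from, but counted alongside, the mode
proportions.

**Segment parameters.** Each segment's own TA-MSD is refitted with its
mode's model: D for every mode, v for active, α for anomalous segments.
Non-active refits use at most the first 10 lags (the short-lag D logic
above; long lags would also leak neighboring-mode behavior into the estimate
after imperfect segmentation), while active refits keep the quarter-range
that v needs. Mode proportions are weighted by position counts — they answer
"what fraction of observed time is in each mode". The rapid-transport
fraction is the share of active segments with D ≥ 0.01 μm²/s, the
conventional cutoff separating fast microtubule transport from
microfilament-scale movement.

## Frame-rate / window sweep

`framerate_window_sweep` simulates one ensemble at the least common multiple
of the requested frame rates, subsamples it to each rate (keeping every
n-th frame — exactly what a slower camera would have recorded), censors at a
minimum trajectory length equal to the analysis window, and segments each
(fps, window) setting. The packaged reference ensemble
(`stop_and_go_spec`) has 14 trajectories of 190 s alternating normal
diffusion (D = 0.004 μm²/s), active transport (v = 0.1 μm/s) and
subdiffusion (α = 0.5, amplitude matched to the normal mode near 0.25 s so
that neither mode dominates the other's MSD magnitude), with bout durations
(40/25/20 s) bracketing the largest analysis windows. On this ensemble,
across the settings (50 fps, 1 s) → (2 fps, 25 s):

* the median active-segment velocity declines monotonically (fine windows
  select strong-signal windows and overestimate v; coarse windows mix active
  bouts with flanking diffusion and dilute it);
* the detected anomalous proportion is lower at 2 fps than at 20 fps for the
  same 15 s window (the significance gate: 30-position windows cannot
  support subdiffusion claims that 300-position windows can);
* the median per-mode D stays within 25% of its cross-setting median, for
  settings where the mode retains at least 5% of positions — a median over a
  vanishing class is not meaningful, the same reason the confined mode is
  conventionally excluded from parameter comparisons when its share is
  negligible.

## Numerical edge cases

Stationary trajectories give MSD ≡ 0 and every model degenerates cleanly to
D = 0 with zero fit error (windows classify as confined — an immobile
particle is the zero-radius limit). Zero-duration schedule entries
contribute no positions. Subsampling drops trajectories left with fewer than
two positions. Boundary durations in length censoring are inclusive. All
randomness flows from explicit integer seeds through numpy Generators; the
same seed and configuration reproduce trajectories bit-for-bit, and pipeline
reruns with one config are byte-identical.

## Problem sizes

The packaged validation protocols use 100-trajectory ensembles of 1000 steps
for estimator calibration, 10×2000-position trajectories for segmentation
accuracy, and the 14-trajectory reference ensemble for the sensitivity
sweep; these sizes put median estimator noise well below the effect sizes
being tested while keeping the full suite to a couple of minutes on one CPU.

## Known limitations

The window decision rule is a reimplementation designed around the four MSD
models; its thresholds were chosen on simulated data and are not fitted to
any experimental recording. fBm subdiffusion is scale-free, so frame-rate
effects on anomalous detection arise here purely from estimator statistics,
whereas in cells they also reflect genuine crossover time scales. Confined
segments are detected but their radii are not propagated into the ensemble
summaries (the mode's share is typically too small for meaningful
distributions). The drift model is constant-velocity per ensemble; slow
nonlinear stage wander is not corrected.
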