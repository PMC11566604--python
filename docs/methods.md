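# Methods

This note documents the models, estimators, and numerical choices behind
`fiberphot`, and what the synthetic-data validation does and does not show.

## Signal model and normalization

Raw fluorescence per region and spectral channel is treated as

    Fraw(t) = F0 · (1 + s(t) + d(t) + ε(t)) · b(t)

where `s` is the event component (Ca²⁺ transients), `d` a slow shared
"drive" (arousal/hemodynamic-like), `ε` white measurement noise, and `b` a
mono-exponential photobleaching factor. The pipeline estimates a baseline
F₀(t) as a moving-window mean of Fraw (centered by default, trailing
optionally; edge windows truncated to the data), forms
ΔF/F = (Fraw − F₀)/F₀, and standardizes to a z-score using the mean and
**population** standard deviation over a normalization span (the whole
session by default). Population rather than sample sd makes the
unit-variance invariant exact.

**Baseline window.** The window length trades drift removal against
transient distortion: a centered mean of window `W` superimposes roughly
`−(event integral)/W` of each event onto its own neighborhood. The package
default is 30 s (adequate for fast neuronal transients); all kinetic
analyses in the validation workflows use 300 s because astrocytic events
last tens of seconds and carry integrals of several z·s — with a 30–120 s
window their own mass visibly structures the baseline. Both are exposed as
`window_s`.

Streams recorded on different clocks (behavior video vs photometry) are
aligned by piecewise-linear interpolation between shared event markers;
residuals vanish at the markers by construction.

## Behavior quantification

Frames are binarized (fixed threshold or Otsu's histogram split; dark mouse
on a white arena by default, invertable), the largest connected component is
taken as the body, and invalid frames (blank, saturated) are interpolated
from neighbors up to a 1 s gap. "Movement relative to body size" is
operationalized as the symmetric-difference pixel count of consecutive body
masks divided by their mean area; this is the simplest body-size-normalized
frame-difference measure, capped at 2.0 for degenerate frame pairs.
Thresholding the index (θ = 0.05, sustained ≥ 1 s, gaps < 0.5 s bridged,
remaining time stationary) partitions the session into states; movement
onsets are movement-segment starts preceded by ≥ 3 s of quiescence. These
operating points are package decisions, not measured values, and are all
configurable.

## Transient detection and event-triggered kinetics

Detection on z traces uses two thresholds: a candidate event is a run of
z ≥ θ_on = 2 sustained ≥ 1 s; its onset extends back to the preceding upward
crossing of θ_off = 0.5 and its end forward to the next downward crossing;
events separated by < 0.5 s merge; the peak is the within-event maximum
(earliest sample on ties). An optional centered moving average
(`smooth_s`) stabilizes threshold crossings on slow, low-amplitude
astrocytic decays; peak heights are always read from the raw trace.

Event-triggered analysis stacks z segments around movement onsets or shocks
(trials without a complete window are dropped, not padded, keeping the SEM
unbiased; each trial may subtract its pre-window mean). Per trial:

- **latency** — first crossing of θ_resp = 2 sustained ≥ 0.33 s within a
  10 s window, measured on a lightly smoothed trace;
- **peak time** — argmax within a peak window (15 s for the slow astro
  response, 5 s for neurons). Broad plateau-like astro peaks use a stronger
  smoothing (2 s) for the argmax alone: the plateau makes the raw argmax
  nearly uniform over several seconds under slow noise, while smoothing at
  the plateau scale converts that jitter into a small tilt-driven error;
- **valley time** (neuronal trace) — argmin after the peak within 15 s,
  capturing the suppression that follows the astrocytic peak;
- **response duration** — from the latency crossing to the final settling
  inside the ±θ_off band. The end is found by locating the last
  "substantive" excursion (|z| ≥ θ_cont = 1.5, well above the noise floor)
  and taking the first sample after it with |z| < θ_off. Counting the
  suppression phase as part of the response is deliberate: the neuronal
  valley lies *inside* the reported neuronal response duration, so a naive
  "first fall below θ_off" definition cannot reproduce both quantities on
  one trace.

Trials with no sustained crossing are non-responders and excluded from
summaries. Timing differences are reported astro − neuron (positive =
astrocyte later); the astro-peak→neuron-valley interval is
valley(neuron) − peak(astro), positive when the peak precedes the valley.

## Connectivity and prediction

State-conditioned series concatenate, in time order, the samples falling in
segments of one behavioral state (≥ 300 samples required). Inter-region
coupling is Spearman rank correlation (average ranks on ties; undefined
entries from constant input are flagged, never imputed). Astro–neuron
coupling is the peak Pearson correlation over integer-sample lags within
±10 s (positive lag = astrocyte follows neuron); at zero max-lag this
reduces to plain Pearson correlation. Graphs place regions at their
stereotaxic (AP, ML) coordinates with edge weights equal to r.

Neuron→astrocyte prediction uses a random forest (100 trees, fixed seed,
`min_samples_leaf` 5) on lagged neuronal features (0–10 s in 1 s steps;
rows with incomplete history dropped) with blocked, contiguous-in-time
5-fold cross-validation — shuffled CV leaks badly on autocorrelated traces.
Variance explained is pooled over held-out folds (1 − SSE/SST), which is
stable for short folds; it can be negative when the model extrapolates
poorly.

Paired comparisons use Wilcoxon's signed-rank test (zeros dropped; exact
enumeration for n ≤ 12 without tied magnitudes, otherwise a tie-corrected
normal approximation with continuity correction) and unpaired comparisons
the rank-sum test (exact for min(n, m) ≤ 10 without ties). No
multiple-testing correction is applied anywhere.

## Synthetic recordings

The generator defines the study conditions the tests recover:

- **Behavior**: stationary/movement bouts from a renewal process (gap =
  min-quiescence + exponential excess sized to the target bout rate;
  truncated-normal durations), or a jittered fixed-count schedule for
  trial-structured sessions; a heading-persistent open-field walk
  (4–8 cm/s during bouts) inside a 40 × 40 cm arena; a smoothed positive
  movement index during bouts.
- **Stimuli**: footshock trains, 0.6 mA (metadata), 1 s pulses every 5 min,
  4 trials per session.
- **Transients**: difference-of-exponentials kernels specified directly by
  the observables the pipeline measures — threshold-crossing latency, peak
  time, duration, z amplitude — with (τ_rise, τ_decay) solved numerically
  so these hold by construction. The family cannot make the fall faster
  than ~5–7× the rise-to-peak (threshold-dependent); requests below that
  are clamped to the feasible boundary. Movement-evoked defaults: astro
  latency 2.47 s, peak 5.66 s; neuron latency 0.42 s, peak 1.07 s.
  Footshock defaults: astro 1.05 s / 1.67 s / 8.05 s duration; neuron
  0.20 s / 0.99 s / 6.24 s. Free-behavior durations default to 40 s
  (astro) and 8 s (neuron), consistent with the >20 s vs <20 s duration
  dichotomy; movement-evoked astro responses in the trial-structured
  recovery condition use 20 s.
- **Valley**: a subtractive Gaussian dip on the neuronal trace centered
  `valley_offset_s` after the astro peak (1.50 s movement, 3.35 s
  footshock; depth 3 z). Its width is solved so the composite neuronal
  excursion settles exactly at latency + configured duration, making the
  configured duration recoverable in the presence of the valley.
- **Microdomains**: stationary-state astrocytic events at a configurable
  fraction (default 0.1) of the movement-state amplitude, emulating the
  ~10× microdomain/global amplitude dichotomy. In the footshock preset the
  fraction is reduced so background events keep their absolute size rather
  than scaling with the large shock responses.
- **Coupling**: one slow common drive (Gaussian-filtered, τ = 2 s) scaled
  per behavioral state plus per-channel slow noise; the drive correlation
  shared²/(shared² + noise²) is calibrated to ≈ 0.88 during movement and
  ≈ 0.30 when stationary and recorded in the ground truth. White
  measurement noise rides on top of every channel.
- **Amplitude calibration**: event shapes are composed in z units and
  mapped to ΔF/F with a gain σ_t = √(var(floor)/(1 − var(shape))), so that
  after whole-session z-scoring realized amplitudes equal `amplitude_z`.
  This requires var(shape) < 1 — dense, slow astro events therefore cap at
  a few z while sparse footshock responses can reach ~15 z, matching how
  session-normalized z amplitudes behave in real recordings. Noiseless
  configurations fall back to unit gain (amplitudes then arbitrary).
- **Controls**: optional GFP/mCherry channels carry drive, noise and bleach
  but no events.
- **Renderers**: fiber-bundle image stacks (one disc per region×channel;
  disc mean equals Fraw to ≤ 0.5 gray level) and behavior video (dark
  ellipse on a bright arena at the ground-truth centroid; 320 × 180 by
  default, the arena mapped onto the frame height).

Identical configurations (including the seed) produce byte-identical
output; internal random streams are split from a single `SeedSequence`.

## Validation workflows and problem sizes

`fiberphot.workflows` runs each validation end to end at desk scale:
movement kinetics on one 2800 s session with 21 scheduled, well-separated
bouts (20 analyzed trials); footshock kinetics on five 1500 s sessions of
4 shocks (20 trials); the duration dichotomy and control false-positive
bound on 900 s free-behavior sessions; connectivity ordering on twenty
300 s sessions with long bouts; prediction ordering on one 400 s session;
behavior recovery on a rendered 90 s video. Per-condition amplitudes vary
with event density solely to respect the z-variance budget above.

## What passing tests do and do not show

The generator shares the analysis' structural assumptions (kernel-shaped
events, Gaussian noise, exponential bleach, binary behavioral states), so
parameter recovery demonstrates that the pipeline is a consistent estimator
of its own model, at realistic SNR — not that the model captures every
property of real recordings. Not emulated: hemodynamic/motion artifacts
with spectral structure (no isosbestic channel is modeled), cell-to-cell
heterogeneity within the fiber volume, amplitude variability across events,
non-exponential bleaching, behavioral states beyond the binary partition,
and imaging artifacts in the video (occlusion, lighting gradients).

## Known limitations

- Threshold-based latency is biased late by a fraction of the rise time at
  low SNR; tolerances in the validation account for this.
- The duration estimator's continuation threshold (1.5 z) assumes response
  excursions clear it; responses shallower than ~2 z truncate at their last
  crossing.
- Spearman matrices on concatenated state samples treat samples as
  exchangeable; autocorrelation inflates their effective confidence, which
  is why state contrasts are tested across independent sessions.
- The cross-correlation peak over many lags is an extreme-value statistic
  and is biased upward on short, noisy segments.
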