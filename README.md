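# fiberphot

Analysis of **dual-color multi-fiber photometry** recordings: simultaneous
astrocytic (GCaMP6f, 470 nm) and neuronal (jRGECO1a, 560 nm) population Ca²⁺
signals from several brain regions (S1, M1, hippocampal CA1) of freely
behaving mice, recorded together with open-field behavior video and sensory
stimuli (footshocks).

The package is aimed at neurophotonics labs that record bulk Ca²⁺ with fiber
bundles and want a tested, scriptable pipeline for:

- **Signal normalization** — ROI extraction from fiber-bundle image stacks,
  moving-window baseline, ΔF/F = (F − F₀)/F₀ and
  z = (ΔF/F − ⟨ΔF/F⟩)/σ(ΔF/F);
- **Behavior quantification** — frame binarization, body delineation, a
  body-size-normalized movement index (|mask XOR maskₜ₋₁| / body area),
  stationary/movement state segmentation and movement onsets, trajectories;
- **Ca²⁺ transient analysis** — two-threshold event detection and
  event-triggered kinetics: response latency, peak time, duration, and the
  neuronal "valley" (the suppression that follows the astrocytic peak);
- **Functional connectivity** — state-conditioned inter-region Spearman
  matrices per cell type, astrocyte–neuron lagged cross-correlation, and
  stereotaxically placed connectivity graphs;
- **Neuron→astrocyte prediction** — random-forest regression on lagged
  neuronal features with blocked cross-validation, reporting variance
  explained per behavioral state;
- **Statistics** — Wilcoxon signed-rank / rank-sum tests (exact for small n)
  and mean ± SEM summaries.

Because raw in-vivo recordings of this kind are rarely public, the package
ships a first-class **synthetic recording generator**
(`fiberphot.simulate`) that emulates the statistical structure of such
sessions — slow, long-lasting astrocytic transients (latency ≈ 2.5 s,
durations mostly > 20 s), fast brief neuronal transients (latency < 0.5 s,
durations < 20 s), astro-peak→neuron-valley locking, stationary microdomain
events at one tenth of the movement-state amplitude, state-dependent shared
drive, photobleaching, and inert GFP/mCherry control channels — with full
ground-truth annotations so every analysis stage is validated by parameter
recovery.

## Worked example

```python
from fiberphot.simulate import (SimulationConfig, MovementBoutParams,
                                make_behavior, simulate_recording)
from fiberphot.preprocess import process_recording
from fiberphot.behavior import segment_states
from fiberphot.transients import build_ensemble, response_metrics, ResponseParams

config = SimulationConfig(
    duration_s=900.0,
    movement_bouts=MovementBoutParams(rate_per_min=0.2, n_bouts=3),
    seed=1,
)
behavior = make_behavior(config)
recording, truth = simulate_recording(config, behavior)

processed = process_recording(recording, window_s=300.0)
segments = segment_states(behavior[0].index, config.rate_hz)

z_astro = processed[("M1", "astro")].z
ens = build_ensemble(z_astro, segments.movement_onsets, pre_s=5.0, post_s=38.0,
                     rate_hz=config.rate_hz, rebaseline=True)
metrics = response_metrics(ens, ResponseParams(peak_window_s=15.0, smooth_s=1.0,
                                               peak_smooth_s=2.0))
print(f"astro latency {metrics.latency_s.mean():.2f} s, "
      f"peak {metrics.peak_time_s.mean():.2f} s ({ens.matrix.shape[0]} trials)")
```

This prints:

```
astro latency 2.47 s, peak 5.87 s (3 trials)
```

i.e. the movement-evoked astrocytic response crosses the 2 z detection
threshold ≈ 2.5 s after movement onset and peaks ≈ 5.9 s after it — the
pipeline reads back the latency (2.47 s) and peak time (5.66 s) injected by
the generator, within the event-triggered measurement noise of a three-bout
session.

A command line mirrors the library (`fiberphot simulate|preprocess|behavior|
detect|connect|predict|run-all`, driven by a YAML config); see
`fiberphot --help`.

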