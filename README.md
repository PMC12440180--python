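# glomlearn

Quantification pipeline for trial-structured olfactory-bulb calcium
imaging, go/no-go behavior, and spatial expression data.

Widefield and two-photon imaging of the dorsal olfactory bulb during odor
discrimination learning produces per-glomerulus fluorescence traces over
many CS+ (rewarded) and CS− (punished) trials, alongside lick records,
immunofluorescence sections, and multiplexed transcript maps. `glomlearn`
implements the full analysis chain for such experiments as a tested,
seeded, reusable library with a thin CLI — aimed at systems-neuroscience
labs that need the bespoke parts of this analysis (responsiveness calls,
selectivity, onset latencies, permutation modulation tests, expression-bias
and colocalization statistics) to be reproducible rather than re-derived
per project.

## The quantities it computes

**Response extraction.** Raw fluorescence is baseline-normalized,
ΔF/F(t) = (F(t) − F₀)/F₀ with F₀ the pre-stimulus mean, smoothed with a
centered 300-ms moving average, and the per-trial peak is the maximum over
the 2-s odor window. An ROI is *responsive* when its trial-averaged peak
exceeds 3×SD of its baseline noise (SD over a 2-s pre-stimulus window,
pooled across trials).

**Selectivity.** SI = (mean CS+ peak − mean CS− peak) / SD(all per-trial
peaks); SI > 1 labels a glomerulus high-CS+, SI < −1 high-CS−, the closed
interval [−1, 1] low.

**Onset latency.** On the unsmoothed trial-averaged ΔF/F, the first frame
at/after odor onset beginning a run of 4 consecutive frames above 3×SD.

**Modulation.** Per ROI, a two-sided trial-identity permutation test: the
Welch t statistic of per-trial peaks between conditions, a null built from
1,000 relabelings of the pooled trials,
p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1), Benjamini–Hochberg FDR across ROIs,
and a direction call (increased / decreased / unchanged) at q < 0.05.

**Spatial maps.** Activation coordinates re-centered on the area (shoelace)
centroid of the traced bulb outline, radius normalized to the farthest
activation per animal, angle in (−π, π]; plus binned fraction-responsive
maps.

**Expression statistics.** Zone-binned cell-density profiles and the bias
statistic (mean CS+ zones − mean CS− zones)/SD(all zones) (positive =
biased toward the rewarded odor's territory); glomerulus volume as stacked
conjoined frusta, V = Σ (πh/3)(R² + Rr + r²); TH⁺ soma density =
counts/volume; and transcript colocalization — Gene2 pixels within a fixed
radius of each Gene1 pixel, normalized by √(n₁·n₂).

**Behavior.** Hit / miss / false-alarm / correct-rejection scoring from
licks in a 3-s window opening 0.3 s after odor delivery, and balanced
session accuracy (hit rate + CR rate)/2.

A seeded synthetic-data module generates every input with planted ground
truth (amplitudes, latencies, colocalized fractions, zone biases), so the
whole chain is benchmarked against known answers.

## Worked example

```python
import numpy as np
import glomlearn as gl

# 20 ROIs, 15 trials per odor at 10 Hz; ROI 0 responds to the rewarded odor
amp = np.zeros((20, 2)); lat = np.zeros((20, 2), dtype=int)
amp[0, 0] = 0.4; lat[0, 0] = 3          # 0.4 dF/F, onset 3 frames after odor
amp[1, 1] = 0.25; lat[1, 1] = 6
spec = gl.SyntheticSessionSpec(n_rois=20, n_trials_per_odor=15,
                               noise_sd=0.05, amplitude_map=amp,
                               latency_map=lat, rng_seed=42)
traces, truth = gl.generate_trial_traces(spec)

summary = gl.summarize_responses(traces)
print(summary[summary.responsive])

dff = gl.compute_dff(traces)
rec = gl.onset_latency(dff, "roi000", "CS+")
print(f"onset: frame {rec.onset_frame} = {rec.onset_s:.1f} s after odor onset")

sm = gl.smooth_moving_average(dff)
from glomlearn.traces import trial_peaks
si = gl.selectivity_index(trial_peaks(sm, "roi000", "CS+"),
                          trial_peaks(sm, "roi000", "CS-"))
print(f"selectivity index roi000: {si:.2f} -> {gl.classify_selectivity(si)}")
```

prints

```
    roi_id odor  peak_dff  baseline_sd  responsive  onset_latency_frame
1   roi001  CS-  0.299960     0.046629        True                 26.0
20  roi000  CS+  0.448131     0.049899        True                 23.0
onset: frame 23 = 0.3 s after odor onset
selectivity index roi000: 1.96 -> high_csplus
```

Only the two planted responders are flagged; their measured peaks sit near
the planted 0.4 and 0.25 ΔF/F (the small excess is the expected maximum of
smoothed noise over the odor window), and the detected onset — frame 23 at
10 Hz with odor onset at frame 20 — recovers the planted 3-frame latency.

The same chain is available from a shell:

```sh
glomlearn simulate --out session/ --seed 42
glomlearn respond  --in session/ --out results/
glomlearn run-all  --out full_run/ --seed 42   # every stage + run manifest
```

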