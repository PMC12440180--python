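# Methods

This note documents the models, parameters and conventions behind
`glomlearn`'s quantification procedures: what each statistic assumes, what
the synthetic generators emulate (and what they deliberately do not), and
the design choices made where the underlying conventions were genuinely
open.

## Response model and ΔF/F chain

Fluorescence traces are organized as a dense `(trials × ROIs × frames)`
array with a shared stimulus window per session. The chain is:

1. **ΔF/F**: per trial and ROI, (F − F₀)/F₀ with F₀ the mean over the
   pre-stimulus baseline window (default: the full interval before odor
   onset). F₀ ≤ 0 is treated as a data error — it indicates broken
   background subtraction upstream, not a valid trace. ΔF/F is invariant
   to rescaling the raw trace by any positive gain, which is why no
   absolute fluorescence calibration is needed anywhere downstream.
2. **Smoothing**: centered moving average of width
   `round(window_ms · rate / 1000)` frames, forced odd (upward) so the
   window is symmetric; 300 ms gives 3 frames at 10 Hz and 5 frames at
   13.3/15 Hz. Edge frames average over the in-range part of the window so
   no frames are discarded and constant traces are fixed points. A
   centered (rather than causal) window was chosen because a causal
   average would systematically delay peaks; onset detection avoids the
   issue entirely by running on unsmoothed traces.
3. **Peaks**: per-trial maximum of the smoothed ΔF/F over the odor window
   (inclusive of both endpoint frames); the per-(ROI, odor) peak response
   is the mean of per-trial peaks. Averaging trials *after* taking maxima
   matches how per-trial response amplitudes are usually reported; the
   alternative (peak of the trial-averaged trace) is smaller under noise
   and can be obtained by peak-extracting a pre-averaged set.
4. **Responsiveness**: peak > k·SD with k = 3 by default, SD being the
   sample SD (n−1) of unsmoothed ΔF/F over a 2-s pre-stimulus window
   pooled across all trials of that ROI. The inequality is strict, so a
   zero-amplitude ROI with zero noise is *not* responsive; with SD = 0 the
   rule degenerates to peak > 0. Pooling across trials (rather than
   per-trial SDs) gives ~40× more baseline frames per ROI at typical trial
   counts and a correspondingly stabler threshold; a per-trial variant is
   available via `summarize_responses(per_trial_threshold=True)`.

## Selectivity index

SI = (mean CS+ peaks − mean CS− peaks) / SD(pooled per-trial peaks of both
odors, n−1). The SD is per-ROI, not population-wide: each glomerulus is
scored against its own trial-to-trial variability. Labels: SI > 1 →
high-CS+, SI < −1 → high-CS−, and the **closed** interval [−1, 1] → low,
so every finite SI has a label; a zero pooled SD yields NaN (undefined)
and the ROI is excluded from selectivity summaries rather than given an
infinite index. SI is antisymmetric under odor exchange and invariant to
trial order within odors — both are asserted as property tests.

## Onset latency

Scanning the **unsmoothed, trial-averaged** ΔF/F from the odor-onset
frame, onset is the first frame beginning a run of `run_length`
(default 4) consecutive frames all strictly above k·SD; the reported frame
is the first of the run. Absence of any such run is a valid result (the
ROI has no detectable onset), not an error. Detection on the trial-average
rather than per-trial traces was chosen because single-trial threshold
crossings at realistic noise levels are dominated by the noise maximum,
and the run-length requirement is then rarely satisfiable at low rates;
the per-trial reading remains possible by passing single-trial sets.
Latency is monotone non-decreasing in k on any fixed trace (property
test). Latency differences between matched sessions (post − pre, seconds)
drop ROIs detected in only one session and report the exclusion count.

## Permutation modulation test

Per ROI, condition A and B per-trial peaks are compared with the Welch t
statistic (B vs A, so positive = increased). The null is built by pooling
all per-trial peaks and reassigning condition labels uniformly at random
`n_perm` = 1,000 times; the two-sided p-value uses the add-one correction
(1 + #{|t*| ≥ |t|})/(n_perm + 1), so p ∈ (0, 1] always. The t statistic
here is only the ranking statistic of a permutation test — no normality
assumption is made — which is also why zero pooled variance short-circuits
to p = 1 and degenerate permutation draws (a constant group) score 0 when
the mean difference is 0 and ±∞ otherwise. Across ROIs, Benjamini–Hochberg
step-up adjustment (implemented in-package, ~10 lines, verified against an
independent reference implementation to 1e−12 in the tests) controls FDR,
and a direction is called only at q < alpha (strict). Per-trial peaks are
the exchangeable units because trial identities are what the null
permutes. All permutations for a session draw from one seeded generator,
so a seed fully determines every p-value.

Under a fully null synthetic session the mean fraction of non-unchanged
calls, over 50 seeded replicates of 200 ROIs, stays below alpha + 2 SE
(in practice far below: under a global null BH controls family-wise
error, so most replicates produce zero calls). A 2-SD mean shift planted
in 10% of ROIs is detected in the correct direction in ≥80% of planted
ROIs (in practice ≈100% at 20 trials per condition).

## Spatial maps

The bulb outline is a manually traced polygon; its centroid is the
**area** (shoelace) centroid — computed via shapely — not the vertex mean,
so unevenly spaced tracing points cannot skew it. Activation points are
re-centered on the centroid; r is normalized by the maximum activation
distance in that animal's point set (so r_norm = 1 is always attained),
not by the boundary radius along the same bearing — the two differ for
non-circular outlines. Angles use +x lateral, +y anterior,
counter-clockwise from +x, range (−π, π]; the convention is a config
field, since imaging orientation varies by rig. Fraction-responsive maps
report occupied bins only; an empty bin is absent, never 0, because 0 is
a meaningful measured value.

## Expression and colocalization statistics

**Colocalization** counts, for every Gene1 pixel, the Gene2 pixels at
Euclidean distance ≤ r (inclusive; one-to-many associations allowed; a
dual-labeled pixel pairs with itself at distance 0), then normalizes by
the geometric mean √(n₁·n₂) of the two genes' pixel totals so sections
with different expression levels are comparable. Although written
directionally, the sum equals the number of unordered cross-label pixel
pairs within r and is therefore exactly symmetric under gene exchange;
the property test asserts this. The neighbor count uses a k-d tree; an
O(n²) brute-force pair count is kept in the tests as the independent
oracle and agrees exactly. The radius r is a required configuration value
with no default fidelity claim — it must be chosen per dataset (pixel
size and probe spacing dependent).

**Zone density profiles** count cell centroids in ordered, non-overlapping
zone polygons (even-odd rule; a centroid on a shared boundary goes to the
lowest-indexed zone covering it — some deterministic tie-break is needed
and this one is order-stable). Supplying zone areas converts counts to
densities.

**Expression bias**: sections are averaged into one per-animal zone
vector, then bias = (mean CS+ zones − mean CS− zones)/SD(all zones, n−1).
Positive values mean expression is biased toward the rewarded odor's
territory; this sign convention (CS+ minus CS−) is fixed here as the
package's convention so that "positive = reward-biased" holds. The
statistic is exactly invariant under multiplying all zone values by a
positive constant (asserted), but not under additive shifts — shifts move
the means and the SD differently — so no shift invariance is claimed. If
the zone vector has zero SD, bias is 0 when the CS+/CS− means are equal
and undefined (NaN) otherwise.

**Glomerulus volume** models the glomerulus as vertically conjoined
frusta, V = Σ (πh/3)(R² + Rr + r²), with radii obtained by halving the
manually measured diameters; adjacent segments must share their interface
radius. Cylinder (R = r) and cone (r = 0) limits and additivity over
concatenation are exact and asserted. TH⁺ soma density is the summed
count across the z-stack divided by this volume.

## Behavior scoring

A trial's response window is [anchor + 0.3 s, anchor + 3.3 s), closed at
the start and open at the end, anchored at odor **offset** by default
(onset anchoring is a config switch — "after odor delivery" admits both
readings, and neither is asserted as the original convention). Licking in
the window on CS+ is a hit, on CS− a false alarm; withholding gives miss /
correct rejection. Session accuracy is the **balanced** mean
(hit rate + CR rate)/2, so unequal trial counts per odor cannot inflate
it; a pooled fraction-correct is available via `pooled=True`.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the real experiment: 2-s
baseline, 2-s odor window, a post-stimulus tail, sampling at 10/13.3/15 Hz,
pseudorandom CS+/CS− orders with at most 3 consecutive same-odor trials
(built by weighted sequential sampling), ~70–80 trials per session,
additive i.i.d. Gaussian noise in ΔF/F units, planted response amplitudes
and onset latencies, planted colocalized pixel fractions, Poisson zone
counts with planted bias, and Bernoulli per-odor lick probabilities.

The response kernel rises to the planted amplitude in one frame at the
planted onset, holds a plateau to the end of the stimulus, then decays
exponentially (τ = 0.5 s default). This kernel was chosen so that, in the
noiseless case, the smoothed-trace peak equals the planted amplitude
*exactly* and the first suprathreshold frame equals the planted onset —
making the generator a machine-precision oracle for the full chain. The
defaults (F₀ = 100 fluorescence units, noise SD 0.05 ΔF/F, amplitudes
0.1–1.0 ΔF/F) are plausible for GCaMP widefield imaging but are config
values, not claims about any particular dataset.

Deliberately **not** modeled: pixel-level movies and segmentation (traces
are generated at ROI level), motion/bleaching artifacts, correlated or
multiplicative noise, biphasic soma responses, sniff-locked temporal
jitter, and spatial correlation between ROI position and response
amplitude. Passing the planted-truth benchmarks therefore shows the
*estimators* are correct and calibrated under the stated noise model — it
does not certify performance under acquisition artifacts that the
generators do not produce.

For planted expression bias, a one-parameter family of four-zone
expectation vectors (base + x, base, base, base − spread) is solved by
root-finding so the planted bias hits any target of magnitude < 2
exactly; Poisson sampling then perturbs it. The recovered bias has a
small downward |bias| tendency because sampling noise inflates the SD in
the denominator; at the default 10 sections with expectations of a few
hundred counts this is ≲0.2% and well inside the 3-SE acceptance band.

## Determinism, numerics, and problem sizes

Every source of randomness is an explicit integer seed; the pipeline
expands its single configured seed into per-stage child seeds (via a seed
sequence, recorded in the run manifest), so a rerun reproduces every
output table byte for byte. CSV floats are written as `%.17g` and parsed
in round-trip mode, making every writer/reader pair lossless. Ties and
boundaries are fixed throughout (strict responsiveness threshold, closed
low-selectivity interval, inclusive colocalization radius, closed-open
lick window, lowest-index zone tie-break) because each is invisible in
expectation but matters for exact reproducibility.

Benchmark problem sizes — 50-ROI/20-trial recovery sessions, 20
calibration replicates, 50 null-modulation replicates of 200 ROIs at
1,000 permutations, 100 colocalization maps, 100 bias replicates — run in
roughly ten seconds on one core thanks to the vectorized permutation
engine; they were sized to leave all Monte-Carlo checks with comfortable
statistical margins rather than to probe asymptotics.

## Known limitations

- Modulation testing compares exactly two conditions; multi-session
  designs need pairwise calls.
- The colocalization score depends on pixelation density; it is a
  *relative* measure between conditions imaged identically, not an
  absolute overlap fraction.
- Zone polygons must be non-overlapping; partially overlapping manual
  tracings are rejected rather than resolved.
- The balanced accuracy treats a session as exchangeable trials; no
  learning-curve or satiety correction is applied within a session.
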