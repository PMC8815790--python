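# Methods

## Pipeline overview

`calunmix` decontaminates one neuron at a time in four stages.

**1. Auxiliary masks.** The background disk of neuron *i* is centered at the
unweighted centroid of its mask with radius 2.5× the radius of a circle whose
area equals the mean mask area of the video. Neighbors are the neurons whose
centroids fall inside this disk (center-to-centroid distance ≤ radius;
pixel membership uses pixel centers). The outside region is the disk minus
the union of *all* neuron masks; if its area falls below half the mean mask
area, the outside disk's radius (bookkept separately — the background disk
itself never grows) increases one pixel at a time until the area clears the
threshold, erroring out only if the radius exceeds the frame diagonal.

**2–3. Traces and background subtraction.** Per frame: the neuron and
outside traces are pixel means over their masks, the background trace is the
pixel median over the disk (median, so sparse bright structures within the
disk do not bias it). The background trace of each neuron's own set is
subtracted from that neuron's and outside traces. Overlapping mask pixels
contribute to every owner's mean; only the outside region excludes neurons.
F_meas stacks the target's background-subtracted trace, each neighbor's trace
(minus *that neighbor's own* background), and the target's outside trace —
rows ordered target, neighbors ascending by id, outside.

**4. Targeted NMF.** F_meas is divided by the quantile-based standard
deviation of its first row and shifted by its global minimum so all entries
are non-negative. The square factorization `F_meas ≈ M·F_sep` (component
count = row count; no dimensionality reduction) is solved by scikit-learn's
coordinate-descent NMF with NNDSVD initialization (zeros replaced by small
seeded random values), at most 20,000 iterations and tolerance 1e-4, with an
L1/L2 penalty at ratio l1 = 0.5 on both factors. scikit-learn scales its
penalties by the opposite matrix dimension, so the solver is called with
`alpha_W = α/T` and `alpha_H = α/n`, which makes the effective weight on
every norm term exactly α. The cost function exposed as `nmf_cost` uses
half-sum norm conventions (`‖A‖²_Fro = ½ΣA²`, `‖A‖₁ = ½Σ|A|`); the solver
optimizes an equivalent objective with the same minimizers.

*Floating α.* A separated trace is "identically zero" when its maximum
absolute value is below 1e-9 in normalized units. If any such row (or an
all-zero column of M) appears, α is halved and the factorization repeated;
below a floor of 1e-4, a final unregularized pass is accepted as-is. The
default α₀ = 1; the optimum clusters near 1 across datasets and
cross-validation can refine it.

*Matching.* Components are permuted back onto input rows by a five-step
greedy procedure: column-normalize M (compensating F_sep rows), then
repeatedly take the largest element of a working copy, record the pairing,
zero its row and column and re-normalize the remaining columns; finally apply
the permutation and normalize the diagonal of M to exactly 1. Every step
preserves the product M·F_sep to machine precision. Ties take the smallest
row then column index; if exact zeros exhaust the working copy early, the
leftover rows and columns are paired in ascending order.

*Rescaling.* Each row of F_sep is multiplied by the quantile-based standard
deviation of the first input row, then shifted so its median matches the
median of the corresponding background-subtracted input row (the
median-alignment reference is the background-subtracted matrix, not the raw
traces).

*Temporal downsampling.* With ratio r > 1, the normalized F_meas is
decimated to every r-th frame, the floating-α factorization yields M′, and
full-resolution separated traces solve the per-frame non-negative
least-squares problem `F_norm(:,t) ≈ M′·F_sep(:,t)` (NNLS preserves the
non-negativity contract; a pseudo-inverse could not). The penalty passed to
the decimated factorization is the same absolute α as the direct path.
Ratio 1 short-circuits to the direct path and is bit-identical to it.

## SNR videos and transient detection

Raw videos can be converted to SNR videos: a spatial homomorphic filter
(log-transform with offset 1, subtract a Gaussian low-pass of the log image,
add back its per-frame mean, exponentiate) removes multiplicative, spatially
broad background; a temporal matched filter shaped like the transient
(difference of exponentials, truncated at 1% of peak, unit L2 norm,
anchored at the current frame so event timing does not shift, edges handled
by replicating the end frames) boosts transient SNR; per-pixel whitening
(subtract the temporal median, divide by the quantile-based standard
deviation, floored at 1e-9) expresses everything in noise units.

Trace-level detection mirrors this: traces from raw videos are
matched-filtered first (traces from SNR videos are not — they already were),
the baseline is the mode of a Gaussian kernel density (Silverman bandwidth,
argmax on a 256-point grid spanning the data range), and the noise is
estimated from the high-frequency half of the Welch power spectral density
**of the unfiltered trace**. The unit-L2 kernel preserves white-noise
variance, so the pre-filter estimate equals the filtered trace's noise level;
the high band of the filtered trace itself is attenuated ~10× by the
kernel's low-pass response and would inflate the SNR scale arbitrarily.

Frames strictly above `th_SNR` are grouped into candidate periods. Periods
with no peak of topographic prominence ≥ `th_SNR/3` are discarded; one peak
gives one transient spanning the period; several peaks split the period at
the leftmost local minimum between each pair — the frame before a boundary
minimum ends the preceding transient, the frame after it starts the next.
Plateau peaks report their leftmost frame.

Ground-truth transients for noiseless simulated traces use the same
machinery with a self-calibrated threshold: peaks with prominence above the
trace's standard deviation are collected, the typical single-event height ĥ
is the mode of the kernel density of their heights, and both the activity
threshold and the minimum prominence are set to ĥ/2.

Detected and reference transients are matched one-to-one by the Hungarian
algorithm on a distance of minus the number of shared frames; matched pairs
with at least one shared frame are true positives. Video-level scores pool
counts over neurons before forming precision, recall and F1. Mask sets are
matched the same way on Dist = 1 − IoU (IoU ≥ 0.5) or 2 (unmatchable).
Leave-one-out cross-validation grid-searches (th_SNR, α) on the training
videos (ties prefer smaller α, then smaller th_SNR) and averages the
held-out F1.

## Synthetic data

The trace fixture exercises the mixing model directly: each source is a
Poisson spike train (one spike per frame at most) convolved with a
difference-of-exponentials template (rise 20 ms, decay 200 ms, amplitude 1);
`M_true` is the identity plus off-diagonal crosstalk drawn uniformly from
0.2–0.5 — always present into the target row, present with probability 0.5
elsewhere, rows rescaled so the off-diagonal sum stays ≤ 0.9 (contamination
is pairwise overlap, and a measured trace is mostly its own neuron);
`F_meas = M_true·F_true` plus unclipped Gaussian noise of σ = 0.1 (SNR ≈ 10).
Ground-truth transients come from the spike times, one per spike, spanning
the frames where the event template exceeds 20% of peak but truncated at the
next spike — the same segmentation a detector produces when it splits summed
events at the dip. The noise is left real-valued because background-
subtracted traces are; clipping at zero would halve the quiet-frame
distribution and collapse the quantile-based normalization.

The video generator renders disk somata with jittered radii
(rejection-sampled centers at least 8 px apart, close enough for partial
overlap), thin 1-px dendrite segments with independent activity, a
background field of three broad Gaussian blobs with independent slow
random-walk amplitudes, a constant baseline, and Gaussian noise, clipped at
zero. Desk-scale defaults are 90×90 px, 3,000 frames at 30 Hz, 20 neurons
of mean radius 5.9 px spiking at 0.05/s, dendrites numbering 20% of
neurons. The generator does not model optics (point-spread blur, depth of
focus), shot noise statistics, indicator nonlinearity, or motion — passing
tests demonstrate the algorithmic contracts, not performance on real
recordings.

## Validation protocols and their rationale

**Threshold calibration.** th_SNR is a cross-validated parameter of the
method, not a constant. The mixing-recovery protocol calibrates it by grid
search over {4,5,6,7,8,10} on 10 training fixtures (seeds disjoint from the
evaluation set) and then scores 50 held-out fixtures; calibration selects
th = 8, about half the matched-filter single-event SNR of ≈ 17 at these
conditions.

**Fixture spike rate.** The mixing-recovery fixtures spike at 0.2/s (~20
events per 100-s trace) rather than the video default of 0.05/s. Mixing
coefficients are identified by source activity: warm-start experiments show
that for a source with only 1–2 events, coordinate descent started *at the
true factorization* converges to the same biased M that cold starts reach —
the regularized objective genuinely prefers absorbing a rarely-active
neighbor's events into the target component over paying for the mixing
entry. The low-rate regime therefore probes identifiability of the model,
not the correctness of the unmixer; residual contamination from weakly
active, under-determined neighbors is a known limitation of the method and
the reason detection thresholds well above the residual level matter.

**Downsampling equivalence.** M′ estimated from a strict subset of frames is
never bit-equal to M, so thresholded event boundaries jitter by a frame or
few, and at fast-indicator conditions (30 Hz, 0.2 s decay) a transient spans
only 1–2 decimated samples at ratio 4 and even event counts can change. The
equivalence protocol therefore uses noiseless slow-indicator fixtures
(decay 1 s, 0.1/s spiking; ~7 samples per decay time at ratio 4), detects
with the clean-trace pathway (the PSD noise estimate is undefined in
principle on noiseless traces), and checks event-level identity — equal
counts, boundaries within one frame, peaks inside the partner event. The
acceptance script reports the continuous version, the event-level F1
between the two paths' detections.

## Numerical choices and degenerate inputs

- All intermediate computation in float64 (videos stored float32).
- Quantile pair (Q25, Q50) with divisor 0.6745, linear-interpolation
  quantiles; a constant series has spread 0.
- Whitening noise floor 1e-9 (dead pixels map to zero); detection noise
  floor 1e-9.
- ε_zero = 1e-9 × quantile std of the normalized first row (= 1e-9);
  α floor 1e-4.
- A flat target trace (zero quantile std) is a per-neuron error; other
  neurons proceed.
- Per-neuron NMF seeds are `config.seed + neuron_id`, so results are
  independent of the worker count.
- Ties everywhere break toward the smaller index (matching step, plateau
  peaks, flat-bottomed minima, cross-validation grids).

## Known limitations

- Mixing entries of weakly active sources are under-determined (see above);
  expect residual contamination below a few noise units after unmixing.
- On scenes with little genuine overlap, unmixing can slightly degrade
  traces relative to plain background subtraction (over-subtraction of the
  target's own events assigned to neighbors); cross-validating α and th_SNR
  per dataset is the intended guard.
- The homomorphic filter cutoff, matched-filter template, and PSD band are
  package defaults, not universal constants; they should be matched to the
  indicator and acquisition rate.
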