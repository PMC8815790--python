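# calunmix

Decontamination of per-neuron calcium fluorescence traces by background
subtraction and **targeted non-negative matrix factorization**.

In calcium imaging, the fluorescence averaged over a neuron's spatial mask is
never just that neuron's signal: overlapping somata, passing axons and
dendrites, and spatially broad background fluctuations all leak into the
trace, producing false transients that corrupt downstream spike inference and
tuning analyses. `calunmix` removes this contamination one neuron at a time,
and ships the transient-detection and F1-scoring machinery needed to measure
how well it worked, plus a seeded synthetic-data generator so the whole
pipeline can be exercised without any microscope data.

## The model

For a target neuron, the pipeline builds a small set of measured traces: the
background-subtracted trace of the neuron itself (mean over its mask minus the
median over a surrounding background disk), the same for each *neighbor*
(neurons whose centroids fall inside that disk), and the trace of the *outside
region* (disk pixels belonging to no neuron). Stacked into a matrix, these
obey a linear mixing model

```
F_meas = M · F_sep
```

where `F_sep` holds the uncontaminated source traces and the non-negative
square mixing matrix `M` has unit diagonal; the off-diagonal entry `m_ij` is
the contamination of source `j` in measured trace `i`. `M` and `F_sep` are
estimated jointly by NMF with an L1/L2 penalty (ratio 0.5, coordinate
descent, NNDSVD initialization), minimizing

```
E = ½‖F_meas − M·F_sep‖²_Fro + α·[ l1(‖M‖₁+‖F_sep‖₁) + (1−l1)(‖M‖²_Fro+‖F_sep‖²_Fro) ]
```

The regularization weight α *floats*: if any separated trace comes out
identically zero (over-regularization), α is halved and the factorization is
repeated. A greedy five-step matching then permutes the components back onto
the input rows — preserving the product `M·F_sep` exactly — and the first row
of the rescaled `F_sep` is the decontaminated trace of the target neuron.

Transients are detected by thresholding an SNR-normalized trace (matched
filtering, density-mode baseline, spectral noise estimate) at `th_SNR`, with
peak-prominence screening at `th_SNR/3`; detected and ground-truth transients
are matched by the Hungarian algorithm on frame overlap and summarized as
precision, recall and `F1 = 2/(recall⁻¹ + precision⁻¹)`.

## Worked example

Unmix one synthetic fixture — four sources whose crosstalk coefficients are
drawn from 0.2–0.5, transient amplitude 10× the noise — and compare transient
detection on the contaminated and decontaminated target trace:

```python
from calunmix.validation import run_mixing_trial

trial = run_mixing_trial(seed=0, th_snr=8.0, alpha0=1.0)
print(f"final alpha: {trial.alpha_final}")
print(f"before unmixing: F1 = {trial.pre.f1:.3f} "
      f"({trial.pre.tp} of {trial.pre.n_detected} detections are true, "
      f"{trial.pre.n_gt} true events)")
print(f"after  unmixing: F1 = {trial.post.f1:.3f} "
      f"({trial.post.tp} of {trial.post.n_detected} detections are true)")
```

prints

```
final alpha: 1.0
before unmixing: F1 = 0.889 (20 of 24 detections are true, 21 true events)
after  unmixing: F1 = 0.976 (20 of 20 detections are true)
```

The contaminated trace shows four false transients leaked from the neighbors;
unmixing removes all of them without losing true events (one true event sits
below threshold in both). On video data the same flow is available from the
shell:

```bash
calunmix simulate --seed 1 --out sim/          # synthetic video + truth
calunmix run --video sim/video.h5 --masks sim/truth.h5 --alpha 1.0 --out traces.h5
calunmix detect --traces traces.h5 --th-snr 8.0 --out detected.csv
calunmix eval --detected detected.csv --gt sim/gt_transients.csv
```

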