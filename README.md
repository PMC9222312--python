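# fwavekit

Extraction of fibrillatory waves (F-waves) from **single-lead**
atrial-fibrillation ECG by optimized resonance-based signal decomposition.

During atrial fibrillation the P-wave is replaced by a continuous 3–12 Hz
fibrillatory waveform of a few tens of µV, buried under QRST complexes that
are 10–50× larger and overlap it in both time and frequency. Multi-lead
methods (spatiotemporal QRST cancellation, ICA) don't apply to wearable
single-lead recordings, and template subtraction breaks on ectopic beats.
`fwavekit` separates the two by *morphology* instead: the F-wave is a
sustained oscillation (high Q-factor), each QRST complex a one-shot
transient (low Q-factor).

The toolkit is aimed at biomedical-signal researchers benchmarking F-wave
extractors and at anyone needing a clean, tested implementation of
resonance-based sparse decomposition.

## Method

Given a trace `x`, two tunable Q-factor wavelet transform (TQWT)
dictionaries — synthesis operators `S1` (high Q, oscillatory) and `S2`
(low Q, transient) — define the morphological component analysis objective

    J(W1, W2) = ‖x − S1·W1 − S2·W2‖₂² + λ1‖W1‖₁ + λ2‖W2‖₁ ,

minimized by SALSA (an ADMM-type shrinkage algorithm; the data step is
solved exactly through the Parseval-frame identity `SᵢSᵢᵀ = I`). The
F-wave estimate is `x̂_f = S1·W1*`. The Q-factor pair is chosen by a
binary-coded genetic algorithm maximizing the kurtosis difference
`kurt(x_trn) − kurt(x_osc)` (population 40, crossover 0.67, per-bit
mutation 0.0175, 10% elitism); the published reference pair (6.42, 1.35)
is the default when the GA is not run. Regularization weights are
grid-calibrated on simulated records with known ground truth.

The package also provides: an exact (1e−15 round-trip) DFT-domain TQWT; a
parametric AF-ECG simulator (harmonic sawtooth F-wave model, types A/B/C at
4/8/12 Hz; synthetic ventricular beats with irregular RR and optional
ventricular premature beats; calibrated Gaussian noise); the standard
evaluation metrics (RMSE, NMSE, Welch PSD with 2-s Hann windows, dominant
frequency in 3–10 Hz, spectral concentration in 3–12 Hz); and the two
classic baselines, average beat subtraction (ABS) and beat-stacking PCA.
See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

```python
import numpy as np
from fwavekit import (compose_record, make_fwave_params, decompose,
                      DualQConfig, evaluate, abs_extract)

# 10 s of simulated AF ECG: type-A F-wave (4 Hz fundamental, lead II)
# on synthetic ventricular beats, no added noise
rec = compose_record(make_fwave_params("A", "II"), duration_s=10.0, seed=7)

res = decompose(rec.x, DualQConfig(q_high=9.0, q_low=1.0,
                                   lambda_osc=2.0, lambda_trn=1.4))
rep = evaluate(rec.fwave_truth, res.x_osc, rec.fs)
print(f"proposed: RMSE {rep.rmse:.1f} uV  NMSE {rep.nmse:.3f}  "
      f"DF {rep.dominant_freq:.1f} Hz  SC {rep.spectral_concentration:.3f}")

rep_abs = evaluate(rec.fwave_truth, abs_extract(rec), rec.fs)
print(f"ABS:      RMSE {rep_abs.rmse:.1f} uV  NMSE {rep_abs.nmse:.3f}  "
      f"DF {rep_abs.dominant_freq:.1f} Hz  SC {rep_abs.spectral_concentration:.3f}")
```

Output:

```
proposed: RMSE 34.1 uV  NMSE 0.731  DF 4.0 Hz  SC 0.959
ABS:      RMSE 47.3 uV  NMSE 1.410  DF 4.0 Hz  SC 0.947
```

The decomposition recovers the simulated 4.0 Hz dominant frequency exactly
and concentrates 96% of the extracted power in the fibrillatory band, with
a one-third lower error than average beat subtraction on the same record
(`x_osc + x_trn + residual` reconstructs the input bit-for-bit). A
scikit-learn-style estimator interface is also available
(`ResonanceDecomposer(...).fit(X).transform(X)`, `GeneticQOptimizer`,
`AverageBeatSubtraction`, `BeatPCA`), and a CLI exposes the same pipeline:

```
fwavekit simulate --type B --noise-mv 0.02 --seed 1 --out rec.tsv
fwavekit decompose --input rec.tsv --out components.tsv
fwavekit evaluate --input components.tsv
fwavekit optimize-q --input rec.tsv --report ga.txt
fwavekit benchmark --type B --noise-mv 0.02 --n-records 10 --out-csv bench.csv
```

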