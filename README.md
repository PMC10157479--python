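# amsanet

Real-time estimation of the **amplitude spectrum area (AMSA)** of a
ventricular-fibrillation (VF) ECG during *uninterrupted* chest
compressions.

AMSA is a well-established waveform measure that predicts defibrillation
success and can guide individualized resuscitation:

    AMSA = Σ A(f)·f  over 2 Hz ≤ f ≤ 48 Hz    [mV·Hz]

where `A(f)` is the single-sided amplitude spectrum of a Tukey-windowed
4-s ECG segment. The problem: chest-compression (CC) artifact occupies
0–20 Hz, exactly on top of the 0–18 Hz VF band, so the spectral estimate
is strongly biased during CPR and reliable AMSA has traditionally required
pausing compressions. This package implements and compares three
estimators on compression-corrupted segments:

| estimator | input | idea |
|---|---|---|
| `AMSA_FFT` | ECG | the spectral statistic applied directly (biased during CC) |
| `AMSA_ADF` | ECG + CPR reference | harmonic LMS canceller tracking the instantaneous compression frequency, then AMSA of the residual |
| `AMSA_CNN` | ECG only | 1-D CNN (N+1 conv blocks + 3 fully connected layers) regressing the clean AMSA directly from a two-channel differential transform of the corrupted waveform |

It is aimed at resuscitation-waveform researchers: it ships a synthetic
generator of VF, CC artifact and SNR-exact mixtures (no public clinical
recordings exist for this task), the full training/evaluation pipeline
(MAE/RMSE/PRD, Spearman r, Bland–Altman, ROC AUC with DeLong and
Hanley–McNeil comparisons), sliding-window continuous monitoring, and a
CLI. Waveforms are read and written as CSV or a minimal WFDB-compatible
format. See `docs/methods.md` for the full model description.

## Worked example

Fit the regressor on synthetic corrupted/uncorrupted segment pairs (40
subjects × 16 pairs at SNR ∈ {3, 0, −3, −6} dB, subject-disjoint splits)
and evaluate on held-out subjects — about a minute on one CPU:

```python
import numpy as np
from amsanet import DatasetConfig, build_dataset, amsa_fft
from amsanet.model import AmsaCnnRegressor

splits = build_dataset(DatasetConfig(seed=1, n_subjects=40, pairs_per_subject=16))
res = AmsaCnnRegressor(splits["train"]).fit(augment=False)
print(res.summary())

test = splits["test"]
rep = res.metrics(test)
naive = np.array([amsa_fft(p.corrupted) for p in test])
truth = np.array([p.amsa_true for p in test])
print(f"CNN   MAE {rep.mae:.2f} mV.Hz, Spearman r {rep.spearman_r:.3f}")
print(f"naive MAE {np.mean(np.abs(naive - truth)):.2f} mV.Hz")
```

prints

```
AMSA 1D-CNN regression results
==============================================
input length                499
conv blocks (pooled + 1)    5 + 1
kernel width W              11
channels C                  32
fully connected             (64, 32, 1)
parameters                  61825
training pairs              448
epochs x batch              30 x 256
final training MSE          3.9401 (mV.Hz)^2
==============================================
CNN   MAE 0.66 mV.Hz, Spearman r 0.933
naive MAE 4.68 mV.Hz
```

The network (kernel width 11, 5 pooled blocks + 1 global-pool block, 32
channels — the grid-search optima) cuts the naive spectral estimate's
held-out error by a factor of ~7 here and preserves the AMSA ranking
(Spearman r 0.93): exactly the property that matters when AMSA guides
shock timing. `res.predict_amsa(segment)` returns the estimate for a
single 4-s segment, clipped at 0 mV·Hz.

## Command line

```
amsanet simulate --config exp.yaml --out data/       # WFDB records + manifest
amsanet train    --dataset data/ --config exp.yaml --out run/
amsanet evaluate --dataset data/ --checkpoint run/checkpoint.npz --out eval/
amsanet monitor  --record rec --checkpoint run/checkpoint.npz --out amsa.csv
```

`evaluate` writes per-estimator, per-SNR metric tables (CSV + JSON);
`monitor` emits the continuous AMSA series (4-s window, 0.5-s step by
default) for both `AMSA_FFT` and `AMSA_CNN`. Every stage logs its seed
and config hash and is bit-reproducible.

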