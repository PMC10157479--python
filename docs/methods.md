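# Methods

## Problem and model

Amplitude spectrum area (AMSA) summarises a 4-s ventricular-fibrillation
(VF) ECG segment as

    AMSA = Σ_k A(f_k) · f_k ,   2 Hz ≤ f_k ≤ 48 Hz   [mV·Hz]

with `A(f_k)` the single-sided amplitude spectrum of the Tukey-windowed
segment. AMSA predicts defibrillation success, but chest-compression (CC)
artifact — quasi-periodic, 0–20 Hz, amplitude above the VF — completely
overlaps the VF band (0–18 Hz), so the naive spectral estimate is biased
upward during CPR. The package provides three estimators of the *clean*
AMSA from a corrupted segment:

* **AMSA_FFT** — the spectral statistic applied directly (biased during CC;
  the reference method between compressions);
* **AMSA_ADF** — a harmonic least-mean-squares (LMS) canceller locked to
  the instantaneous compression frequency from a CPR reference channel,
  followed by AMSA of the residual;
* **AMSA_CNN** — a 1-D convolutional network regressing AMSA directly from
  the corrupted waveform, no reference channel needed.

## Spectral conventions

* Window: Tukey, taper ratio 0.2 (a common choice for AMSA; the ratio is
  configurable). Amplitude normalisation `A = 2|X_k| / Σw` compensates the
  window gain, so a 1 mV sinusoid contributes 1 mV at its bin.
* No zero padding; 4-s / 250 Hz segments give 0.25 Hz bins.
* The band sum is **not** multiplied by the bin width by default: the
  classic AMSA convention gives clinical values of roughly 2–25 mV·Hz. The
  literal integral approximation (`× fs/n`) is available as
  `SpectralConfig(df_weighting=True)`; it only rescales by 0.25.
* Baseline removal: second-order Butterworth high-pass at 0.5 Hz, applied
  causally (`lfilter`) because the intended use is real-time monitoring.
  Its 1 mV step response decays with a ~0.3 s time constant; DC rejection
  is judged on the settled part of a segment.

## Synthetic data generator

No public clinical recordings exist for this problem, so the generator
emulates the study conditions and every experiment runs on it:

* **VF**: `n_components` (3) narrowband oscillators with instantaneous
  frequency performing a reflected random walk inside the dominant band
  (3–7 Hz, inside the physiologic 2–18 Hz), a smooth lognormal amplitude
  envelope (σ = 0.4, ~0.5 Hz bandwidth), plus 1/f noise 20 dB below the
  oscillator power. The median per-second peak-to-peak amplitude is scaled
  to a target drawn from 0.2–1.5 mV (the VF rhythm criterion requires
  > 0.1 mV). Generated VF passes the `is_vf` rule: amplitude criterion
  plus "disorganized", operationalised as no normalised autocorrelation
  peak above 0.75 at lags 0.25–1.5 s (the QRS-periodicity range of
  organized rhythms) — a cheap surrogate for annotator judgement.
* **CC artifact**: concatenated compression cycles at a record-level rate
  drawn from 80–130/min, lognormal cycle-length jitter (CV 0.05). Within a
  cycle the waveform is a harmonic series k = 1..5 with 1/k magnitudes,
  per-cycle lognormal magnitude modulation (σ = 0.2) to mimic the
  heterogeneity of real CPR artifacts, and fixed per-record phases; each
  harmonic completes an integer number of periods per cycle, so the
  concatenation is continuous. Peak-to-peak target 1–5 mV.
* **Mixing**: `mix_at_snr` scales the artifact by
  `g = sqrt((P_vf/P_cc)/10^(SNR/10))` (powers are raw mean squares, taken
  before any filtering), achieving the requested SNR exactly; the study
  levels are {3, 0, −3, −6} dB. A `concat` mode instead corrupts the
  *adjacent* 4-s stretch of a longer VF record, reproducing the
  adjacent-window pairing of real recordings, where the label carries the
  natural quasi-stationarity error.
* **Outcomes**: shock success is simulated as
  Bernoulli(logistic(β₀ + β₁·log AMSA)), β₀ = −3, β₁ = 1.5, giving
  realistic mid-range success rates and a testable AUC target.
* Datasets are built per synthetic subject (subject-level amplitude
  anchor for between-subject heterogeneity), SNR levels cycled for exact
  balance, splits subject-disjoint, and the whole build is
  byte-deterministic from one seed.

What the generator does **not** emulate: non-additive electrode-motion
nonlinearities, ventilation artifact, rhythm transitions within a segment,
device filtering chains, and the long-tailed AMSA distribution of real
patients. Passing tests therefore demonstrate correctness of the method
and its implementation under controlled conditions, not clinical
performance.

## LMS baseline

The artifact model is a harmonic series at the instantaneous compression
frequency `f0(n)` (inverse of each cycle length from the reference
channel), with per-sample phase *accumulation* `φ(i) = φ(i−1) + f0(i)/fs`
so that rate steps cause no phase jumps. Coefficients adapt by normalised
LMS on the residual; with step 0 the filter is an exact pass-through.

The step size is unstated in the method being implemented, so it is a
design parameter here. The default **μ = 0.05 (normalised)** sits at the
knee between convergence speed and misadjustment: it yields ~29 dB
steady-state suppression of a stationary artifact while maximising
full-segment SNR improvement on 0 dB mixtures. Two structural limits are
worth recording. First, the convergence transient (~1 s) always leaks
broadband energy into the residual, which the frequency-weighted AMSA
statistic amplifies; a pure stationary artifact therefore retains roughly
a quarter to a half of its AMSA after cancellation even when its *power*
is suppressed by ≥ 15 dB. Second, at 0 dB the canceller inevitably
removes genuine VF energy near the artifact harmonics (harmonics 2–4 of a
~2 Hz fundamental sit inside the 3–7 Hz dominant VF band): a batch
least-squares fit of the same basis — the ideal time-invariant canceller
and an upper bound for LMS — achieves only ~10 dB mean / 5 dB minimum SNR
improvement over 20 trials, and single-pass causal LMS lands near 5 dB.
This is the quantitative reason the CNN estimator outperforms the
adaptive-filter baseline.

## CNN estimator

Input: after the 0.5 Hz high-pass, the segment S (length L) is split into
two lag-2 difference channels, `ch1(i) = S(2i+1) − S(2i−1)` and
`ch2(i) = S(2i+2) − S(2i)` (1-based), length ⌊L/2⌋ − 1 = 499 for 4-s
segments. Differencing removes DC exactly and whitens toward the
frequency-weighted content AMSA measures. The printed channel index range
(up to L/2) overruns the last valid sample; channels are built to
⌊L/2⌋ − 1.

Architecture (defaults are the grid-search optima W = 11, N = 5, C = 32):
N blocks of {same-padded conv(W, C) → batch-norm → leaky-ReLU(0.01) →
max-pool(2, stride 2, ceil)}, one further block with *global* max-pool
and dropout 0.5, then fully connected layers 64–32–1 with a linear
output. Temporal length after block n is ⌈499/2ⁿ⌉. The fully connected
widths, dropout and slope are unstated in the published protocol and fixed here as
configuration defaults. The output is clipped at 0 at prediction time
only; the MSE fit itself is unconstrained.

Training: Adam at 1e-3 on MSE. Both members of each segment pair enter
with the shared clean-AMSA label. Conv weights use Xavier-normal init and
dense weights uniform [−0.1, 0.1] — the published protocol names both
initialisers without mapping them to layer types; this mapping is ours.
Augmentation (optional, training split only, applied once up front for
determinism) multiplies the data ×8 via the negate/reverse/swap group,
which preserves per-channel magnitude spectra and hence the label.
Batch-norm in the global-pool block is retained (the published description
is ambiguous); no early stopping — a fixed epoch budget is used.

The network itself is a compact NumPy engine (`_nn.py`): shift-accumulated
BLAS matmuls for convolution, reverse-mode gradients for every layer, and
an Adam loop, all driven by one `numpy.random.Generator` so training is
bit-reproducible for a fixed seed. Gradients are verified against central
differences in the test suite.

### Problem sizes and protocol defaults

The published protocol (batch 1024, 50 epochs, five-fold CV over ~6600
pairs) is available via `FULL_SCALE_TRAIN`; the package defaults are the
desk scale used throughout the tests: batch 256, 30 epochs, and a
synthetic dataset of 60 subjects × 36 pairs (2160 pairs, ~1500 training
pairs after the 70/15/15 subject split). At this scale the default
architecture trains in a few minutes on one CPU and, on held-out
subjects, roughly quarters the naive spectral estimate's MAE at +3 dB and
improves it by an order of magnitude at −6 dB, with Spearman r ≈ 0.99 at
0 dB. The end-to-end test trains without augmentation (the ×8 blow-up
changes runtime, not the qualitative ordering, which is what the test
pins down).

## Evaluation

MAE, RMSE and PRD = `sqrt(Σ(y−ŷ)² / Σy²)·100 %` — the square root is part
of the standard PRD definition and is used here even though one printed
form of the formula omits it; this keeps the MAE/RMSE/PRD triple mutually
consistent (PRD may still exceed 100 % for badly matched estimates).
Spearman correlation uses average ranks for ties. Bland–Altman agreement
reports bias and mean ± 1.96 sample-SD limits. ROC AUC uses the
Mann–Whitney identity with half-credit for ties and a Hanley–McNeil
standard error; paired AUC comparison defaults to DeLong's method (fully
specified, no table lookups), with the Hanley–McNeil 1983 z-test —
correlation adjustment approximated by the mean within-class Pearson
correlation of the two score vectors — available for fidelity.

## Numerical and degenerate-input choices

* Zero-power artifact in `mix_at_snr`, single-onset compression
  references, empty training sets, single-class outcome labels and
  all-zero PRD denominators raise typed errors rather than propagating
  NaNs.
* `K·max(f0) ≥ fs/2` (aliased harmonic model) is rejected.
* Pair extraction anchors windows at CC-state transitions; windows never
  straddle a transition, and a configurable guard gap can trim samples
  next to the transition. Records with no qualifying window yield an
  empty list, not an error.
* Grid-search ties break toward the smaller parameter count; invalid
  combinations (input shorter than 2^N) are skipped with a logged
  warning.
* WFDB I/O uses format 32 with gain 10⁶/mV, making round trips exact to
  5·10⁻⁷ mV; the reader supports exactly the subset the writer emits.

## Known limitations

* The synthetic generator is a stand-in for clinical recordings; the
  clinical headline numbers of the underlying study are not reproducible
  from it and are not claimed.
* The LMS baseline's SNR improvement at 0 dB is bounded near 5 dB by the
  VF/artifact spectral overlap (see above); reference-free or
  longer-window cancellers are out of scope.
* The CNN input length is fixed at training time; records at other rates
  must be resampled to 250 Hz first.
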