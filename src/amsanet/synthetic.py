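"""Synthetic VF signals, compression artifacts and SNR-controlled mixtures.

Clinical resuscitation recordings are not publicly deposited, so every
downstream stage is exercised on synthetic data that emulates the study
conditions:

* **VF** is quasi-stationary and disorganized, with spectral energy in
  0-18 Hz and a median peak-to-peak amplitude above 0.1 mV.  The generator
  sums a few narrowband oscillators whose instantaneous frequency drifts
  slowly inside the dominant band (default 3-7 Hz), modulated by a smooth
  random envelope, plus a 1/f broadband noise floor.
* **Chest-compression (CC) artifact** is quasi-periodic with energy at the
  harmonics of the compression rate (fundamental ~1.3-2.2 Hz, band
  ~0-20 Hz) and amplitude exceeding the VF.  Each compression cycle is a
  harmonic series with 1/k^decay magnitudes, per-cycle lognormal magnitude
  modulation (~+/-20%) to mimic the heterogeneity of real CPR artifacts,
  and cycle-length jitter.
* **Corrupted VF** mixes the two additively with an exact power-ratio
  scale: the artifact is multiplied by g = sqrt((P_vf / P_cc) / 10^(SNR/10)),
  so the realised clean-to-artifact power ratio equals the requested SNR
  (in dB) to machine precision.  The study levels are {3, 0, -3, -6} dB.

Powers are mean-square amplitudes of the raw (pre-filter) segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig
from scipy.special import expit

from .core import ANALYSIS_FS, CompressionReference, EcgSegment, SegmentPair, SegmentRole
from .exceptions import ConfigurationError, InvalidInputError

STUDY_SNR_LEVELS_DB = (3.0, 0.0, -3.0, -6.0)


@dataclass(frozen=True)
class VfGenParams:
    """Parameters of the synthetic VF generator.

    dominant_freq_range : (Hz, Hz)
        Band containing the oscillators' instantaneous frequencies; must
        sit inside [2, 18] Hz.
    n_components : int
        Number of narrowband oscillators summed.
    freq_drift_sd : Hz / sqrt(s)
        Scale of the random-walk drift of each instantaneous frequency.
    amplitude_pp_range : (mV, mV)
        Range of the target median per-second peak-to-peak amplitude.
    noise_floor_db : dB
        Power of the 1/f noise floor relative to the oscillator sum.
    """

    dominant_freq_range: tuple[float, float] = (3.0, 7.0)
    n_components: int = 3
    freq_drift_sd: float = 0.3
    amplitude_pp_range: tuple[float, float] = (0.2, 1.5)
    noise_floor_db: float = -20.0

    def validate(self) -> None:
        lo, hi = self.dominant_freq_range
        if not (2.0 <= lo < hi <= 18.0):
            raise ConfigurationError(
                f"dominant_freq_range {self.dominant_freq_range} must sit in [2, 18] Hz")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        alo, ahi = self.amplitude_pp_range
        if not (0 < alo <= ahi):
            raise ConfigurationError("amplitude_pp_range must be positive and ordered")
        if ahi <= 0.1:
            raise ConfigurationError(
                "amplitude range must allow median peak-to-peak > 0.1 mV (VF criterion)")


@dataclass(frozen=True)
class CcGenParams:
    """Parameters of the synthetic chest-compression artifact generator.

    rate_range : (min, max) compressions/min
        The record's mean compression rate is drawn here (study CPR rates
        cluster at 80-130/min, i.e. fundamentals of ~1.3-2.2 Hz).
    cycle_jitter_cv : float
        Coefficient of variation of per-cycle length jitter.
    n_harmonics, harmonic_decay :
        Harmonic series k = 1..n_harmonics with 1/k^decay magnitudes.
    amplitude_pp_range : (mV, mV)
        Target peak-to-peak range; artifacts dominate the VF amplitude.
    """

    rate_range: tuple[float, float] = (80.0, 130.0)
    cycle_jitter_cv: float = 0.05
    n_harmonics: int = 5
    harmonic_decay: float = 1.0
    amplitude_pp_range: tuple[float, float] = (1.0, 5.0)
    magnitude_mod_sigma: float = 0.2

    def validate(self) -> None:
        lo, hi = self.rate_range
        if not (50.0 <= lo <= hi <= 200.0):
            raise ConfigurationError(
                f"compression rate range {self.rate_range} outside [50, 200]/min")
        if self.n_harmonics < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        if self.cycle_jitter_cv < 0:
            raise ConfigurationError("cycle_jitter_cv must be >= 0")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic link from log-AMSA to defibrillation-shock success.

    P(success | AMSA = a) = logistic(beta0 + beta1 * log(a)); beta1 > 0 so
    higher AMSA implies higher success probability.
    """

    beta0: float = -3.0
    beta1: float = 1.5

    def __post_init__(self) -> None:
        if not (self.beta1 > 0):
            raise ConfigurationError("beta1 must be positive")

    def success_probability(self, amsa: np.ndarray) -> np.ndarray:
        amsa = np.asarray(amsa, dtype=float)
        if np.any(amsa <= 0):
            raise InvalidInputError("AMSA values must be positive")
        return expit(self.beta0 + self.beta1 * np.log(amsa))


def _median_pp_per_second(x: np.ndarray, fs: float) -> float:
    n_sec = max(int(len(x) // fs), 1)
    step = int(fs)
    pps = [np.ptp(x[i * step:(i + 1) * step]) for i in range(n_sec)]
    return float(np.median(pps))


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    return pink / np.std(pink)


def generate_vf(
    params: VfGenParams = VfGenParams(),
    duration: float = 4.0,
    rng_seed: int | np.random.SeedSequence = 0,
    fs: float = ANALYSIS_FS,
) -> EcgSegment:
    """Generate a quasi-stationary synthetic VF segment (role UVF).

    Deterministic for a fixed seed.  The returned waveform passes the
    VF amplitude/disorganization rule :func:`is_vf`.
    """
    params.validate()
    if duration < 4.0:
        raise ConfigurationError("duration must be >= 4 s")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * fs))
    t_step = 1.0 / fs
    lo, hi = params.dominant_freq_range

    x = np.zeros(n)
    for _ in range(params.n_components):
        f0 = rng.uniform(lo, hi)
        drift = np.cumsum(rng.standard_normal(n)) * params.freq_drift_sd * np.sqrt(t_step)
        inst_f = f0 + drift
        # reflect the random walk back into the dominant band
        width = hi - lo
        inst_f = lo + np.abs((inst_f - lo) % (2 * width) - width)
        phase = 2 * np.pi * np.cumsum(inst_f) * t_step + rng.uniform(0, 2 * np.pi)
        # smooth positive envelope: lognormal (sigma 0.4) with ~0.5 Hz bandwidth
        b, a = _sig.butter(2, 0.5, fs=fs)
        mod = _sig.filtfilt(b, a, rng.standard_normal(n))
        env = np.exp(0.4 * mod / max(np.std(mod), 1e-12))
        env /= np.mean(env)
        x += rng.uniform(0.5, 1.0) * env * np.sin(phase)

    noise = _one_over_f_noise(n, rng)
    noise *= np.std(x) * 10 ** (params.noise_floor_db / 20.0)
    x = x + noise

    target_pp = rng.uniform(*params.amplitude_pp_range)
    x *= target_pp / _median_pp_per_second(x, fs)
    return EcgSegment(samples=x, fs=fs, role=SegmentRole.UVF)


def generate_cc_artifact(
    params: CcGenParams = CcGenParams(),
    duration: float = 4.0,
    rng_seed: int | np.random.SeedSequence = 0,
    fs: float = ANALYSIS_FS,
) -> tuple[EcgSegment, CompressionReference]:
    """Generate a quasi-periodic compression artifact and its cycle onsets.

    The record's mean rate is drawn from ``rate_range``; each cycle's
    length gets lognormal jitter of CV ``cycle_jitter_cv``.  Within a cycle
    of length T the waveform is sum_k m_k / k^decay * cos(2 pi k tau + phi_k)
    with tau the cycle-local phase in [0, 1), phi_k fixed per record and
    m_k per-cycle lognormal modulation; because each harmonic completes an
    integer number of periods per cycle, the concatenation is continuous.
    """
    params.validate()
    if duration < 4.0:
        raise ConfigurationError("duration must be >= 4 s")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * fs))

    rate = rng.uniform(*params.rate_range)
    mean_cycle = 60.0 / rate
    onsets = [0.0]
    while onsets[-1] < duration:
        jitter = np.exp(rng.normal(0.0, params.cycle_jitter_cv)) if params.cycle_jitter_cv else 1.0
        cyc = float(np.clip(mean_cycle * jitter, 0.3, 1.2))
        onsets.append(onsets[-1] + cyc)
    onsets = np.asarray(onsets)

    ks = np.arange(1, params.n_harmonics + 1)
    base_mag = 1.0 / ks.astype(float) ** params.harmonic_decay
    phis = rng.uniform(0, 2 * np.pi, size=params.n_harmonics)

    t = np.arange(n) / fs
    x = np.zeros(n)
    for t_on, t_off in zip(onsets[:-1], onsets[1:]):
        sel = (t >= t_on) & (t < t_off)
        if not np.any(sel):
            continue
        tau = (t[sel] - t_on) / (t_off - t_on)
        mags = base_mag * np.exp(rng.normal(0.0, params.magnitude_mod_sigma,
                                            size=params.n_harmonics))
        x[sel] = np.sum(mags[:, None] * np.cos(2 * np.pi * ks[:, None] * tau + phis[:, None]),
                        axis=0)

    target_pp = rng.uniform(*params.amplitude_pp_range)
    x *= target_pp / np.ptp(x)
    seg = EcgSegment(samples=x, fs=fs, role=SegmentRole.CC)
    ref = CompressionReference(onset_times=onsets, fs=fs)
    return seg, ref


def mix_at_snr(clean: EcgSegment, artifact: EcgSegment, snr_db: float) -> EcgSegment:
    """Additively corrupt ``clean`` with ``artifact`` at an exact SNR (dB).

    The artifact is scaled by g = sqrt((P_clean / P_artifact) / 10^(SNR/10))
    with P the mean-square amplitude, so 10 log10(P_clean / P_scaled)
    equals ``snr_db`` in closed form.
    """
    if clean.fs != artifact.fs or clean.n != artifact.n:
        raise InvalidInputError("clean and artifact must share length and rate")
    p_clean = float(np.mean(clean.samples ** 2))
    p_art = float(np.mean(artifact.samples ** 2))
    if p_art == 0.0:
        raise InvalidInputError("artifact has zero power; cannot scale to a target SNR")
    g = np.sqrt((p_clean / p_art) / 10.0 ** (snr_db / 10.0))
    return replace(clean, samples=clean.samples + g * artifact.samples,
                   role=SegmentRole.SVF)


def measured_snr_db(clean: EcgSegment, scaled_artifact: EcgSegment) -> float:
    """10 log10 of clean power over artifact power, in dB."""
    p_c = float(np.mean(clean.samples ** 2))
    p_a = float(np.mean(scaled_artifact.samples ** 2))
    return 10.0 * np.log10(p_c / p_a)


def is_asystole(segment: EcgSegment) -> bool:
    """Isoelectric rule: overall peak-to-peak amplitude below 0.1 mV."""
    return bool(np.ptp(segment.samples) < 0.1)


def is_vf(segment: EcgSegment, organization_threshold: float = 0.75) -> bool:
    """Amplitude + disorganization rule for ventricular fibrillation.

    True iff the median of per-1-s peak-to-peak amplitudes exceeds 0.1 mV
    and the rhythm is disorganized.  Disorganization is operationalised as
    the absence of a dominant normalised-autocorrelation peak above
    ``organization_threshold`` at lags of 0.25-1.5 s (the QRS-regularity
    range of organized rhythms at 40-240 beats/min); this is a cheap,
    testable surrogate for annotator judgement of QRS regularity.
    """
    x = segment.samples - np.mean(segment.samples)
    if _median_pp_per_second(segment.samples, segment.fs) <= 0.1:
        return False
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return False
    lags = np.arange(int(0.25 * segment.fs), int(1.5 * segment.fs) + 1)
    lags = lags[lags < segment.n]
    ac = np.array([np.dot(x[:-k], x[k:]) / denom for k in lags])
    return bool(np.max(ac, initial=0.0) <= organization_threshold)


def simulate_shock_outcomes(
    amsa_values: np.ndarray,
    model: OutcomeModel = OutcomeModel(),
    rng_seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Bernoulli shock-success labels from the logistic outcome model."""
    p = model.success_probability(amsa_values)
    rng = np.random.default_rng(rng_seed)
    return (rng.random(p.shape) < p).astype(int)


@dataclass
class DatasetConfig:
    """Size, mixing and split parameters of a synthetic dataset build."""

    seed: int = 0
    n_subjects: int = 24
    pairs_per_subject: int = 8
    snr_levels_db: tuple[float, ...] = STUDY_SNR_LEVELS_DB
    split_fractions: dict = field(
        default_factory=lambda: {"train": 0.7, "validation": 0.15, "test": 0.15})
    vf: VfGenParams = field(default_factory=VfGenParams)
    cc: CcGenParams = field(default_factory=CcGenParams)
    mode: str = "mix"  # "mix" (Eq-style additive SNR) or "concat" (adjacent-window layout)
    duration: float = 4.0
    fs: float = ANALYSIS_FS

    def validate(self) -> None:
        if abs(sum(self.split_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if self.mode not in {"mix", "concat"}:
            raise ConfigurationError(f"unknown dataset mode {self.mode!r}")
        self.vf.validate()
        self.cc.validate()


def build_dataset(config: DatasetConfig) -> dict[str, list[SegmentPair]]:
    """Build subject-disjoint train/validation/test splits of segment pairs.

    Every synthetic subject gets ``pairs_per_subject`` corrupted/uncorrupted
    pairs whose SNR levels cycle through ``snr_levels_db`` (phase-shifted
    per subject so levels stay balanced overall).  In ``mix`` mode the
    corrupted member is the clean member plus a scaled artifact, so the
    label is exact; in ``concat`` mode the corrupted member is the
    *adjacent* 4-s stretch of a longer VF record plus artifact, emulating
    the adjacent-window pairing of real recordings (the label then carries
    the natural quasi-stationarity error).  Subject ids never cross splits
    and the build is byte-deterministic for a fixed seed.
    """
    from .spectral import amsa_fft

    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(config.n_subjects)
    rng = np.random.default_rng(root.spawn(1)[0])

    subjects = [f"subj{idx:04d}" for idx in range(config.n_subjects)]
    order = rng.permutation(config.n_subjects)
    names = list(config.split_fractions)
    fracs = np.array([config.split_fractions[k] for k in names])
    bounds = np.round(np.cumsum(fracs) * config.n_subjects).astype(int)
    split_of: dict[str, str] = {}
    start = 0
    for name, stop in zip(names, bounds):
        for j in order[start:stop]:
            split_of[subjects[j]] = name
        start = stop

    splits: dict[str, list[SegmentPair]] = {name: [] for name in names}
    for s_idx, (subj, sseq) in enumerate(zip(subjects, subj_seeds)):
        pair_seeds = sseq.spawn(config.pairs_per_subject)
        srng = np.random.default_rng(sseq)
        # per-subject amplitude anchor for between-subject heterogeneity
        lo, hi = config.vf.amplitude_pp_range
        anchor = srng.uniform(lo, hi)
        pp_range = (max(lo, 0.8 * anchor), min(hi, 1.2 * anchor))
        vf_params = replace(config.vf, amplitude_pp_range=pp_range)
        for p_idx, pseq in enumerate(pair_seeds):
            snr = config.snr_levels_db[
                (s_idx * config.pairs_per_subject + p_idx) % len(config.snr_levels_db)]
            gen_seeds = pseq.spawn(2)
            if config.mode == "mix":
                clean = generate_vf(vf_params, config.duration, gen_seeds[0], config.fs)
                art, ref = generate_cc_artifact(config.cc, config.duration,
                                                gen_seeds[1], config.fs)
                corrupted = mix_at_snr(clean, art, snr)
            else:
                long_vf = generate_vf(vf_params, 2 * config.duration,
                                      gen_seeds[0], config.fs)
                clean = replace(long_vf.slice_seconds(config.duration,
                                                      2 * config.duration),
                                role=SegmentRole.UVF)
                first = replace(long_vf.slice_seconds(0.0, config.duration),
                                role=SegmentRole.UVF)
                art, ref = generate_cc_artifact(config.cc, config.duration,
                                                gen_seeds[1], config.fs)
                corrupted = replace(mix_at_snr(first, art, snr), role=SegmentRole.CVF)
            clean = replace(clean, subject_id=subj)
            corrupted = replace(corrupted, subject_id=subj)
            splits[split_of[subj]].append(
                SegmentPair(corrupted=corrupted, uncorrupted=clean,
                            amsa_true=amsa_fft(clean), subject_id=subj, snr_db=snr,
                            cc_ref=ref))
    return splits
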