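"""Harmonic LMS adaptive cancellation of chest-compression artifact.

The comparison baseline models the compression artifact as a harmonic
series locked to the instantaneous compression frequency f0(n) derived
from a CPR reference channel:

    s_cc_hat(i) = sum_{k=1..K} a_k(i) cos(2 pi k phi(i)) + b_k(i) sin(2 pi k phi(i))

where the phase phi is *accumulated*, phi(i) = phi(i-1) + f0(i)/fs, so
step changes in f0 at cycle boundaries cause no phase jumps and the
estimate stays continuous.  The coefficients a_k, b_k adapt by the (by
default normalised) least-mean-squares rule on the residual
e(i) = s(i) - s_cc_hat(i); the residual is the estimated VF signal whose
AMSA is the baseline estimate ``amsa_adf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CompressionReference, EcgSegment, SegmentRole
from .exceptions import ConfigurationError, InvalidInputError
from .spectral import DEFAULT_SPECTRAL, SpectralConfig, amsa_fft


@dataclass(frozen=True)
class LmsConfig:
    """LMS canceller parameters.

    n_harmonics : int
        K, the number of cos/sin harmonic pairs (default 5: covers the
        ~0-20 Hz artifact band at a ~2 Hz compression fundamental).
    step_size : float
        Adaptation step mu.  With ``normalized=True`` (default) the update
        is scaled by the instantaneous basis power, making stability
        independent of harmonic count; stable for 0 < mu < 2.  The default
        0.05 sits at the knee between convergence speed (larger mu) and
        cancellation of genuine VF energy near the artifact harmonics
        (misadjustment, smaller mu) for 4-s segments.
    coeff_init : float
        Initial value of every a_k, b_k.
    """

    n_harmonics: int = 5
    step_size: float = 0.05
    coeff_init: float = 0.0
    normalized: bool = True

    def validate(self) -> None:
        if self.n_harmonics < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        if not (self.step_size >= 0):
            raise ConfigurationError("step_size must be non-negative")


DEFAULT_LMS = LmsConfig()


def instantaneous_frequency(
    ref: CompressionReference, n_samples: int, fs: float
) -> np.ndarray:
    """Per-sample compression frequency f0 (Hz) from cycle onsets.

    f0(i) = 1 / cycle_length of the cycle containing sample i; samples
    before the first onset take the first cycle's value and samples after
    the last onset take the last cycle's value.
    """
    onsets = ref.onset_times
    if onsets.size < 2:
        raise InvalidInputError("need at least 2 compression onsets to derive f0")
    cycle_f = 1.0 / np.diff(onsets)
    t = np.arange(n_samples) / fs
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, cycle_f.size - 1)
    return cycle_f[idx]


def lms_cancel(
    corrupted: EcgSegment,
    f0: np.ndarray,
    cfg: LmsConfig = DEFAULT_LMS,
) -> tuple[EcgSegment, EcgSegment]:
    """Adaptively cancel the harmonic artifact; return (residual, artifact estimate).

    Runs causally over the segment once, coefficients starting at
    ``cfg.coeff_init``.  With ``step_size = 0`` the coefficients never move
    and the residual equals the input (minus the constant-init model).
    """
    cfg.validate()
    f0 = np.asarray(f0, dtype=float)
    if f0.shape[0] != corrupted.n:
        raise InvalidInputError("f0 track length must equal the segment length")
    fs = corrupted.fs
    if cfg.n_harmonics * float(np.max(f0)) >= fs / 2:
        raise ConfigurationError(
            f"K * max(f0) = {cfg.n_harmonics * np.max(f0):.1f} Hz reaches the "
            f"Nyquist rate {fs / 2:.1f} Hz (aliasing)")

    x = corrupted.samples
    n = corrupted.n
    k = np.arange(1, cfg.n_harmonics + 1)
    a = np.full(cfg.n_harmonics, float(cfg.coeff_init))
    b = np.full(cfg.n_harmonics, float(cfg.coeff_init))
    phase = np.cumsum(f0) / fs  # cycles; accumulated so f0 steps keep phase continuous
    residual = np.empty(n)
    artifact = np.empty(n)
    mu = cfg.step_size
    eps = 1e-12
    for i in range(n):
        arg = 2 * np.pi * k * phase[i]
        c, s = np.cos(arg), np.sin(arg)
        y = float(a @ c + b @ s)
        e = x[i] - y
        artifact[i] = y
        residual[i] = e
        if mu:
            if cfg.normalized:
                step = mu * e / (eps + float(c @ c + s @ s))
            else:
                step = mu * e
            a += step * c
            b += step * s
    est_vf = corrupted.with_samples(residual, role=SegmentRole.UNKNOWN)
    art = corrupted.with_samples(artifact, role=SegmentRole.CC)
    return est_vf, art


def amsa_adf(
    corrupted: EcgSegment,
    ref: CompressionReference,
    lms_cfg: LmsConfig = DEFAULT_LMS,
    spectral_cfg: SpectralConfig = DEFAULT_SPECTRAL,
) -> float:
    """AMSA of the LMS-cancelled residual (the adaptive-filter baseline)."""
    f0 = instantaneous_frequency(ref, corrupted.n, corrupted.fs)
    est_vf, _ = lms_cancel(corrupted, f0, lms_cfg)
    return amsa_fft(est_vf, spectral_cfg)
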