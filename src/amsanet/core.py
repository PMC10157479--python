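"""Domain types and waveform utilities shared by every pipeline stage.

The central container is :class:`EcgSegment`, a fixed-rate single-lead ECG
waveform in millivolts.  Analysis segments are 4 s long at 250 Hz (1000
samples); recordings at other rates are brought to 250 Hz with
:func:`resample_to` before analysis.  Segment roles follow the study's
taxonomy for ventricular-fibrillation (VF) resuscitation waveforms:

``UVF``
    uncorrupted VF, no chest compressions (CC).
``AVF``
    the adjacent uncorrupted VF segment of a UVF segment.
``CVF``
    VF corrupted by real chest-compression artifact.
``CC``
    pure compression artifact (underlying rhythm asystole).
``SVF``
    simulated corrupted VF: UVF plus a scaled pure artifact at known SNR.
``PVF``
    uncorrupted pre-shock VF.

All sample indexing is 0-based half-open internally; published equations
that count from 1 are translated in the docstring of each operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _sig

from .exceptions import ConfigurationError, InvalidInputError

ANALYSIS_FS = 250.0
ANALYSIS_DURATION_S = 4.0


class SegmentRole(str, Enum):
    UVF = "UVF"
    AVF = "AVF"
    CVF = "CVF"
    CC = "CC"
    SVF = "SVF"
    PVF = "PVF"
    UNKNOWN = "UNKNOWN"


@dataclass
class EcgSegment:
    """A fixed-rate ECG waveform in mV.

    Parameters
    ----------
    samples : array-like of float
        Waveform samples in millivolts; must be finite.
    fs : float
        Sampling rate in Hz, > 0.  Default 250.
    role : SegmentRole
        Semantic role tag (see module docstring).
    subject_id : str or None
        Opaque subject identifier; used to keep dataset splits
        subject-disjoint.
    t0 : float
        Start time of the segment in seconds within its source record.
    """

    samples: np.ndarray
    fs: float = ANALYSIS_FS
    role: SegmentRole = SegmentRole.UNKNOWN
    subject_id: str | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidInputError("EcgSegment samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("EcgSegment samples must be finite")
        if not (self.fs > 0):
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        self.role = SegmentRole(self.role)

    @property
    def n(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, role: SegmentRole | None = None) -> "EcgSegment":
        """Copy of this segment with new samples (and optionally a new role)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       role=self.role if role is None else role)

    def slice_seconds(self, start: float, stop: float) -> "EcgSegment":
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        if not (0 <= i0 < i1 <= self.n):
            raise InvalidInputError(
                f"slice [{start}, {stop}) s outside segment of {self.duration} s")
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass
class CompressionReference:
    """Per-compression cycle onsets derived from a CPR reference channel.

    ``onset_times`` are strictly increasing times (s) of compression-cycle
    starts.  Consecutive differences must lie in [0.3, 1.2] s, i.e. rates
    of 50-200 compressions/min.  The instantaneous compression frequency
    f0 of the cycle starting at onset k is ``1 / (onset[k+1] - onset[k])``.
    """

    onset_times: np.ndarray
    fs: float = ANALYSIS_FS

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.onset_times.ndim != 1:
            raise InvalidInputError("onset_times must be 1-D")
        if self.onset_times.size >= 2:
            d = np.diff(self.onset_times)
            if np.any(d <= 0):
                raise InvalidInputError("onset_times must be strictly increasing")
            if np.any(d < 0.3) or np.any(d > 1.2):
                raise InvalidInputError(
                    "compression cycle lengths must lie in [0.3, 1.2] s "
                    "(50-200 compressions/min)")

    @property
    def n_cycles(self) -> int:
        """Number of complete cycles (pairs of consecutive onsets)."""
        return max(self.onset_times.size - 1, 0)


@dataclass
class SegmentPair:
    """A corrupted/uncorrupted 4-s segment pair sharing one true AMSA label.

    ``amsa_true`` is the FFT-based AMSA of the uncorrupted member, used as
    the regression target for both members of the pair.
    """

    corrupted: EcgSegment
    uncorrupted: EcgSegment
    amsa_true: float
    subject_id: str | None = None
    snr_db: float | None = None
    cc_ref: "CompressionReference | None" = None

    def __post_init__(self) -> None:
        if self.corrupted.fs != self.uncorrupted.fs:
            raise InvalidInputError("pair members must share the sampling rate")
        if self.corrupted.n != self.uncorrupted.n:
            raise InvalidInputError("pair members must share the duration")
        if not (self.amsa_true >= 0 and math.isfinite(self.amsa_true)):
            raise InvalidInputError("amsa_true must be a finite non-negative value")


def resample_to(segment: EcgSegment, target_fs: float) -> EcgSegment:
    """Resample a segment to ``target_fs`` with a polyphase anti-aliased filter.

    Band content below ``min(fs, target_fs) / 2`` is preserved; the output
    length is rescaled by ``target_fs / fs``.
    """
    if not (target_fs > 0):
        raise ConfigurationError(f"target_fs must be positive, got {target_fs}")
    if target_fs == segment.fs:
        return segment
    frac = Fraction(target_fs / segment.fs).limit_denominator(1000)
    out = _sig.resample_poly(segment.samples, frac.numerator, frac.denominator)
    return replace(segment, samples=out, fs=target_fs)


def _constant_runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of constant value in a boolean mask as (start, stop, value)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate(([0], edges, [mask.size]))
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def extract_segment_pairs(
    ecg: EcgSegment,
    cc_mask: Sequence[bool] | np.ndarray,
    window_s: float = ANALYSIS_DURATION_S,
    guard_s: float = 0.0,
    label_fn: Callable[[EcgSegment], float] | None = None,
) -> list[SegmentPair]:
    """Extract adjacent corrupted/uncorrupted 4-s pairs around CC transitions.

    At every transition of ``cc_mask`` (sample-aligned with ``ecg``) where
    the run before and the run after each span at least one full window
    (plus ``guard_s`` of slack trimmed off next to the transition), the 4-s
    window ending at the transition and the 4-s window starting at it form
    a pair: one is entirely CC-free, the other entirely CC-covered.  The
    shared label is the FFT AMSA of the uncorrupted member.  Windows never
    straddle a CC-state transition.

    Returns an empty list (not an error) when no window qualifies.
    """
    cc_mask = np.asarray(cc_mask, dtype=bool)
    if cc_mask.shape[0] != ecg.n:
        raise InvalidInputError(
            f"cc_mask length {cc_mask.shape[0]} does not match ecg length {ecg.n}")
    if label_fn is None:
        from .spectral import amsa_fft  # local import avoids a module cycle
        label_fn = amsa_fft
    w = int(round(window_s * ecg.fs))
    g = int(round(guard_s * ecg.fs))
    runs = _constant_runs(cc_mask)
    pairs: list[SegmentPair] = []
    for (a0, a1, aval), (b0, b1, bval) in zip(runs[:-1], runs[1:]):
        # windows sit guard_s away from the transition, inside their runs
        left_start, left_stop = a1 - g - w, a1 - g
        right_start, right_stop = b0 + g, b0 + g + w
        if left_start < a0 or right_stop > b1:
            continue
        left = replace(ecg, samples=ecg.samples[left_start:left_stop],
                       t0=ecg.t0 + left_start / ecg.fs,
                       role=SegmentRole.CVF if aval else SegmentRole.UVF)
        right = replace(ecg, samples=ecg.samples[right_start:right_stop],
                        t0=ecg.t0 + right_start / ecg.fs,
                        role=SegmentRole.CVF if bval else SegmentRole.UVF)
        corrupted, clean = (left, right) if aval else (right, left)
        pairs.append(SegmentPair(corrupted=corrupted, uncorrupted=clean,
                                 amsa_true=float(label_fn(clean)),
                                 subject_id=ecg.subject_id))
    return pairs
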