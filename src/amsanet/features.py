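"""CNN input transform and the 8-element augmentation group.

The network does not see the raw segment: after optional 0.5 Hz high-pass
filtering, the signal S of length L is split by a downsampling
differential operation into two channels (1-based indices):

    ch1(i) = S(2i+1) - S(2i-1)
    ch2(i) = S(2i+2) - S(2i),      i = 1 .. floor(L/2) - 1

i.e. lag-2 differences of the odd- and even-indexed subsequences.  For a
4-s segment at 250 Hz (L = 1000) each channel has 499 samples.  The
differencing removes the DC offset exactly and emphasises the frequency
content that AMSA weights.

Training data are augmented by the 7 non-identity elements of the group
generated by three label-preserving operations: sign negation, time
reversal and channel swap.  Each preserves the per-channel magnitude
spectrum (up to the channel swap), so every variant legitimately carries
the source segment's AMSA label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EcgSegment
from .exceptions import InvalidInputError
from .spectral import DEFAULT_SPECTRAL, SpectralConfig, highpass


@dataclass(frozen=True)
class TwoChannelInput:
    """The two-channel differential signal fed to the CNN."""

    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ch1", np.asarray(self.ch1, dtype=float))
        object.__setattr__(self, "ch2", np.asarray(self.ch2, dtype=float))
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise InvalidInputError("channels must be 1-D and of equal length")
        if not (np.all(np.isfinite(self.ch1)) and np.all(np.isfinite(self.ch2))):
            raise InvalidInputError("channel values must be finite")

    @property
    def length(self) -> int:
        return int(self.ch1.shape[0])

    def as_array(self) -> np.ndarray:
        """Stack to shape (2, length)."""
        return np.stack([self.ch1, self.ch2])


def difference_transform(
    segment: EcgSegment,
    hp: bool = True,
    cfg: SpectralConfig = DEFAULT_SPECTRAL,
) -> TwoChannelInput:
    """Differential two-channel transform of a segment (see module docstring).

    ``hp`` applies the 0.5 Hz second-order high-pass first (the default
    preprocessing); channel length is floor(L/2) - 1.
    """
    if segment.n < 4:
        raise InvalidInputError("segment too short for the difference transform")
    x = highpass(segment, cfg).samples if hp else segment.samples
    m = len(x) // 2 - 1
    even = x[0::2]
    odd = x[1::2]
    return TwoChannelInput(ch1=even[1:m + 1] - even[:m], ch2=odd[1:m + 1] - odd[:m])


def _neg(x: TwoChannelInput) -> TwoChannelInput:
    return TwoChannelInput(-x.ch1, -x.ch2)


def _rev(x: TwoChannelInput) -> TwoChannelInput:
    return TwoChannelInput(x.ch1[::-1], x.ch2[::-1])


def _swap(x: TwoChannelInput) -> TwoChannelInput:
    return TwoChannelInput(x.ch2, x.ch1)


def augment(x: TwoChannelInput) -> list[TwoChannelInput]:
    """The 7 non-identity variants of the negate/reverse/swap group.

    Returned in the canonical order: negate; reverse; swap; negate+reverse;
    negate+swap; reverse+swap; negate+reverse+swap.  Together with the
    identity these form a commuting group of order 8 (each generator is an
    involution).  All variants share the source's AMSA label.
    """
    return [
        _neg(x),
        _rev(x),
        _swap(x),
        _neg(_rev(x)),
        _neg(_swap(x)),
        _rev(_swap(x)),
        _neg(_rev(_swap(x))),
    ]
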