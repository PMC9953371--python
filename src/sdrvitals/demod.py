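"""Phase recovery from quadrature records.

The quadrature receiver is immune to range null points: the four-quadrant
arctangent of (Q, I) recovers the modulated phase at any distance, whereas
a single-channel receiver's sensitivity collapses every quarter wavelength.
Both paths are provided, plus the streaming DC-removal stage that subtracts
the running mean of the stored arctangent data at the refresh cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .signal_model import QuadratureRecord, RadarConfig

#: below this |sin(theta)| the single-channel demodulator is flagged degenerate
_NULL_SENSITIVITY_FLOOR = 1e-6


@dataclass
class PhaseRecord:
    """Unwrapped phase series in radians."""

    sample_rate: float
    phase_samples: np.ndarray
    dc_removed: bool = False
    #: single-channel only: A*|sin(theta)| conversion factor (V/rad)
    sensitivity: Optional[float] = field(default=None, repr=False)
    #: single-channel only: set when the chosen distance sits on a null point
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.phase_samples = np.asarray(self.phase_samples, dtype=float)

    def __len__(self) -> int:
        return len(self.phase_samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate


def arctan_demodulate(
    record: QuadratureRecord,
    dc_offsets: Optional[Tuple[float, float]] = None,
    subtract_mean: bool = False,
) -> PhaseRecord:
    """Arctangent demodulation: ``atan2(Q, I)`` per sample, then unwrapped.

    Unwrapping applies a 2*pi correction wherever consecutive samples jump
    by more than pi, so displacement spans beyond a half wavelength remain
    continuous.

    Parameters
    ----------
    record : QuadratureRecord
    dc_offsets : (dc_i, dc_q), optional
        Known receiver DC offsets to subtract before the arctangent.
    subtract_mean : bool
        Estimate and remove the offsets as the per-channel time averages
        instead.  Off by default: for a modulated record the channel mean
        includes a signal-dependent term, so exact offsets are preferred
        whenever they are known.
    """
    if len(record) == 0:
        raise ValueError("record must be non-empty")
    i = record.i_samples.astype(float, copy=True)
    q = record.q_samples.astype(float, copy=True)
    if dc_offsets is not None:
        i -= dc_offsets[0]
        q -= dc_offsets[1]
    if subtract_mean:
        i -= i.mean()
        q -= q.mean()
    phase = np.unwrap(np.arctan2(q, i))
    return PhaseRecord(sample_rate=record.sample_rate, phase_samples=phase)


def remove_dc_streaming(
    phase: PhaseRecord,
    config: RadarConfig,
    window_samples: Optional[int] = None,
) -> PhaseRecord:
    """Streaming DC removal by running-mean subtraction.

    Samples arrive in blocks of ``sample_rate/refresh_rate`` (8 at the
    default 200 Hz / 25 Hz).  Each new block is appended to the stored
    dataset, the dataset mean is recomputed, and the block is emitted with
    that mean subtracted — so the subtracted DC estimate refreshes every
    0.04 s at defaults.

    Parameters
    ----------
    window_samples : int, optional
        If given, the stored dataset is a sliding window of at most this
        many samples instead of growing without bound.
    """
    if abs(phase.sample_rate - config.sample_rate) > 1e-9:
        raise ValueError(
            f"phase.sample_rate ({phase.sample_rate}) must equal "
            f"config.sample_rate ({config.sample_rate})"
        )
    x = phase.phase_samples
    n = len(x)
    block = config.samples_per_refresh
    csum = np.cumsum(x)
    ends = np.arange(block, n + 1, block)
    if len(ends) == 0 or ends[-1] != n:
        ends = np.append(ends, n)  # trailing partial block
    if window_samples is None:
        means = csum[ends - 1] / ends
    else:
        w = int(window_samples)
        if w <= 0:
            raise ValueError("window_samples must be positive")
        starts = np.maximum(ends - w, 0)
        sums = csum[ends - 1] - np.where(starts > 0, csum[starts - 1], 0.0)
        means = sums / (ends - starts)
    reps = np.diff(np.concatenate(([0], ends)))
    out = x - np.repeat(means, reps)
    return PhaseRecord(sample_rate=phase.sample_rate, phase_samples=out, dc_removed=True)


def single_channel_phase(record: QuadratureRecord, config: RadarConfig) -> PhaseRecord:
    """Small-signal linear demodulation using the I channel only.

    Around the operating point ``theta = 4*pi*d0/lambda`` a small phase
    excursion ``delta`` gives ``I ≈ A*cos(theta) - A*sin(theta)*delta``, so
    the mean-removed I channel divided by ``-A*sin(theta)`` approximates
    the phase in radians.  The conversion factor ``A*|sin(theta)|`` is
    returned as ``sensitivity``; it vanishes at every quarter-wavelength
    null, where the record is flagged ``degenerate`` (output forced to
    zero) instead of dividing by ~0.
    """
    if len(record) == 0:
        raise ValueError("record must be non-empty")
    s = np.sin(config.range_phase)
    sensitivity = config.amplitude * abs(s)
    i = record.i_samples
    if abs(s) < _NULL_SENSITIVITY_FLOOR:
        out = np.zeros(len(record))
        return PhaseRecord(
            sample_rate=record.sample_rate,
            phase_samples=out,
            sensitivity=sensitivity,
            degenerate=True,
        )
    out = -(i - i.mean()) / (config.amplitude * s)
    return PhaseRecord(
        sample_rate=record.sample_rate,
        phase_samples=out,
        sensitivity=sensitivity,
        degenerate=False,
    )
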