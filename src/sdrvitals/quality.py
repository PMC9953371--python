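"""I/Q waveform quality scoring (the posture effect).

A subject leaning back reflects less power toward the receive antenna, so
the I/Q voltage swings shrink and the demodulated phase gets noisier.  The
quality check reads the per-channel peak swings, combines them RMS-style
and applies a strict > 3 mV acceptability threshold; amplitude ratios
convert to SNR gain as 20*log10(ratio) dB (a 5-10x swing ratio is a
14-20 dB SNR difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import QuadratureRecord

#: combined-swing acceptability threshold, volts (3 mV)
DEFAULT_QUALITY_THRESHOLD = 3e-3


@dataclass(frozen=True)
class SwingStats:
    i_swing: float
    q_swing: float
    combined: float
    label: str  # "Good" | "Bad"
    threshold: float = DEFAULT_QUALITY_THRESHOLD


def peak_swing(samples: np.ndarray) -> float:
    """Robust peak-to-peak swing: the 99th minus the 1st percentile.

    Percentiles rather than min/max keep the reading insensitive to
    isolated spikes.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    hi, lo = np.percentile(samples, [99.0, 1.0])
    return float(hi - lo)


def combined_magnitude(i_swing: float, q_swing: float) -> float:
    """RMS combination of the two channel swings: sqrt((I^2 + Q^2)/2)."""
    if i_swing < 0 or q_swing < 0:
        raise ValueError("swings must be non-negative")
    return float(np.sqrt((i_swing**2 + q_swing**2) / 2.0))


def snr_gain_db(amplitude_ratio: float) -> float:
    """SNR difference in dB for an amplitude (voltage) ratio: 20*log10(r)."""
    if amplitude_ratio <= 0:
        raise ValueError("amplitude ratio must be positive")
    return float(20.0 * np.log10(amplitude_ratio))


def posture_quality(
    record: QuadratureRecord, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> SwingStats:
    """Label a record Good/Bad by its combined I/Q swing.

    Good requires the combined magnitude to exceed the threshold strictly
    (a record sitting exactly at 3 mV is Bad).
    """
    if len(record) == 0:
        raise ValueError("record must be non-empty")
    i_swing = peak_swing(record.i_samples)
    q_swing = peak_swing(record.q_samples)
    combined = combined_magnitude(i_swing, q_swing)
    label = "Good" if combined > threshold else "Bad"
    return SwingStats(
        i_swing=i_swing,
        q_swing=q_swing,
        combined=combined,
        label=label,
        threshold=threshold,
    )
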