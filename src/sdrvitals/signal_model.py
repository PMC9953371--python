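"""Physical signal model for a continuous-wave Doppler vital-signs radar.

A stationary subject's chest moves periodically with respiration (mm scale)
and heartbeat (sub-mm scale).  Because the motion has no net velocity it
produces no Doppler frequency shift; instead it phase-modulates the
reflected carrier.  With round-trip path length ``2*(d0 + x(t) + y(t))`` the
received baseband quadrature pair is

    I(t) = A * cos(theta + (4*pi/lambda)*(x(t) + y(t)) + dphi(t))
    Q(t) = A * sin(theta + (4*pi/lambda)*(x(t) + y(t)) + dphi(t))

where ``theta = 4*pi*d0/lambda`` is the constant range phase, ``x`` the
respiration displacement, ``y`` the heartbeat displacement and ``dphi`` the
oscillator phase noise.  The synthesizer here re-introduces the
imperfections an ideal derivation ignores: DC offsets, I/Q gain imbalance,
quadrature skew and additive thermal noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class RadarConfig:
    """Geometry and timing constants of the radar front end.

    Parameters
    ----------
    carrier_frequency : float
        Transmitted CW carrier in Hz.  Default 2.4 GHz (ISM band).
    propagation_speed : float
        Wave speed in m/s.  Default ``3.0e8`` so that the 2.4 GHz
        wavelength is exactly 12.5 cm.
    sample_rate : float
        Baseband I/Q sampling rate in Hz (default 200).
    refresh_rate : float
        Rate-estimate update cadence in Hz (default 25, i.e. every 40 ms).
    distance : float
        Antenna-to-subject distance d0 in metres (default 1.3).
    amplitude : float
        Received-signal amplitude in volts; stands in for the product of
        TX power, antenna gains and path loss (default 1 mV).
    """

    carrier_frequency: float = 2.4e9
    propagation_speed: float = 3.0e8
    sample_rate: float = 200.0
    refresh_rate: float = 25.0
    distance: float = 1.3
    amplitude: float = 1e-3

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0 or self.propagation_speed <= 0:
            raise ValueError("carrier_frequency and propagation_speed must be positive")
        if self.sample_rate <= 0 or self.refresh_rate <= 0:
            raise ValueError("sample_rate and refresh_rate must be positive")
        ratio = self.sample_rate / self.refresh_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "sample_rate must be an integer multiple of refresh_rate "
                f"(got {self.sample_rate}/{self.refresh_rate})"
            )
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def wavelength(self) -> float:
        """Free-space wavelength in metres (12.5 cm at defaults)."""
        return self.propagation_speed / self.carrier_frequency

    @property
    def samples_per_refresh(self) -> int:
        """Raw samples accumulated between estimate updates (8 at defaults)."""
        return int(round(self.sample_rate / self.refresh_rate))

    @property
    def refresh_interval(self) -> float:
        """Seconds between estimate updates (0.04 s at defaults)."""
        return 1.0 / self.refresh_rate

    @property
    def range_phase(self) -> float:
        """Constant round-trip phase ``theta = 4*pi*distance/wavelength``."""
        return 4.0 * np.pi * self.distance / self.wavelength


@dataclass(frozen=True)
class VitalProfile:
    """Ground-truth physiology of a simulated subject.

    ``resp_harmonic_weights`` gives relative amplitudes of the respiration
    harmonics (index k = harmonic number k+1); a pure sinusoid is
    ``(1.0,)``.  Higher harmonics of a non-sinusoidal breathing waveform can
    land inside the heart band and interfere with heart-rate extraction,
    which is exactly what the weights are there to reproduce.
    """

    rr_bpm: float = 15.0
    hr_bpm: float = 72.0
    resp_amplitude: float = 4e-3
    heart_amplitude: float = 3e-4
    resp_harmonic_weights: Sequence[float] = (1.0,)
    resp_phase: float = 0.0
    heart_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_bpm < 0 or self.hr_bpm < 0:
            raise ValueError("rates must be non-negative")
        if self.resp_amplitude < 0 or self.heart_amplitude < 0:
            raise ValueError("displacement amplitudes must be non-negative")
        if any(w < 0 for w in self.resp_harmonic_weights):
            raise ValueError("harmonic weights must be non-negative")
        if self.resp_amplitude > 0 and self.heart_amplitude >= self.resp_amplitude:
            warnings.warn(
                "heart_amplitude >= resp_amplitude is physiologically unusual",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption model applied on top of the ideal quadrature pair.

    phase_walk_std : per-sample increment std (rad) of the oscillator
        phase-noise random walk.
    thermal_std : per-channel additive white Gaussian noise std in volts.
    dc_offset_i / dc_offset_q : receiver DC offsets in volts.
    gain_imbalance : Q-channel gain relative to I (1.0 = balanced).
    quadrature_error : phase skew of the Q channel in radians.
    seed : seed for all stochastic terms; identical spec => identical record.
    """

    phase_walk_std: float = 0.0
    thermal_std: float = 0.0
    dc_offset_i: float = 0.0
    dc_offset_q: float = 0.0
    gain_imbalance: float = 1.0
    quadrature_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_walk_std < 0 or self.thermal_std < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.gain_imbalance <= 0:
            raise ValueError("gain_imbalance must be positive")


@dataclass
class DisplacementRecord:
    """Chest-wall displacement series with components kept separate."""

    sample_rate: float
    respiration: np.ndarray  # x(t), metres
    heartbeat: np.ndarray    # y(t), metres

    @property
    def samples(self) -> np.ndarray:
        """Total displacement x(t) + y(t)."""
        return self.respiration + self.heartbeat

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.respiration)) / self.sample_rate


@dataclass
class QuadratureRecord:
    """Sampled baseband I/Q voltages, optionally carrying synthesis truth."""

    sample_rate: float
    i_samples: np.ndarray
    q_samples: np.ndarray
    truth_displacement: Optional[DisplacementRecord] = field(default=None, repr=False)
    truth_phase: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.i_samples = np.asarray(self.i_samples, dtype=float)
        self.q_samples = np.asarray(self.q_samples, dtype=float)
        if self.i_samples.shape != self.q_samples.shape:
            raise ValueError("I and Q series must have equal length")

    def __len__(self) -> int:
        return len(self.i_samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate


class NullPoints(NamedTuple):
    positions: np.ndarray  # metres, ascending, within (0, max_distance]
    spacing: float         # metres, = wavelength / 4


def chest_displacement(
    profile: VitalProfile, sample_rate: float, duration: float
) -> DisplacementRecord:
    """Generate the ground-truth chest displacement series.

    Respiration is a harmonic series at the breathing fundamental,
    heartbeat a pure sinusoid:

        x(t) = resp_amplitude * sum_k w_k * sin(2*pi*k*f_r*t + resp_phase)
        y(t) = heart_amplitude * sin(2*pi*f_h*t + heart_phase)

    with ``f_r = rr_bpm/60`` and ``f_h = hr_bpm/60`` in Hz.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    f_resp = profile.rr_bpm / 60.0
    f_heart = profile.hr_bpm / 60.0
    x = np.zeros(n)
    for k, w in enumerate(profile.resp_harmonic_weights, start=1):
        if w:
            x += w * np.sin(2.0 * np.pi * k * f_resp * t + profile.resp_phase)
    x *= profile.resp_amplitude
    y = profile.heart_amplitude * np.sin(2.0 * np.pi * f_heart * t + profile.heart_phase)
    return DisplacementRecord(sample_rate=sample_rate, respiration=x, heartbeat=y)


def phase_noise_walk(noise: NoiseSpec, n_samples: int) -> np.ndarray:
    """Oscillator phase-noise as a Gaussian random walk, first element 0.

    A random walk (integrated white noise, 1/f^2 power spectrum) stands in
    for the close-in phase noise of the VCO/PLL; the increments are i.i.d.
    zero-mean normal with std ``phase_walk_std``.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    rng = np.random.default_rng(noise.seed)
    return _walk(rng, noise.phase_walk_std, n_samples)


def _walk(rng: np.random.Generator, std: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    out = np.zeros(n)
    if std > 0 and n > 1:
        out[1:] = np.cumsum(rng.normal(0.0, std, n - 1))
    return out


def synthesize_quadrature(
    config: RadarConfig,
    profile: VitalProfile,
    noise: NoiseSpec,
    duration: float,
) -> QuadratureRecord:
    """Synthesize a corrupted baseband quadrature record.

    The total modulated phase is
    ``phi(t) = theta + (4*pi/lambda)*(x(t) + y(t)) + dphi(t)`` and the
    channels are

        I = A*cos(phi) + dc_i + n_I
        Q = A*g*sin(phi + eps) + dc_q + n_Q

    with gain imbalance ``g``, quadrature skew ``eps`` and white thermal
    noise ``n_I, n_Q``.  The ground-truth displacement and phase are kept
    on the returned record for oracle checks.
    """
    disp = chest_displacement(profile, config.sample_rate, duration)
    n = len(disp.respiration)
    if n < 2:
        raise ValueError("duration * sample_rate must be at least 2 samples")
    rng = np.random.default_rng(noise.seed)
    walk = _walk(rng, noise.phase_walk_std, n)
    phi = config.range_phase + (4.0 * np.pi / config.wavelength) * disp.samples + walk
    amp = config.amplitude
    i = amp * np.cos(phi) + noise.dc_offset_i + rng.normal(0.0, noise.thermal_std, n)
    q = (
        amp * noise.gain_imbalance * np.sin(phi + noise.quadrature_error)
        + noise.dc_offset_q
        + rng.normal(0.0, noise.thermal_std, n)
    )
    return QuadratureRecord(
        sample_rate=config.sample_rate,
        i_samples=i,
        q_samples=q,
        truth_displacement=disp,
        truth_phase=phi,
    )


def null_point_positions(config: RadarConfig, max_distance: float) -> NullPoints:
    """Distances at which a single-channel receiver loses phase sensitivity.

    Nulls occur wherever ``sin(4*pi*d/lambda) = 0``, i.e. every quarter
    wavelength (3.125 cm at 2.4 GHz).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    spacing = config.wavelength / 4.0
    k_max = int(np.floor(max_distance / spacing + 1e-12))
    positions = spacing * np.arange(1, k_max + 1)
    return NullPoints(positions=positions, spacing=spacing)
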