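"""Stimulation waveforms, RMS voltage, and effective-field estimation.

The stimulus is a zero-mean biphasic square wave: alternating +Vpp/2 and
-Vpp/2 half-periods with a 50/50 duty cycle and no interphase gap.  The
effective field inside a conductive porous scaffold is estimated as the
nominal field (V_RMS over the electrode gap) divided by the transport
tortuosity factor:

    E_eff [mV/cm] = V_RMS [mV] / (d [cm] * tau)

This divisor policy is explicit and swappable; it treats tortuosity as a
bulk attenuation of the nominal field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "FieldEstimate",
    "generate_waveform",
    "rms",
    "effective_field",
    "write_waveform",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Biphasic square stimulation parameters (Vpp in mV)."""

    vpp: float  # mV peak-to-peak
    frequency: float = 1000.0  # Hz
    duration: float = 0.01  # s
    sample_rate: float = 1e6  # Hz
    shape: str = "biphasic_square"

    def __post_init__(self) -> None:
        if self.vpp < 0:
            raise ValueError("vpp must be >= 0")
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("frequency and duration must be positive")
        if self.sample_rate < 20 * self.frequency:
            raise ValueError("sample_rate must be >= 20x frequency")
        if self.shape != "biphasic_square":
            raise ValueError(f"unsupported waveform shape '{self.shape}'")


@dataclass(frozen=True)
class FieldEstimate:
    v_rms: float  # mV
    electrode_distance: float  # mm
    tortuosity_factor: float
    effective_field: float  # mV/cm

    def to_dict(self) -> dict:
        return asdict(self)


def generate_waveform(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    """(time s, voltage mV): deterministic sampled biphasic square wave."""
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    half = spec.vpp / 2.0
    # first half-period positive, second negative
    phase = np.floor(2.0 * spec.frequency * t).astype(int) % 2
    v = np.where(phase == 0, half, -half)
    return t, v


def rms(voltage: np.ndarray) -> float:
    """Root-mean-square of a sampled voltage sequence."""
    v = np.asarray(voltage, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage sequence")
    return float(np.sqrt(np.mean(v * v)))


def effective_field(v_rms: float, electrode_distance: float = 3.17,
                    tortuosity_factor: float = 1.0) -> FieldEstimate:
    """Effective field in mV/cm: V_RMS / (distance_cm * tau).

    ``electrode_distance`` is in mm (3.17 mm default electrode gap).
    """
    if v_rms <= 0 or electrode_distance <= 0 or tortuosity_factor <= 0:
        raise ValueError("all inputs must be positive")
    d_cm = electrode_distance / 10.0
    e = v_rms / (d_cm * tortuosity_factor)
    return FieldEstimate(v_rms, electrode_distance, tortuosity_factor, e)


def write_waveform(t: np.ndarray, v: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": t, "voltage_mV": v}).to_csv(path, index=False,
                                                        float_format="%.9g")
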