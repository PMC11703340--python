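"""Unconfined-compression DMA loading protocol.

The protocol is the standard cartilage-style sequence: sinusoidal cyclic
preconditioning to a peak strain, a short rest, a ramp to a held strain,
a long stress-relaxation hold, and finally a small-amplitude sinusoidal
dynamic segment.  The dynamic frequency is derived from the peak strain
velocity: for eps(t) = eps0*sin(w t) the peak rate is w*eps0, so
w = velocity / amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ProtocolSpec:
    """Strain schedule for one DMA run.

    Parameters
    ----------
    precondition_peak_strain
        Peak engineering strain of the preconditioning cycles (default 0.14).
    precondition_frequency
        Preconditioning frequency in Hz (default 0.5).
    precondition_cycles
        Number of preconditioning cycles (default 8).
    rest_duration
        Zero-strain rest after preconditioning, seconds (default 5).
    ramp_target_strain
        Strain held during relaxation (default 0.12).
    ramp_duration
        Duration of the linear ramp to the held strain, seconds.  Default
        1.2 s, i.e. a 10 %/s ramp rate consistent with the dynamic segment.
    relaxation_duration
        Stress-relaxation hold, seconds (default 120).
    dynamic_amplitude
        Strain amplitude of the dynamic sinusoid (default 0.01).
    dynamic_strain_velocity
        Peak strain rate of the dynamic sinusoid, 1/s (default 0.10).
    dynamic_cycles
        Number of dynamic cycles (default 10).
    sample_rate
        Sampling rate in Hz (default 500).
    """

    precondition_peak_strain: float = 0.14
    precondition_frequency: float = 0.5
    precondition_cycles: int = 8
    rest_duration: float = 5.0
    ramp_target_strain: float = 0.12
    ramp_duration: float = 1.2
    relaxation_duration: float = 120.0
    dynamic_amplitude: float = 0.01
    dynamic_strain_velocity: float = 0.10
    dynamic_cycles: int = 10
    sample_rate: float = 500.0

    def __post_init__(self) -> None:
        for name in ("precondition_peak_strain", "ramp_target_strain", "dynamic_amplitude"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.precondition_frequency <= 0 or self.sample_rate <= 0:
            raise ValueError("frequencies must be positive")
        if self.precondition_cycles < 1 or self.dynamic_cycles < 1:
            raise ValueError("cycle counts must be >= 1")
        if min(self.rest_duration, self.ramp_duration, self.relaxation_duration) < 0:
            raise ValueError("durations must be non-negative")
        if self.dynamic_strain_velocity <= 0:
            raise ValueError("dynamic_strain_velocity must be positive")
        samples_per_cycle = self.sample_rate / self.precondition_frequency
        if samples_per_cycle < 50:
            raise ValueError(
                "sample_rate too low: need >= 50 samples per preconditioning "
                f"cycle, got {samples_per_cycle:.1f}"
            )

    @property
    def dynamic_angular_frequency(self) -> float:
        """omega of the dynamic sinusoid in rad/s (velocity / amplitude)."""
        return self.dynamic_strain_velocity / self.dynamic_amplitude

    @property
    def dynamic_frequency(self) -> float:
        """Dynamic frequency in Hz."""
        return self.dynamic_angular_frequency / (2.0 * math.pi)

    # ------------------------------------------------------------------
    # schedule
    # ------------------------------------------------------------------
    def segment_schedule(self) -> list[tuple[str, float, float]]:
        """Ordered (label, t_start, t_end) for every protocol segment.

        Preconditioning cycles are labelled ``precondition:1`` ..
        ``precondition:K`` (1-based).  Times are in seconds from the start
        of the run; each segment is the half-open interval [t_start, t_end).
        """
        out: list[tuple[str, float, float]] = []
        t = 0.0
        period = 1.0 / self.precondition_frequency
        for k in range(1, self.precondition_cycles + 1):
            out.append((f"precondition:{k}", t, t + period))
            t += period
        out.append(("rest", t, t + self.rest_duration))
        t += self.rest_duration
        out.append(("ramp", t, t + self.ramp_duration))
        t += self.ramp_duration
        out.append(("relaxation", t, t + self.relaxation_duration))
        t += self.relaxation_duration
        dyn = self.dynamic_cycles / self.dynamic_frequency
        out.append(("dynamic", t, t + dyn))
        return out

    @property
    def total_duration(self) -> float:
        return self.segment_schedule()[-1][2]
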