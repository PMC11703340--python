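"""Synthetic bioreactor traces and decay series with attached ground truth.

The constitutive ground truth is a linear-viscoelastic Prony-series
(generalized Maxwell) material: an equilibrium spring ``E_inf`` in parallel
with relaxing arms ``(E_i, tau_i)``.  Its relaxation modulus is

    E(t) = E_inf + sum_i E_i * exp(-t / tau_i)

and its complex modulus at angular frequency ``w`` has the standard
storage/loss components

    E'(w)  = E_inf + sum_i E_i w^2 tau_i^2 / (1 + w^2 tau_i^2)
    E''(w) =         sum_i E_i w   tau_i   / (1 + w^2 tau_i^2)

The time-domain stress is the Boltzmann hereditary integral of the strain
history, discretized with the exact-exponential recursive update per arm
(exact for piecewise-linear strain, unconditionally stable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .mechanics import (SpecimenGeometry, StressStrainTrace, TimeSeriesRecord,
                        label_segments)
from .protocol import ProtocolSpec

__all__ = [
    "PronyMaterial",
    "SimulatedTrace",
    "prony_complex_modulus",
    "prony_relaxation_modulus",
    "strain_schedule",
    "simulate_dma_protocol",
    "generate_decay_series",
    "generate_approach_ramp",
    "trace_to_record",
]


@dataclass(frozen=True)
class PronyMaterial:
    """Linear-viscoelastic ground-truth material.

    Parameters
    ----------
    equilibrium_modulus
        Long-time stiffness E_inf in Pa; must be positive.
    arms
        Relaxing arms as (modulus Pa, relaxation time s) pairs.
    noise_sd
        Additive Gaussian stress noise (Pa).  ``None`` (default) means
        0.5 % of the noise-free peak preconditioning stress; pass 0.0 for a
        noise-free simulation.
    """

    equilibrium_modulus: float
    arms: tuple[tuple[float, float], ...] = ()
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.equilibrium_modulus) and self.equilibrium_modulus > 0):
            raise ValueError("equilibrium_modulus must be finite and positive")
        object.__setattr__(self, "arms", tuple((float(e), float(t)) for e, t in self.arms))
        for e, t in self.arms:
            if not (np.isfinite(e) and e >= 0):
                raise ValueError("arm modulus must be finite and >= 0")
            if not (np.isfinite(t) and t > 0):
                raise ValueError("relaxation time must be finite and positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def instantaneous_modulus(self) -> float:
        return self.equilibrium_modulus + sum(e for e, _ in self.arms)


def prony_relaxation_modulus(material: PronyMaterial, t: np.ndarray | float) -> np.ndarray:
    """E(t) = E_inf + sum E_i exp(-t/tau_i)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, material.equilibrium_modulus, dtype=float)
    for e, tau in material.arms:
        out = out + e * np.exp(-t / tau)
    return out


def prony_complex_modulus(material: PronyMaterial, omega: float) -> tuple[float, float]:
    """Frequency-domain oracle: (storage E', loss E'') at omega rad/s."""
    storage = material.equilibrium_modulus
    loss = 0.0
    for e, tau in material.arms:
        wt2 = (omega * tau) ** 2
        storage += e * wt2 / (1.0 + wt2)
        loss += e * (omega * tau) / (1.0 + wt2)
    return storage, loss


def _analytic_truth(material: PronyMaterial, protocol: ProtocolSpec) -> dict[str, float]:
    w = protocol.dynamic_angular_frequency
    sp, lo = prony_complex_modulus(material, w)
    arm_sum = sum(e for e, _ in material.arms)
    return {
        "equilibrium_modulus": material.equilibrium_modulus,
        "storage_modulus": sp,
        "loss_modulus": lo,
        "dynamic_modulus": math.hypot(sp, lo),
        "phase_shift": math.atan2(lo, sp),
        "stress_relaxation_percent": 100.0 * arm_sum / (material.equilibrium_modulus + arm_sum),
        "dynamic_angular_frequency": w,
    }


@dataclass
class SimulatedTrace:
    """A simulated DMA run plus the closed-form endpoint values."""

    trace: StressStrainTrace
    material: PronyMaterial
    protocol: ProtocolSpec
    seed: int
    analytic_truth: dict[str, float]


# ----------------------------------------------------------------------
# strain schedule and hereditary-integral stress
# ----------------------------------------------------------------------

def strain_schedule(protocol: ProtocolSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample times, strain and per-sample labels for the full protocol."""
    dt = 1.0 / protocol.sample_rate
    n = int(round(protocol.total_duration / dt)) + 1
    t = np.arange(n) * dt
    strain = np.zeros(n)
    sched = protocol.segment_schedule()
    bounds = {name: (a, b) for name, a, b in sched}

    f_pre = protocol.precondition_frequency
    pre_end = protocol.precondition_cycles / f_pre
    m = t < pre_end
    strain[m] = 0.5 * protocol.precondition_peak_strain * (
        1.0 - np.cos(2.0 * math.pi * f_pre * t[m]))

    a, b = bounds["ramp"]
    m = (t >= a) & (t < b)
    if protocol.ramp_duration > 0:
        strain[m] = protocol.ramp_target_strain * (t[m] - a) / protocol.ramp_duration

    a, b = bounds["relaxation"]
    m = (t >= a) & (t < b)
    strain[m] = protocol.ramp_target_strain

    a, _ = bounds["dynamic"]
    m = t >= a
    strain[m] = protocol.ramp_target_strain + protocol.dynamic_amplitude * np.sin(
        protocol.dynamic_angular_frequency * (t[m] - a))

    labels = label_segments(t, protocol)
    return t, strain, labels


def prony_stress(material: PronyMaterial, time: np.ndarray, strain: np.ndarray) -> np.ndarray:
    """Hereditary (Boltzmann superposition) stress on a uniform time grid.

    Per-arm exact-exponential update for piecewise-linear strain:
    h[n] = exp(-dt/tau) h[n-1] + E (tau/dt)(1 - exp(-dt/tau)) (eps[n]-eps[n-1]).
    """
    dt = float(time[1] - time[0])
    if not np.allclose(np.diff(time), dt, rtol=1e-9, atol=1e-12):
        raise ValueError("prony_stress requires a uniform time grid")
    stress = material.equilibrium_modulus * strain
    deps = np.diff(strain, prepend=strain[0])
    for e, tau in material.arms:
        a = math.exp(-dt / tau)
        b = e * (tau / dt) * (1.0 - a)
        stress = stress + lfilter([b], [1.0, -a], deps)
    return stress


def simulate_dma_protocol(material: PronyMaterial, protocol: ProtocolSpec,
                          seed: int = 0) -> SimulatedTrace:
    """Simulate the full DMA protocol for a Prony material.

    Returns the labelled stress/strain trace, the material and protocol
    used, and the closed-form endpoint values computed from the material
    alone (no signal processing).
    """
    t, strain, labels = strain_schedule(protocol)
    min_arc = protocol.sample_rate / protocol.precondition_frequency / 2.0
    if min_arc < 12:
        raise ValueError("protocol yields < 12 samples per loading arc")
    stress = prony_stress(material, t, strain)
    sd = material.noise_sd
    if sd is None:
        pre_mask = t < protocol.precondition_cycles / protocol.precondition_frequency
        sd = 0.005 * float(np.max(stress[pre_mask]))
    if sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, sd, size=stress.size)
    trace = StressStrainTrace(t, stress, strain, labels)
    return SimulatedTrace(trace, material, protocol, seed, _analytic_truth(material, protocol))


# ----------------------------------------------------------------------
# exponential decay series (energy-dissipation ground truth)
# ----------------------------------------------------------------------

def generate_decay_series(A: float, tau: float, y0: float,
                          times: Sequence[float], noise_sd: float = 0.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """y(t) = A exp(-t/tau) + y0 plus seeded Gaussian noise."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    y = A * np.exp(-t / tau) + y0
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return t, y


# ----------------------------------------------------------------------
# plumbing helpers
# ----------------------------------------------------------------------

def generate_approach_ramp(thickness: float = 1.0, stiffness: float = 0.5,
                           initial_gap: float = 1.5, speed: float = 0.01,
                           sample_rate: float = 100.0, overtravel: float = 0.15,
                           ) -> TimeSeriesRecord:
    """Actuator approach ramp against an elastic specimen.

    Force is zero until the platen gap closes to ``thickness`` (mm), then
    grows linearly with ``stiffness`` (N/mm of compression).  Used to
    exercise preload-contact thickness detection.
    """
    travel = initial_gap - thickness + overtravel
    n = int(round(travel / speed * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    disp = speed * t
    gap = initial_gap - disp
    force = np.where(gap < thickness, stiffness * (thickness - gap), 0.0)
    return TimeSeriesRecord(t, force, disp)


def trace_to_record(sim: SimulatedTrace, geometry: SpecimenGeometry) -> TimeSeriesRecord:
    """Convert a simulated stress/strain trace to force/displacement."""
    if geometry.thickness is None:
        raise ValueError("geometry thickness must be set")
    area_m2 = geometry.cross_section_area * 1e-6
    force = sim.trace.stress * area_m2
    disp = sim.trace.strain * geometry.thickness
    return TimeSeriesRecord(sim.trace.time, force, disp)
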