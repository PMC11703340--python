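"""DMA endpoint extraction from a labelled stress/strain trace.

Five endpoints are extracted from the unconfined-compression protocol:

* **compressive linear modulus** — slope of an ordinary least-squares line
  through the 12 samples centred on the peak dS/dE of the loading arc of
  the final preconditioning cycle;
* **equilibrium modulus** — tail-mean relaxation stress divided by the held
  strain;
* **stress relaxation %** — fractional drop from the post-ramp peak stress
  to the equilibrium stress;
* **dynamic modulus |E*|** and **phase shift delta** — stress and strain
  amplitude ratio and phase lag from sinusoid fits to the last cycles of
  the dynamic segment.

Sinusoids are fit at the known protocol frequency by linear least squares
(``y = c + a sin(wt) + b cos(wt)``), which is deterministic and avoids a
free-frequency nonlinear fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import StressStrainTrace
from .protocol import ProtocolSpec

__all__ = [
    "SinusoidFit",
    "DmaEndpoints",
    "compressive_linear_modulus",
    "equilibrium_modulus",
    "stress_relaxation_percent",
    "dynamic_modulus_and_phase",
    "extract_endpoints",
    "fit_sinusoid",
]


@dataclass
class SinusoidFit:
    """Least-squares fit of y = mean + amplitude * sin(w t + phase)."""

    mean_level: float
    amplitude: float
    phase: float  # radians, wrapped to (-pi, pi]
    angular_frequency: float
    residual_rms: float


@dataclass
class DmaEndpoints:
    compressive_modulus: float  # Pa
    equilibrium_modulus: float  # Pa
    stress_relaxation: float  # %
    dynamic_modulus: float  # Pa
    phase_shift: float  # radians
    diagnostics: dict = field(default_factory=dict)


def fit_sinusoid(t: np.ndarray, y: np.ndarray, omega: float) -> SinusoidFit:
    """Fit y = c + a sin(wt) + b cos(wt) at known omega; amplitude/phase form.

    amplitude = hypot(a, b); phase = atan2(b, a) so that
    y = c + amplitude * sin(wt + phase).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c, a, b = coef
    resid = y - X @ coef
    phase = math.atan2(b, a)
    return SinusoidFit(float(c), float(math.hypot(a, b)), phase, omega,
                       float(np.sqrt(np.mean(resid**2))))


def _loading_arc_of_last_cycle(trace: StressStrainTrace, protocol: ProtocolSpec,
                               ) -> tuple[np.ndarray, np.ndarray]:
    label = f"precondition:{protocol.precondition_cycles}"
    seg = trace.segment(label)
    peak = int(np.argmax(seg.strain))
    return seg.strain[: peak + 1], seg.stress[: peak + 1]


def compressive_linear_modulus(trace: StressStrainTrace,
                               protocol: ProtocolSpec,
                               n_points: int = 12) -> tuple[float, dict]:
    """Slope at the peak dS/dE of the final preconditioning loading arc.

    The derivative is taken by central differences over the arc; the 12-point
    OLS window is centred on the (first) peak, 6 samples each side, shifted
    inward (never shrunk) at the arc boundaries.
    """
    strain, stress = _loading_arc_of_last_cycle(trace, protocol)
    n = strain.size
    if n < n_points:
        raise ValueError(f"loading arc has {n} samples; need >= {n_points}")
    ds_de = np.gradient(stress, strain)
    if not np.all(np.isfinite(ds_de)):
        raise ValueError("non-finite dS/dE on the loading arc")
    # exclude the turnaround tips: where the strain rate vanishes the
    # stress/strain tangent of a viscoelastic loop diverges (vertical loop
    # tip), which is an artifact, not material stiffness
    d_eps = np.gradient(strain)
    advancing = d_eps >= 0.1 * float(np.max(d_eps))
    masked = np.where(advancing, ds_de, -np.inf)
    peak = int(np.argmax(masked))  # first occurrence on ties
    lo = peak - n_points // 2
    lo = max(0, min(lo, n - n_points))
    window = slice(lo, lo + n_points)
    slope, intercept = np.polyfit(strain[window], stress[window], 1)
    fitted = slope * strain[window] + intercept
    ss_res = float(np.sum((stress[window] - fitted) ** 2))
    ss_tot = float(np.sum((stress[window] - stress[window].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    diag = {"peak_dsde_index": peak, "window": (lo, lo + n_points), "r_squared": r2}
    return float(slope), diag


def equilibrium_modulus(trace: StressStrainTrace, tail_window: float = 10.0,
                        ) -> tuple[float, dict]:
    """sigma_eq / held strain, with sigma_eq the mean over the final tail."""
    seg = trace.segment("relaxation")
    t_end = seg.time[-1]
    m = seg.time >= t_end - tail_window
    sigma_eq = float(np.mean(seg.stress[m]))
    held = float(np.median(seg.strain))
    if held <= 0:
        raise ValueError("held strain is zero during relaxation")
    return sigma_eq / held, {"sigma_eq": sigma_eq, "held_strain": held,
                             "tail_samples": int(m.sum())}


def stress_relaxation_percent(trace: StressStrainTrace, tail_window: float = 10.0,
                              peak_search_hold: float = 1.0) -> tuple[float, dict]:
    """100 (sigma_peak - sigma_eq) / sigma_peak.

    sigma_peak is searched over the ramp plus the first ``peak_search_hold``
    seconds of the hold, to catch the overshoot directly after compression.
    """
    ramp = trace.segment("ramp")
    relax = trace.segment("relaxation")
    early = relax.time <= relax.time[0] + peak_search_hold
    sigma_peak = float(max(np.max(ramp.stress), np.max(relax.stress[early])))
    if sigma_peak <= 0:
        raise ValueError("peak stress must be positive")
    m = relax.time >= relax.time[-1] - tail_window
    sigma_eq = float(np.mean(relax.stress[m]))
    pct = 100.0 * (sigma_peak - sigma_eq) / sigma_peak
    return pct, {"sigma_peak": sigma_peak, "sigma_eq": sigma_eq}


def dynamic_modulus_and_phase(trace: StressStrainTrace, protocol: ProtocolSpec,
                              n_cycles: int = 3,
                              ) -> tuple[float, float, SinusoidFit, SinusoidFit]:
    """|E*| and delta from sinusoid fits to the last n_cycles dynamic cycles.

    |E*| = stress amplitude / strain amplitude; delta = stress phase minus
    strain phase, wrapped to the centred interval (-pi/2, pi/2].  Passive
    materials give delta in [0, pi/2); values a hair below zero can occur
    under measurement noise when the true lag is itself near zero.
    """
    seg = trace.segment("dynamic")
    omega = protocol.dynamic_angular_frequency
    period = 2.0 * math.pi / omega
    total = seg.time[-1] - seg.time[0]
    if total + 1e-9 < n_cycles * period:
        raise ValueError(f"dynamic segment shorter than {n_cycles} cycles")
    m = seg.time >= seg.time[-1] - n_cycles * period
    t, stress, strain = seg.time[m], seg.stress[m], seg.strain[m]
    stress_fit = fit_sinusoid(t, stress, omega)
    strain_fit = fit_sinusoid(t, strain, omega)
    if strain_fit.amplitude <= 1e-12:
        raise ValueError("strain amplitude is ~0 in the dynamic segment")
    e_star = stress_fit.amplitude / strain_fit.amplitude
    # centred wrap resolves the pi ambiguity of the amplitude/phase pair
    # without folding a noise-level negative lag up to ~pi
    delta = (stress_fit.phase - strain_fit.phase + math.pi / 2) % math.pi \
        - math.pi / 2
    delta = abs(delta) if abs(delta) < 1e-12 else delta
    return float(e_star), float(delta), stress_fit, strain_fit


def extract_endpoints(trace: StressStrainTrace, protocol: ProtocolSpec,
                      tail_window: float = 10.0, n_cycles: int = 3) -> DmaEndpoints:
    """All five endpoints plus per-fit diagnostics."""
    comp, d1 = compressive_linear_modulus(trace, protocol)
    eq, d2 = equilibrium_modulus(trace, tail_window)
    relax, d3 = stress_relaxation_percent(trace, tail_window)
    e_star, delta, sfit, efit = dynamic_modulus_and_phase(trace, protocol, n_cycles)
    diag = {"compressive": d1, "equilibrium": d2, "relaxation": d3,
            "stress_fit_rms": sfit.residual_rms, "strain_fit_rms": efit.residual_rms}
    return DmaEndpoints(comp, eq, relax, e_star, delta, diag)
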