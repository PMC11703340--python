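"""Hysteresis loops, dissipated/strain energies, and exponential-decay fits.

Each preconditioning cycle traces a closed loop in stress/strain space.
The area enclosed by the loading and unloading arcs is the energy density
dissipated in that cycle (J/m^3 for stress in Pa and dimensionless strain;
reported in kJ/m^3); the area under the loading arc is the strain energy
put into the cycle.  Dissipated energy per cycle decays roughly
exponentially toward a steady-state level as the material shakes down, and
is modelled as

    y_fit(t)      = A exp(-t/tau) + y0
    y_normalized  = y_fit / A
    y_adjusted    = (y_fit - y0) / A = exp(-t/tau)

fitted by bounded trust-region nonlinear least squares with deterministic
restarts, with RMSE, R^2 and the regression-F diagnostics the fit quality
is judged by.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mechanics import StressStrainTrace

__all__ = [
    "HysteresisLoop",
    "DecayFit",
    "extract_hysteresis_loops",
    "loop_energies",
    "max_stress",
    "energy_decay_series",
    "fit_energy_decay",
    "compare_first_last",
]


@dataclass
class HysteresisLoop:
    """One preconditioning cycle split into loading and unloading arcs."""

    cycle_index: int  # 1-based
    loading_strain: np.ndarray
    loading_stress: np.ndarray
    unloading_strain: np.ndarray
    unloading_stress: np.ndarray
    cycle_end_time: float
    dissipated_energy: float = float("nan")  # kJ/m^3
    strain_energy: float = float("nan")  # kJ/m^3

    @property
    def max_stress(self) -> float:
        return float(max(np.max(self.loading_stress), np.max(self.unloading_stress)))


@dataclass
class DecayFit:
    A: float
    tau: float
    y0: float
    rmse: float
    r_squared: float
    f_statistic: float
    p_value: float
    times: np.ndarray
    observed: np.ndarray
    fitted_series: np.ndarray
    normalized_series: np.ndarray
    adjusted_series: np.ndarray
    tau_identifiable: bool = True
    converged: bool = True


def extract_hysteresis_loops(trace: StressStrainTrace) -> list[HysteresisLoop]:
    """Split each labelled preconditioning cycle at its strain maximum."""
    labels = sorted({str(s) for s in trace.segment_labels
                     if str(s).startswith("precondition:")},
                    key=lambda s: int(s.split(":")[1]))
    if not labels:
        raise ValueError("trace has no labelled preconditioning cycles")
    loops = []
    for lab in labels:
        # exact match, not prefix: precondition:1 must not absorb :10
        exact = np.array([str(s) == lab for s in trace.segment_labels])
        seg = StressStrainTrace(trace.time[exact], trace.stress[exact],
                                trace.strain[exact], trace.segment_labels[exact])
        peak = int(np.argmax(seg.strain))
        if peak == 0 or peak == len(seg) - 1:
            raise ValueError(f"cycle '{lab}' has monotone strain (no turning point)")
        k = int(lab.split(":")[1])
        loop = HysteresisLoop(
            cycle_index=k,
            loading_strain=seg.strain[: peak + 1],
            loading_stress=seg.stress[: peak + 1],
            unloading_strain=seg.strain[peak:],
            unloading_stress=seg.stress[peak:],
            cycle_end_time=float(seg.time[-1]),
        )
        loop.dissipated_energy, loop.strain_energy = loop_energies(loop)
        loops.append(loop)
    return loops


def loop_energies(loop: HysteresisLoop) -> tuple[float, float]:
    """(dissipated, strain energy) in kJ/m^3 by trapezoidal integration.

    Dissipated = closed-cycle integral of sigma d-epsilon (loading integral
    minus unloading integral, both taken in increasing-strain direction).
    A signed result below -1e-9 kJ/m^3 flags an orientation bug and raises.
    """
    if loop.loading_strain.size < 2 or loop.unloading_strain.size < 2:
        raise ValueError("degenerate loop arcs (< 2 points)")
    load = np.trapezoid(loop.loading_stress, loop.loading_strain)
    # unloading arc runs from peak strain back down; integrate along the path
    unload = -np.trapezoid(loop.unloading_stress, loop.unloading_strain)
    dissipated = (load - unload) / 1e3  # J/m^3 -> kJ/m^3
    if dissipated < -1e-9:
        raise ValueError(f"negative dissipated energy {dissipated:.3e} kJ/m^3: "
                         "loop orientation bug")
    strain_energy = load / 1e3
    return abs(float(dissipated)), float(strain_energy)


def max_stress(loop: HysteresisLoop) -> float:
    """Peak stress over both arcs of the loop (Pa)."""
    return loop.max_stress


def energy_decay_series(loops: list[HysteresisLoop],
                        normalize_by: str = "none",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(t, y): cycle-end times vs dissipated energy per cycle.

    ``normalize_by='cycle1_max_stress'`` divides every energy by the peak
    stress of the first cycle in kPa, matching the per-sample-set
    normalization used before decay fitting (units then kJ/m^3 per kPa).
    """
    if len(loops) < 3:
        raise ValueError("need >= 3 loops for a decay series")
    loops = sorted(loops, key=lambda l: l.cycle_index)
    t = np.array([l.cycle_end_time for l in loops])
    y = np.array([l.dissipated_energy for l in loops])
    if normalize_by == "cycle1_max_stress":
        ref = loops[0].max_stress / 1e3  # Pa -> kPa
        if ref == 0:
            raise ValueError("cycle-1 max stress is zero; cannot normalize")
        y = y / ref
    elif normalize_by != "none":
        raise ValueError(f"unknown normalization '{normalize_by}'")
    return t, y


def _decay_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, tau, y0 = params
    return A * np.exp(-t / tau) + y0


def fit_energy_decay(times: np.ndarray, values: np.ndarray,
                     max_restarts: int = 3) -> DecayFit:
    """Fit y = A exp(-t/tau) + y0 by bounded nonlinear least squares.

    Deterministic initialization (y0 = min y, A = y(t1) - y0, tau = span/3)
    with restarts at tau0 * {0.3, 1, 3}; bounds A >= 0, tau > 0.  A flat
    series returns A = 0 with tau flagged unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 points to fit the decay model")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the series")

    scale = float(np.max(np.abs(y))) or 1.0
    y0_init = float(np.min(y))
    a_init = max(float(y[0] - y0_init), 1e-12 * scale)
    tau_base = (t[-1] - t[0]) / 3.0

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= (1e-12 * scale) ** 2 * t.size:
        # degenerate flat series
        fitted = np.full_like(y, y.mean())
        return DecayFit(0.0, float("nan"), float(y.mean()), 0.0, 1.0,
                        float("nan"), float("nan"), t, y, fitted,
                        np.full_like(y, np.inf), np.zeros_like(y),
                        tau_identifiable=False)

    best = None
    for mult in (0.3, 1.0, 3.0)[: max_restarts]:
        x0 = np.array([a_init, tau_base * mult, y0_init])
        try:
            res = optimize.least_squares(
                lambda p: _decay_model(p, t) - y, x0,
                bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = 2.0 * res.cost
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise RuntimeError("decay fit failed to converge from all restarts")
    sse, res = best
    A, tau, y0 = (float(v) for v in res.x)
    n = t.size
    fitted = _decay_model(res.x, t)
    rmse = math.sqrt(sse / n)
    r2 = 1.0 - sse / sst
    # regression F: exponential model (3 params) vs intercept-only, df (2, n-3)
    df1, df2 = 2, n - 3
    if sse <= 0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = ((sst - sse) / df1) / (sse / df2)
        p_val = float(stats.f.sf(f_stat, df1, df2))
    a_floor = 1e-9 * scale
    identifiable = A > a_floor
    normalized = fitted / A if identifiable else np.full_like(fitted, np.inf)
    adjusted = (fitted - y0) / A if identifiable else np.zeros_like(fitted)
    return DecayFit(A, tau if identifiable else float("nan"), y0, rmse, r2,
                    f_stat, p_val, t, y, fitted, normalized, adjusted,
                    tau_identifiable=identifiable, converged=res.success)


def compare_first_last(loops_by_specimen: dict[str, list[HysteresisLoop]],
                       first: int = 1, last: int = 8,
                       ) -> list[tuple[str, float, float]]:
    """Per-specimen (id, cycle-1 energy, cycle-8 energy) pairs.

    Specimens with fewer than ``last`` cycles are excluded with a warning.
    The result feeds the paired t-test comparing start-up to shaken-down
    dissipation.
    """
    pairs = []
    for sid, loops in loops_by_specimen.items():
        by_idx = {l.cycle_index: l for l in loops}
        if first not in by_idx or last not in by_idx:
            warnings.warn(f"specimen '{sid}' lacks cycle {last}; excluded",
                          stacklevel=2)
            continue
        pairs.append((sid, by_idx[first].dissipated_energy,
                      by_idx[last].dissipated_energy))
    return pairs
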