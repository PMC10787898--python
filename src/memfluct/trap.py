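"""Optical-trap calibration, tether force and apparent membrane tension.

The trap is calibrated by equipartition, k = k_B T / <x^2>, from a no-load
segment of the bead trajectory.  The tether force during the parked period
is F = k |<x>|, and the apparent membrane tension follows from the
Canham-Helfrich tether relation sigma_A = F^2 / (8 pi^2 kappa) with the
bending rigidity fixed at 15 k_B T.  Because sigma_A is quadratic in F, a
fractional force reduction r_F maps to a tension reduction
r_sigma = 1 - (1 - r_F)^2 (e.g. 2% -> ~4%, 52% -> ~77%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_B, kappa_default
from .synthetic import TrapTrace

__all__ = ["TetherResult", "trap_stiffness", "tether_force",
           "apparent_tension", "tension_fold_change", "analyze_tether_trace"]


@dataclass
class TetherResult:
    """Trap stiffness, tether force and Canham-Helfrich apparent tension."""

    stiffness: float          # N/m
    tether_force_pN: float
    apparent_tension: float   # N/m
    kappa: float              # J
    parked_window_s: tuple[float, float] | None = None


def trap_stiffness(trace: TrapTrace,
                   no_load_window_s: tuple[float, float] | None = None
                   ) -> float:
    """Equipartition stiffness k = k_B T / Var(x) (N/m).

    ``no_load_window_s`` delimits the stationary unloaded segment (default:
    the first 10 s of the trace).  The segment mean is subtracted before the
    variance, so a constant offset of the position detector drops out.
    """
    x = np.asarray(trace.x, dtype=float)
    t = np.arange(x.size) / trace.sample_rate
    if no_load_window_s is None:
        no_load_window_s = (0.0, min(10.0, t[-1]))
    sel = (t >= no_load_window_s[0]) & (t <= no_load_window_s[1])
    if sel.sum() < 100:
        raise ValueError("no-load window contains fewer than 100 samples")
    var = float(np.var(x[sel]))
    if var <= 0:
        raise ValueError("zero variance in the no-load window")
    return K_B * trace.temperature / var


def tether_force(trace: TrapTrace, stiffness: float,
                 parked_window_s: tuple[float, float],
                 baseline: float = 0.0) -> float:
    """Tether force (pN) from the mean bead displacement while parked:
    F = k * |<x> - baseline| over the parked window."""
    x = np.asarray(trace.x, dtype=float)
    t = np.arange(x.size) / trace.sample_rate
    sel = (t >= parked_window_s[0]) & (t <= parked_window_s[1])
    if not sel.any():
        raise ValueError("parked window lies outside the trace")
    mean_disp = float(np.mean(x[sel])) - baseline
    return stiffness * abs(mean_disp) * 1e12


def apparent_tension(force_pN: float, kappa: float | None = None) -> float:
    """Canham-Helfrich apparent membrane tension sigma_A = F^2/(8 pi^2 kappa)
    in N/m, for a tether force in pN (kappa defaults to 15 k_B T)."""
    if force_pN < 0:
        raise ValueError("force must be >= 0")
    if kappa is None:
        kappa = kappa_default()
    F = force_pN * 1e-12
    return F ** 2 / (8.0 * np.pi ** 2 * kappa)


def tension_fold_change(force_before_pN: float, force_after_pN: float
                        ) -> tuple[float, float]:
    """Fractional reductions (r_F, r_sigma) between two tether forces.

    r_F = 1 - F_after/F_before; the quadratic force-tension relation gives
    r_sigma = 1 - (1 - r_F)^2, so r_sigma >= r_F always.
    """
    if force_before_pN <= 0:
        raise ValueError("baseline force must be positive")
    r_f = 1.0 - force_after_pN / force_before_pN
    r_sigma = 1.0 - (1.0 - r_f) ** 2
    return r_f, r_sigma


def analyze_tether_trace(trace: TrapTrace,
                         parked_window_s: tuple[float, float],
                         no_load_window_s: tuple[float, float] | None = None,
                         kappa: float | None = None) -> TetherResult:
    """Full single-trace analysis: stiffness, parked-window force, tension."""
    k = trap_stiffness(trace, no_load_window_s)
    F = tether_force(trace, k, parked_window_s)
    if kappa is None:
        kappa = kappa_default(trace.temperature)
    return TetherResult(stiffness=k, tether_force_pN=F,
                        apparent_tension=apparent_tension(F, kappa),
                        kappa=kappa, parked_window_s=parked_window_s)
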