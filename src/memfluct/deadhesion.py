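"""Spread-area time courses and de-adhesion phase classification.

After adding the de-adhering agent (trypsin), a cell's spread area passes
through four phases: C (untreated baseline), P1 (slow early detachment, area
still within 90% of baseline), P2 (exponential area loss, reaching at least
~67% of baseline) and P3 (area stabilised at ~40-20% of baseline).  The
de-adhesion time t67 is the first crossing of 67% of baseline.  Per-cell
fold changes normalise a quantity measured at P2 or P3 by its value at C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AreaSeries", "PhaseSeries", "time_to_fraction",
           "classify_phases", "normalize_to_C"]


@dataclass
class AreaSeries:
    """Cell spread area (um^2) vs time (min), with the treatment time."""

    time_min: np.ndarray
    area_um2: np.ndarray
    treatment_time_min: float = 0.0
    cell_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        if self.time_min.shape != self.area_um2.shape:
            raise ValueError("time and area must match")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be increasing")
        if np.any(self.area_um2 <= 0):
            raise ValueError("areas must be positive")

    @property
    def baseline(self) -> float:
        """Mean area over pre-treatment samples."""
        pre = self.time_min < self.treatment_time_min
        if not pre.any():
            return float(self.area_um2[0])
        return float(self.area_um2[pre].mean())


@dataclass
class PhaseSeries:
    """Per-sample phase labels and boundary times."""

    labels: np.ndarray               # array of "C"/"P1"/"P2"/"P3"/""
    t67_min: float | None
    t67_reason: str = ""
    boundaries: dict | None = None   # phase -> start time
    p3_flag: str = ""                # why P3 is absent, if it is


def time_to_fraction(series: AreaSeries, fraction: float = 0.67
                     ) -> tuple[float | None, str]:
    """First time (min after treatment) the area crosses ``fraction`` of
    baseline, linearly interpolated between samples; (None, reason) when the
    series never crosses."""
    base = series.baseline
    target = fraction * base
    t, a = series.time_min, series.area_um2
    post = t >= series.treatment_time_min
    t, a = t[post], a[post]
    below = a <= target
    if not below.any():
        return None, f"area never reached {fraction:.0%} of baseline"
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0] - series.treatment_time_min), ""
    # linear interpolation between the bracketing samples
    t_cross = t[i - 1] + (target - a[i - 1]) * (t[i] - t[i - 1]) \
        / (a[i] - a[i - 1])
    return float(t_cross - series.treatment_time_min), ""


def classify_phases(series: AreaSeries,
                    p1_fraction: float = 0.90,
                    p2_fraction: float = 0.67,
                    p3_band: tuple[float, float] = (0.20, 0.40),
                    stable_slope_per_min: float = 0.02,
                    stable_window_min: float = 2.0) -> PhaseSeries:
    """Label each sample C/P1/P2/P3.

    C before treatment; P1 from treatment until the area first drops below
    ``p1_fraction`` of baseline; P2 from then until the area has both
    reached ``p2_fraction`` of baseline and its relative slope magnitude has
    fallen below ``stable_slope_per_min`` over ``stable_window_min``; P3
    afterwards while the area sits inside ``p3_band`` of baseline.  A series
    that ends mid-P2, or stabilises outside the P3 band, has no P3 and the
    reason is flagged.
    """
    t, a = series.time_min, series.area_um2
    base = series.baseline
    rel = a / base
    n = t.size
    labels = np.array([""] * n, dtype=object)
    labels[t < series.treatment_time_min] = "C"

    post = np.where(t >= series.treatment_time_min)[0]
    state = "P1"
    reached_p2_depth = False
    boundaries = {"C": float(t[0])}
    p3_flag = ""
    for i in post:
        if state == "P1":
            if rel[i] < p1_fraction:
                state = "P2"
                boundaries.setdefault("P1", float(t[post[0]]))
                boundaries["P2"] = float(t[i])
            else:
                boundaries.setdefault("P1", float(t[post[0]]))
        if state == "P2":
            if rel[i] <= p2_fraction:
                reached_p2_depth = True
            if reached_p2_depth:
                # rate stability over a trailing window
                w = (t >= t[i] - stable_window_min) & (t <= t[i])
                if w.sum() >= 2:
                    slope = np.polyfit(t[w], rel[w], 1)[0]
                    if abs(slope) < stable_slope_per_min:
                        if p3_band[0] <= rel[i] <= p3_band[1]:
                            state = "P3"
                            boundaries["P3"] = float(t[i])
                        else:
                            p3_flag = ("area stabilised at "
                                       f"{rel[i]:.2f} of baseline, outside "
                                       f"the {p3_band} band")
        labels[i] = state
    if "P3" not in boundaries and not p3_flag:
        if reached_p2_depth:
            p3_flag = "series ended before the area stabilised (mid-P2)"
        elif "P2" in boundaries:
            p3_flag = "area never reached the P2 depth criterion"
        else:
            p3_flag = "no de-adhesion beyond P1 observed"
    t67, reason = time_to_fraction(series, p2_fraction)
    return PhaseSeries(labels=labels, t67_min=t67, t67_reason=reason,
                       boundaries=boundaries, p3_flag=p3_flag)


def normalize_to_C(values_by_phase: dict, cells=None) -> dict:
    """Per-cell fold changes: divide each cell's P2/P3 value by its C value.

    ``values_by_phase`` maps cell id -> {"C": v, "P2": v, "P3": v} (P2/P3
    optional).  Cells without a usable (present, nonzero) C value are
    excluded and listed under "excluded".
    """
    out = {"P2": {}, "P3": {}, "excluded": []}
    for cell, vals in values_by_phase.items():
        c = vals.get("C")
        if c is None or not np.isfinite(c) or c == 0:
            out["excluded"].append((cell, "missing or zero C value"))
            continue
        for ph in ("P2", "P3"):
            if ph in vals and vals[ph] is not None \
                    and np.isfinite(vals[ph]):
                out[ph][cell] = vals[ph] / c
    return out
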