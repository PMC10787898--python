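"""Fluctuation amplitudes and excess membrane area from height movies.

SD_time is the per-pixel standard deviation of relative height across the
movie's frames (averaged over an FBR's pixels to give the FBR value);
SD_space is the standard deviation across an FBR's pixels of the
time-averaged height; excess area compares the true undulating membrane
area A = sum sqrt(1 + h_x^2 + h_y^2) dx dy with the projected flat area A_P,
reported as 100 * (A - A_P) / A.  All three are invariant under a global
height offset.  Population (not sample) SDs are used throughout.
"""

from __future__ import annotations

import numpy as np

from .synthetic import HeightMovie

__all__ = ["sd_time_map", "sd_time_fbr", "sd_space", "excess_area_fraction",
           "fluctuation_summary"]


def sd_time_map(movie: HeightMovie) -> np.ndarray:
    """Per-pixel SD (nm) of height over frames; NaN pixels stay NaN."""
    h = movie.h
    if h.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    valid = np.all(np.isfinite(h), axis=0)
    out = np.full(h.shape[1:], np.nan)
    out[valid] = h[:, valid].std(axis=0)
    return out


def sd_time_fbr(movie: HeightMovie, fbrs) -> list[float]:
    """FBR-wise SD_time: mean of the member pixels' temporal SDs."""
    m = sd_time_map(movie)
    vals = []
    for fbr in fbrs:
        r0, c0 = fbr.origin
        s = fbr.side_pixels
        vals.append(float(np.nanmean(m[r0:r0 + s, c0:c0 + s])))
    return vals


def sd_space(movie: HeightMovie, fbr=None, n_average_frames: int = 20,
             frame_range: tuple[int, int] | None = None) -> float:
    """SD (nm) across an FBR's pixels of the height averaged over the first
    ``n_average_frames`` frames (or an explicit ``frame_range``)."""
    h = movie.h
    if frame_range is None:
        frame_range = (0, n_average_frames)
    if h.shape[0] < frame_range[1]:
        raise ValueError(f"need at least {frame_range[1]} frames")
    if fbr is not None:
        r0, c0 = fbr.origin
        s = fbr.side_pixels
        h = h[:, r0:r0 + s, c0:c0 + s]
    mean_img = h[frame_range[0]:frame_range[1]].mean(axis=0)
    return float(np.std(mean_img[np.isfinite(mean_img)]))


def excess_area_fraction(height_map: np.ndarray, pixel_size_nm: float
                         ) -> float:
    """Percentage excess area of a single height map over a window.

    Per-pixel surface element dA = sqrt(1 + h_x^2 + h_y^2) dx dy with
    gradients by central differences in the interior and one-sided at the
    window edges; returns 100 * (A - A_P) / A.  A window containing NaN is
    rejected (the conversion flagged pixels off the first branch).
    """
    h = np.asarray(height_map, dtype=float)
    if h.ndim != 2 or min(h.shape) < 2:
        raise ValueError("need a 2-d window of at least 2x2 pixels")
    if not np.all(np.isfinite(h)):
        raise ValueError("window contains missing pixels")
    hy, hx = np.gradient(h, pixel_size_nm)
    dA = np.sqrt(1.0 + hx ** 2 + hy ** 2)
    A = dA.sum()
    A_P = float(h.size)          # in units of pixel_size^2
    return 100.0 * (A - A_P) / A


def fluctuation_summary(movie: HeightMovie, fbrs,
                        n_average_frames: int = 20):
    """Per-FBR table of sd_time, sd_space and excess area (on the
    20-frame-averaged height map), as a list of dicts ready for a DataFrame."""
    sm = sd_time_map(movie)
    rows = []
    for i, fbr in enumerate(fbrs):
        r0, c0 = fbr.origin
        s = fbr.side_pixels
        block = movie.h[:, r0:r0 + s, c0:c0 + s]
        mean_img = block[:n_average_frames].mean(axis=0)
        try:
            ea = excess_area_fraction(mean_img, movie.pixel_size_nm)
        except ValueError:
            ea = np.nan
        rows.append({
            "fbr": i, "origin_row": r0, "origin_col": c0, "side_pixels": s,
            "sd_time_nm": float(np.nanmean(sm[r0:r0 + s, c0:c0 + s])),
            "sd_space_nm": sd_space(movie, fbr,
                                    n_average_frames=n_average_frames),
            "excess_area_percent": ea,
        })
    return rows
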