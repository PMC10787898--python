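"""IRM intensity-to-height conversion and first-branch region selection.

Interference reflection microscopy encodes the basal-membrane height h above
the coverslip in the reflected intensity

    I(h) = offset - amplitude * cos(4 pi n h / lambda),

darkest at contact (h = 0) and rising monotonically over the first branch
h in [0, lambda/(4 n)] (~102 nm for lambda = 546 nm in aqueous medium,
n = 1.335).  Heights are therefore recoverable without ambiguity only in
windows whose intensities stay on that first branch — first-branch regions
(FBRs).  Calibration of (offset, amplitude) comes from imaging a large bead
of known geometry resting on the coverslip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import NM
from .synthetic import HeightMovie, OpticsConfig

__all__ = ["Calibration", "FBR", "calibrate_from_bead", "intensity_to_height",
           "height_movie_from_irm", "select_fbrs"]


@dataclass
class Calibration:
    """Interference calibration: intensity scale plus optical constants."""

    intensity_offset: float
    intensity_amplitude: float
    wavelength: float = 546.0        # nm
    refractive_index: float = 1.335
    residual_rms: float = 0.0        # of the bead-profile fit

    def __post_init__(self) -> None:
        if self.intensity_amplitude <= 0:
            raise ValueError("intensity_amplitude must be positive")

    @property
    def branch_height_span(self) -> float:
        """First-branch height extent lambda/(4 n), in nm."""
        return self.wavelength / (4.0 * self.refractive_index)


@dataclass
class FBR:
    """A square first-branch window: origin (row, col), side in pixels."""

    origin: tuple[int, int]
    side_pixels: int = 12
    pixel_size_nm: float = 72.2

    @property
    def area_um2(self) -> float:
        return (self.side_pixels * self.pixel_size_nm * 1e-3) ** 2


def calibrate_from_bead(bead_image: np.ndarray, bead_radius_um: float,
                        optics: OpticsConfig,
                        center: tuple[float, float] | None = None,
                        ) -> Calibration:
    """Fit (offset, amplitude) from the radial intensity profile of a large
    calibration bead resting on the coverslip.

    The height profile under a sphere of radius R is h(r) = R - sqrt(R^2 -
    r^2), which sweeps several interference fringes within a small radius, so
    a nonlinear least-squares fit of I(r) = offset - amplitude*cos(4 pi n
    h(r)/lambda) determines the intensity scale.  The phase is fixed by the
    dark-contact convention (minimum at h = 0).  Fails if less than one full
    fringe is inside the image.
    """
    img = np.asarray(bead_image, dtype=float)
    if center is None:
        # contact point: darkest pixel after mild smoothing
        from scipy.ndimage import uniform_filter
        sm = uniform_filter(img, size=5)
        center = np.unravel_index(np.argmin(sm), sm.shape)
    R = bead_radius_um * 1e3  # nm
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    r = np.hypot(yy - center[0], xx - center[1]) * optics.pixel_size
    h = np.where(r < R, R - np.sqrt(np.maximum(R ** 2 - r ** 2, 0.0)), np.nan)
    valid = np.isfinite(h)
    span = optics.wavelength / (2.0 * optics.refractive_index)  # full fringe
    if np.nanmax(h) < span:
        raise ValueError("bead image spans less than one interference fringe")
    # restrict to a few fringes where the radial sampling is dense enough
    sel = valid & (h <= 4.0 * span)
    hv, iv = h[sel], img[sel]

    def model(hh, offset, amplitude):
        return offset - amplitude * np.cos(
            4.0 * np.pi * optics.refractive_index * hh / optics.wavelength)

    p0 = (float(iv.mean()), float((iv.max() - iv.min()) / 2.0))
    popt, _ = curve_fit(model, hv, iv, p0=p0)
    offset, amplitude = float(popt[0]), float(abs(popt[1]))
    rms = float(np.sqrt(np.mean((model(hv, offset, amplitude) - iv) ** 2)))
    return Calibration(intensity_offset=offset, intensity_amplitude=amplitude,
                       wavelength=optics.wavelength,
                       refractive_index=optics.refractive_index,
                       residual_rms=rms)


def intensity_to_height(intensity: np.ndarray, cal: Calibration,
                        clamp_tolerance: float = 0.01) -> np.ndarray:
    """Convert first-branch IRM intensity to height (nm).

    h = (lambda / (4 pi n)) * arccos((offset - I) / amplitude), monotone in I
    over the branch, range [0, lambda/(4 n)].  Normalized intensities within
    ``clamp_tolerance`` outside [-1, 1] are clamped (camera noise); anything
    further off-branch becomes NaN rather than an extrapolated height.
    """
    arg = (cal.intensity_offset - np.asarray(intensity, dtype=float)) \
        / cal.intensity_amplitude
    out_of_branch = np.abs(arg) > 1.0 + clamp_tolerance
    arg = np.clip(arg, -1.0, 1.0)
    h = cal.wavelength / (4.0 * np.pi * cal.refractive_index) * np.arccos(arg)
    if np.any(out_of_branch):
        h = np.where(out_of_branch, np.nan, h)
    return h


def _unfold_phase(theta_folded: np.ndarray,
                  theta_range: tuple[float, float] = (-np.pi, 2.0 * np.pi)
                  ) -> np.ndarray:
    """Continue a folded interference phase in time.

    ``theta_folded`` (frames, ...) lies in [0, pi] (arccos output).  The true
    phase theta = 4 pi n h / lambda is known only up to the even-periodic
    folding theta -> arccos(cos(theta)).  Frame-to-frame continuity picks,
    at each step, the candidate 2 pi k +/- theta_f closest to the previous
    phase, which undoes transversal branch crossings; shallow grazing
    excursions remain clipped at the fold.  Candidates are restricted to
    ``theta_range`` (default: one interference branch on either side of the
    principal one) so that occasional tracking errors cannot drift across
    many branches.
    """
    tf = np.asarray(theta_folded, dtype=float)
    out = np.empty_like(tf)
    out[0] = tf[0]
    two_pi = 2.0 * np.pi
    lo, hi = theta_range
    for t in range(1, tf.shape[0]):
        prev = out[t - 1]
        plus = tf[t] + two_pi * np.round((prev - tf[t]) / two_pi)
        minus = -tf[t] + two_pi * np.round((prev + tf[t]) / two_pi)
        # out-of-range candidates are folded back by one period
        plus = np.where(plus > hi, plus - two_pi, plus)
        plus = np.where(plus < lo, plus + two_pi, plus)
        minus = np.where(minus > hi, minus - two_pi, minus)
        minus = np.where(minus < lo, minus + two_pi, minus)
        out[t] = np.where(np.abs(plus - prev) <= np.abs(minus - prev),
                          plus, minus)
    return out


def height_movie_from_irm(intensity_movie: np.ndarray, cal: Calibration,
                          pixel_size_nm: float, frame_interval_s: float,
                          branch_continuation: bool = False,
                          clamp_tolerance: float = 0.01) -> HeightMovie:
    """Convert an IRM intensity movie (frames, rows, cols) to heights.

    With ``branch_continuation`` the folded interference phase is continued
    in time per pixel (see :func:`_unfold_phase`), recovering excursions that
    transiently leave the first branch; otherwise out-of-branch intensities
    fold back onto it (plain arccos inversion).
    """
    arg = (cal.intensity_offset - np.asarray(intensity_movie, dtype=float)) \
        / cal.intensity_amplitude
    arg = np.clip(arg, -1.0, 1.0)
    theta = np.arccos(arg)
    if branch_continuation:
        theta = _unfold_phase(theta)
    h = cal.wavelength / (4.0 * np.pi * cal.refractive_index) * theta
    if clamp_tolerance is not None:
        over = np.abs((cal.intensity_offset - intensity_movie)
                      / cal.intensity_amplitude) > 1.0 + clamp_tolerance
        if np.any(over):
            h = np.where(over, np.nan, h)
    return HeightMovie(h=h, pixel_size_nm=pixel_size_nm,
                       frame_interval_s=frame_interval_s)


def select_fbrs(intensity_movie: np.ndarray, cal: Calibration,
                side_pixels: int = 12, pixel_size_nm: float = 72.2,
                mean_band: float = 0.9, clamp_tolerance: float = 0.01,
                edge_value: float = 0.98, edge_fraction: float = 0.05,
                ) -> list[FBR]:
    """Tile the field with non-overlapping square windows that qualify as
    first-branch regions.

    A window qualifies when every member pixel (i) has a temporal-mean
    normalized intensity (I - offset)/amplitude within ``+-mean_band``,
    (ii) never leaves [-1, 1] beyond the clamp tolerance, and (iii) spends
    less than ``edge_fraction`` of its frames with |normalized intensity| >
    ``edge_value``.  The last criterion catches membranes that repeatedly
    touch a branch extremum — folded excursions beyond the branch look like
    in-range intensities pinned near +-1, so dwelling there marks the
    conversion as unreliable.  Deterministic for fixed inputs; an empty
    list simply means no window qualified.
    """
    if side_pixels < 2:
        raise ValueError("side_pixels must be >= 2")
    mov = np.asarray(intensity_movie, dtype=float)
    norm = (mov - cal.intensity_offset) / cal.intensity_amplitude
    mean_ok = np.abs(norm.mean(axis=0)) <= mean_band
    never_out = (np.abs(norm) <= 1.0 + clamp_tolerance).all(axis=0)
    edge_ok = (np.abs(norm) > edge_value).mean(axis=0) < edge_fraction
    pix_ok = mean_ok & never_out & edge_ok
    ny, nx = pix_ok.shape
    out = []
    for r0 in range(0, ny - side_pixels + 1, side_pixels):
        for c0 in range(0, nx - side_pixels + 1, side_pixels):
            if pix_ok[r0:r0 + side_pixels, c0:c0 + side_pixels].all():
                out.append(FBR(origin=(r0, c0), side_pixels=side_pixels,
                               pixel_size_nm=pixel_size_nm))
    return out
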