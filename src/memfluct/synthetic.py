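"""Synthetic data generators with recorded ground truth.

Every input the analysis pipeline consumes can be produced here: membrane
height movies drawn from the Helfrich-type mode model, interferometric (IRM)
renderings of those heights, optical-trap bead traces, two-channel puncta
images, cortical line scans, spread-area decay curves, and a two-temperature
bead fixture with a closed-form entropy production rate.

The membrane simulator inverts the power-spectral-density model that the
fitting stage assumes: each spatial Fourier mode q of the height field is an
independent Ornstein-Uhlenbeck process with relaxation rate

    omega_q = (kappa q^3 + sigma q + gamma/q) / (4 eta_eff)

and stationary variance

    <|h_q|^2> = A k_B T / (L^2 (kappa q^4 + sigma q^2 + gamma)),

so the single-pixel temporal PSD converges (in the mode-count limit) to the
continuum integral the fitter uses.  Modes are integrated with the exact OU
update (exponential decay plus exact-variance noise increment), so the
stationary statistics are correct at any frame interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import K_B, DEFAULT_TEMPERATURE, NM, kappa_default

__all__ = [
    "MembraneSimParams",
    "OpticsConfig",
    "GroundTruth",
    "HeightMovie",
    "TrapTrace",
    "simulate_membrane_patch",
    "mode_grid",
    "stationary_pixel_variance",
    "render_irm_movie",
    "simulate_trap_trace",
    "render_puncta_pair",
    "render_linescan",
    "simulate_area_decay",
    "simulate_two_temperature_beads",
    "two_bead_entropy_rate",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MembraneSimParams:
    """Parameters of the membrane-patch fluctuation simulation.

    Units: ``domain_side`` in um, ``kappa`` in J, ``sigma_true`` in N/m,
    ``gamma_true`` in N/m^3, ``eta_eff`` in Pa.s, ``mean_height`` in nm.
    ``active_A`` is the dimensionless active-temperature multiplier (1 =
    purely thermal).  The pixel grid equals the mode grid: the patch is
    sampled on ``n_modes_per_axis`` x ``n_modes_per_axis`` pixels.
    """

    domain_side: float = 6.9312          # um; 96 px of 72.2 nm
    n_modes_per_axis: int = 96
    kappa: float | None = None           # J; None -> 15 k_B T
    sigma_true: float = 5e-7             # N/m
    gamma_true: float = 2e6              # N/m^3
    eta_eff: float = 0.1                 # Pa s
    active_A: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    mean_height: float = 51.0            # nm
    frame_rate: float = 20.0             # Hz
    n_frames: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa is None:
            self.kappa = kappa_default(self.temperature)
        if self.kappa <= 0 or self.eta_eff <= 0:
            raise ValueError("kappa and eta_eff must be positive")
        if self.frame_rate <= 0 or self.n_frames <= 0:
            raise ValueError("frame_rate and n_frames must be positive")
        if self.sigma_true < 0 or self.gamma_true < 0 or self.active_A < 0:
            raise ValueError("sigma_true, gamma_true, active_A must be >= 0")
        if self.n_modes_per_axis < 2:
            raise ValueError("need at least 2 modes per axis")

    @property
    def pixel_size_nm(self) -> float:
        return self.domain_side * 1e3 / self.n_modes_per_axis


@dataclass
class OpticsConfig:
    """IRM imaging model: interference wavelength/medium and camera scaling."""

    wavelength: float = 546.0            # nm
    refractive_index: float = 1.335      # aqueous medium
    pixel_size: float = 72.2             # nm
    camera_noise_sd: float = 2.0         # additive Gaussian, intensity units
    intensity_offset: float = 1000.0
    intensity_amplitude: float = 400.0

    def __post_init__(self) -> None:
        if min(self.wavelength, self.refractive_index, self.pixel_size,
               self.intensity_amplitude) <= 0:
            raise ValueError(
                "wavelength, refractive_index, pixel_size and "
                "intensity_amplitude must be positive")

    @property
    def branch_height_span(self) -> float:
        """Height span of the first interference branch, lambda/(4n) in nm."""
        return self.wavelength / (4.0 * self.refractive_index)


@dataclass
class GroundTruth:
    """True values of whatever a generator simulated, keyed by artifact id."""

    artifact: str
    values: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"artifact": self.artifact, "values": self.values},
                      fh, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(artifact=d["artifact"], values=d["values"])


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


@dataclass
class HeightMovie:
    """Relative membrane height movie.

    ``h`` has shape (n_frames, n_rows, n_cols), in nm; invalid pixels are
    NaN (e.g. intensities that left the first interference branch).
    """

    h: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.h.shape[0]


@dataclass
class TrapTrace:
    """Bead displacement from the trap centre, metres per sample."""

    x: np.ndarray
    sample_rate: float = 200.0
    temperature: float = DEFAULT_TEMPERATURE


# ---------------------------------------------------------------------------
# membrane patch
# ---------------------------------------------------------------------------

def mode_grid(params: MembraneSimParams):
    """Wavevector magnitudes (1/m) on the simulation's FFT mode grid.

    Returns ``q`` with shape (N, N); the zero mode is set to inf so that
    1/E(q) vanishes there (it carries the mean height, not a fluctuation).
    """
    N = params.n_modes_per_axis
    L = params.domain_side * 1e-6
    k = np.fft.fftfreq(N, d=1.0 / N)  # integer mode numbers
    m, n = np.meshgrid(k, k, indexing="ij")
    q = 2.0 * np.pi * np.hypot(m, n) / L
    q[0, 0] = np.inf
    return q


def _mode_variance(params: MembraneSimParams, q: np.ndarray) -> np.ndarray:
    """Stationary variance <|h_q|^2> (m^2) per mode."""
    L = params.domain_side * 1e-6
    E = params.kappa * q ** 4 + params.sigma_true * q ** 2 + params.gamma_true
    with np.errstate(divide="ignore"):
        v = params.active_A * K_B * params.temperature / (L ** 2 * E)
    v[~np.isfinite(q)] = 0.0
    return v


def stationary_pixel_variance(params: MembraneSimParams) -> float:
    """Closed-form single-pixel height variance (nm^2): the sum of
    A k_B T / (L^2 (kappa q^4 + sigma q^2 + gamma)) over the simulated modes."""
    q = mode_grid(params)
    return float(_mode_variance(params, q).sum()) / NM ** 2


def _conj_index(a: np.ndarray) -> np.ndarray:
    """Reindex an FFT-grid array from q to -q (mod grid)."""
    return np.roll(a[::-1, ::-1], 1, axis=(0, 1))


def simulate_membrane_patch(params: MembraneSimParams,
                            store_window: tuple[int, int, int] | None = None
                            ) -> HeightMovie:
    """Simulate a fluctuating membrane patch; returns heights in nm.

    Each mode is evolved with the exact OU update.  The Hermitian field is
    assembled from two real OU arrays (alpha, beta) per grid point via

        h_q = ((alpha_q + alpha_{-q}) + i (beta_q - beta_{-q})) / sqrt(2),

    which yields <|h_q|^2> equal to the target mode variance, E[h_q^2] = 0,
    and exact conjugate symmetry, so the pixel variance equals the plain sum
    of mode variances at every pixel.

    ``store_window`` = (row0, col0, side) keeps only that pixel window of
    each frame (the dynamics still involve the full mode field); use it to
    analyse a small patch of a large simulated domain without holding the
    whole movie in memory.
    """
    if params.n_frames < 256:
        raise ValueError("n_frames must be >= 256 for spectral analysis")
    N = params.n_modes_per_axis
    q = mode_grid(params)
    v = _mode_variance(params, q)          # target <|h_q|^2>, m^2
    var_ou = v / 2.0                        # per real OU component

    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (params.kappa * q ** 3 + params.sigma_true * q
                 + params.gamma_true / q) / (4.0 * params.eta_eff)
    omega[~np.isfinite(q)] = 0.0

    dt = 1.0 / params.frame_rate
    decay = np.exp(-omega * dt)
    innov_sd = np.sqrt(np.maximum(var_ou * (1.0 - decay ** 2), 0.0))
    stat_sd = np.sqrt(var_ou)

    rng = np.random.default_rng(params.seed)
    alpha = rng.standard_normal((N, N)) * stat_sd
    beta = rng.standard_normal((N, N)) * stat_sd

    mean_m = params.mean_height * NM
    if store_window is None:
        r0, c0, side = 0, 0, N
    else:
        r0, c0, side = store_window
        if r0 < 0 or c0 < 0 or r0 + side > N or c0 + side > N:
            raise ValueError("store_window outside the simulated domain")
    frames = np.empty((params.n_frames, side, side), dtype=np.float64)
    for t in range(params.n_frames):
        if t > 0:
            alpha = alpha * decay + rng.standard_normal((N, N)) * innov_sd
            beta = beta * decay + rng.standard_normal((N, N)) * innov_sd
        H = ((alpha + _conj_index(alpha))
             + 1j * (beta - _conj_index(beta))) / np.sqrt(2.0)
        # h(r) = sum_q h_q exp(iq.r) = N^2 * ifft2(H); the zero mode carries
        # the (constant) mean height.
        H[0, 0] = mean_m
        frames[t] = (N ** 2) * np.fft.ifft2(H).real[r0:r0 + side,
                                                    c0:c0 + side]

    frames /= NM  # m -> nm
    return HeightMovie(h=frames, pixel_size_nm=params.pixel_size_nm,
                       frame_interval_s=dt)


# ---------------------------------------------------------------------------
# IRM rendering
# ---------------------------------------------------------------------------

def irm_intensity(h_nm: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Noiseless interference intensity for heights in nm:
    I(h) = offset - amplitude * cos(4 pi n h / lambda).

    Minimal at h = 0 (membrane touching the coverslip: darkest) and periodic
    in h with period lambda/(2n)."""
    phase = 4.0 * np.pi * optics.refractive_index * np.asarray(h_nm) \
        / optics.wavelength
    return optics.intensity_offset - optics.intensity_amplitude * np.cos(phase)


def render_irm_movie(movie: HeightMovie, optics: OpticsConfig,
                     seed: int | None = None) -> np.ndarray:
    """Render a height movie (nm) to an IRM intensity movie, with additive
    Gaussian camera noise of SD ``optics.camera_noise_sd``."""
    intensity = irm_intensity(movie.h, optics)
    if optics.camera_noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, optics.camera_noise_sd, size=intensity.shape)
    return intensity


def render_bead_image(optics: OpticsConfig, bead_radius_um: float = 30.0,
                      image_px: int = 257, seed: int | None = None
                      ) -> np.ndarray:
    """IRM image of a spherical calibration bead resting on the coverslip.

    Height profile h(r) = R - sqrt(R^2 - r^2) around the contact point;
    pixels beyond the bead radius are left at the large-height mean level.
    """
    R = bead_radius_um * 1e3  # nm
    c = (image_px - 1) / 2.0
    yy, xx = np.mgrid[0:image_px, 0:image_px]
    r = np.hypot(yy - c, xx - c) * optics.pixel_size
    h = np.where(r < R, R - np.sqrt(np.maximum(R ** 2 - r ** 2, 0.0)), np.nan)
    img = irm_intensity(np.nan_to_num(h), optics)
    img[np.isnan(h)] = optics.intensity_offset
    if optics.camera_noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, optics.camera_noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# optical trap
# ---------------------------------------------------------------------------

def simulate_trap_trace(k_true: float, temperature: float = DEFAULT_TEMPERATURE,
                        n_samples: int = 200_000, seed: int = 0,
                        sample_rate: float = 200.0,
                        drag: float = 1e-7,
                        plateau_force_pN: float | None = None,
                        plateau_window_s: tuple[float, float] | None = None,
                        ) -> TrapTrace:
    """Trapped-bead displacement trace (m) as an OU process.

    Stationary variance is k_B T / k_true (equipartition).  ``drag`` (kg/s)
    sets the relaxation time gamma/k.  If ``plateau_force_pN`` is given, a
    constant force is applied during ``plateau_window_s`` (defaults to the
    second half of the trace), shifting the mean by F/k as during a parked
    tether pull.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    rng = np.random.default_rng(seed)
    var = K_B * temperature / k_true
    dt = 1.0 / sample_rate
    omega = k_true / drag
    decay = np.exp(-omega * dt)
    innov = np.sqrt(var * (1.0 - decay ** 2))
    x = np.empty(n_samples)
    x[0] = rng.standard_normal() * np.sqrt(var)
    noise = rng.standard_normal(n_samples - 1) * innov
    for i in range(1, n_samples):
        x[i] = x[i - 1] * decay + noise[i - 1]
    if plateau_force_pN is not None:
        shift = plateau_force_pN * 1e-12 / k_true
        t = np.arange(n_samples) * dt
        if plateau_window_s is None:
            plateau_window_s = (t[-1] / 2.0, t[-1])
        sel = (t >= plateau_window_s[0]) & (t <= plateau_window_s[1])
        x[sel] += shift
    return TrapTrace(x=x, sample_rate=sample_rate, temperature=temperature)


# ---------------------------------------------------------------------------
# fluorescence fixtures
# ---------------------------------------------------------------------------

def render_puncta_pair(objects_a, objects_b, image_shape=(100, 100),
                       pixel_size_um: float = 0.1, noise_sd: float = 0.0,
                       amplitude: float = 100.0, seed: int = 0):
    """Two-channel puncta image with exact painted-area ground truth.

    ``objects_a``/``objects_b`` are lists of dicts with keys ``center``
    (row, col), ``radius`` (px, a disc) or ``half_side`` (px, a square).
    Overlapping objects within one channel merge in the ground-truth area
    accounting (the union mask is what counts).

    Returns (image_a, image_b, GroundTruth) where the ground truth records
    per-channel union pixel areas and the exact overlap pixel area.
    """
    rng = np.random.default_rng(seed)

    def paint(objs):
        mask = np.zeros(image_shape, dtype=bool)
        yy, xx = np.mgrid[0:image_shape[0], 0:image_shape[1]]
        for o in objs:
            r0, c0 = o["center"]
            if "radius" in o:
                m = (yy - r0) ** 2 + (xx - c0) ** 2 <= o["radius"] ** 2
            else:
                hs = o["half_side"]
                m = (np.abs(yy - r0) <= hs) & (np.abs(xx - c0) <= hs)
            if not m.any() or (yy[m].min() < 0):
                raise ValueError("object outside image bounds")
            mask |= m
        return mask

    mask_a, mask_b = paint(objects_a), paint(objects_b)
    img_a = amplitude * mask_a.astype(float)
    img_b = amplitude * mask_b.astype(float)
    if noise_sd > 0:
        img_a = img_a + rng.normal(0, noise_sd, image_shape)
        img_b = img_b + rng.normal(0, noise_sd, image_shape)
    npx = image_shape[0] * image_shape[1]
    gt = GroundTruth(artifact="puncta_pair", values={
        "area_px_a": int(mask_a.sum()),
        "area_px_b": int(mask_b.sum()),
        "overlap_px": int((mask_a & mask_b).sum()),
        "area_fraction_a": mask_a.sum() / npx,
        "area_fraction_b": mask_b.sum() / npx,
        "n_objects_a": len(objects_a),
        "n_objects_b": len(objects_b),
        "pixel_size_um": pixel_size_um,
    })
    return img_a, img_b, gt


# ---------------------------------------------------------------------------
# line scans
# ---------------------------------------------------------------------------

def render_linescan(peaks, baseline: float = 10.0, noise_sd: float = 0.0,
                    length_um: float = 4.0, pixel_size_nm: float = 45.0,
                    seed: int = 0,
                    count_thresholds: tuple[float, float] = (6.0, 5.0)):
    """Cortical line-scan intensity profile built from Gaussian peaks.

    ``peaks`` is a list of (position_um, height, width_um).  The ground truth
    records how many peaks meet the stated (prominence, width-in-samples)
    thresholds, judged on the analytic profile: for well-separated Gaussian
    peaks the prominence equals the peak height and the full width at half
    prominence is 2*sqrt(2 ln 2)*width/pixel samples.
    """
    n = int(round(length_um * 1e3 / pixel_size_nm)) + 1
    pos = np.arange(n) * pixel_size_nm * 1e-3  # um
    y = np.full(n, float(baseline))
    qualifying = 0
    for (p, h, w) in peaks:
        if not 0.0 <= p <= length_um:
            raise ValueError("peak position outside the scan")
        y += h * np.exp(-0.5 * ((pos - p) / w) ** 2)
        fwhm_samples = 2.3548 * w * 1e3 / pixel_size_nm
        if h >= count_thresholds[0] and fwhm_samples >= count_thresholds[1]:
            qualifying += 1
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sd, n)
    gt = GroundTruth(artifact="linescan", values={
        "n_qualifying_peaks": qualifying,
        "n_peaks_total": len(peaks),
        "baseline": baseline,
        "length_um": length_um,
    })
    return pos, y, gt


# ---------------------------------------------------------------------------
# spread-area decay
# ---------------------------------------------------------------------------

def simulate_area_decay(A0: float = 1500.0, pre_plateau_min: float = 5.0,
                        tau_min: float = 10.0, final_fraction: float = 0.3,
                        dt_min: float = 0.5, total_min: float = 60.0,
                        noise_sd: float = 0.0, seed: int = 0):
    """Spread-area time course of a de-adhering cell (um^2 vs min).

    Constant at ``A0`` during the pre-treatment plateau, then exponential
    decay with time constant ``tau_min``, clipped at
    ``final_fraction * A0``.  Returns (t_min, area, GroundTruth); the ground
    truth records the treatment time, the analytic time of the 67% crossing
    and the time the plateau is reached.
    """
    if not 0.0 < final_fraction < 1.0:
        raise ValueError("final_fraction must be in (0, 1)")
    if tau_min <= 0:
        raise ValueError("tau_min must be positive")
    t = np.arange(0.0, total_min + 1e-9, dt_min)
    area = np.where(t < pre_plateau_min, A0,
                    A0 * np.exp(-(t - pre_plateau_min) / tau_min))
    area = np.maximum(area, final_fraction * A0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        area = area + rng.normal(0, noise_sd, area.shape)
    t67 = pre_plateau_min + tau_min * np.log(1.0 / 0.67)
    t_plateau = pre_plateau_min + tau_min * np.log(1.0 / final_fraction)
    gt = GroundTruth(artifact="area_decay", values={
        "A0": A0, "treatment_time_min": pre_plateau_min,
        "tau_min": tau_min, "final_fraction": final_fraction,
        "t67_min": t67, "t_plateau_min": t_plateau,
    })
    return t, area, gt


# ---------------------------------------------------------------------------
# two-temperature bead fixture (entropy production oracle)
# ---------------------------------------------------------------------------

def two_bead_entropy_rate(k: float, kc: float, drag: float,
                          T1: float, T2: float) -> float:
    """Stationary entropy production rate (k_B/s) of two linearly coupled
    overdamped beads held at temperatures T1 and T2.

    Computed from the stationary covariance C solving the Lyapunov equation
    A C + C A^T + 2D = 0 as EPR = tr(D^{-1} Lam C Lam^T) with
    Lam = A + D C^{-1} (the irreversible phase-space velocity)."""
    from scipy.linalg import solve_lyapunov
    A = -np.array([[k + kc, -kc], [-kc, k + kc]]) / drag
    D = np.diag([K_B * T1, K_B * T2]) / drag
    C = solve_lyapunov(A, -2.0 * D)
    Lam = A + D @ np.linalg.inv(C)
    return float(np.trace(np.linalg.inv(D) @ Lam @ C @ Lam.T))


def simulate_two_temperature_beads(k: float = 1.0, kc: float = 1.0,
                                   drag: float = 1.0,
                                   T1: float = 1.0 / K_B, T2: float = 4.0 / K_B,
                                   dt: float = 0.05, n: int = 50_000,
                                   seed: int = 0):
    """Trajectory of two coupled overdamped beads at unequal temperatures.

    Integrated with the exact Gaussian update of the linear SDE (matrix
    exponential decay + exact covariance increment), so the stationary law
    is exact at any dt.  Default temperatures are in "k_B = 1" natural units
    (T = 1/K_B makes k_B*T = 1 J).

    Returns (x, analytic_rate) where x has shape (n, 2) and analytic_rate is
    the closed-form stationary entropy production rate in k_B/s.
    """
    if T1 <= 0 or T2 <= 0:
        raise ValueError("temperatures must be positive")
    from scipy.linalg import expm, solve_lyapunov, cholesky
    A = -np.array([[k + kc, -kc], [-kc, k + kc]]) / drag
    D = np.diag([K_B * T1, K_B * T2]) / drag
    C = solve_lyapunov(A, -2.0 * D)            # stationary covariance
    M = expm(A * dt)
    # covariance of the increment: C - M C M^T (stationary-start identity)
    Q = C - M @ C @ M.T
    Q = (Q + Q.T) / 2.0
    Lq = cholesky(Q, lower=True)
    Lc = cholesky(C, lower=True)
    rng = np.random.default_rng(seed)
    x = np.empty((n, 2))
    x[0] = Lc @ rng.standard_normal(2)
    z = rng.standard_normal((n - 1, 2))
    for i in range(1, n):
        x[i] = M @ x[i - 1] + Lq @ z[i - 1]
    rate = two_bead_entropy_rate(k, kc, drag, T1, T2)
    return x, rate
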