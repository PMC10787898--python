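"""Temporal power spectral densities of membrane height fluctuations and the
Helfrich-type model fit that extracts fluctuation-tension.

The fitted model is the single-point temporal PSD of an overdamped membrane
whose modes relax at omega_q = (kappa q^3 + sigma q + gamma/q)/(4 eta_eff):

    PSD(f) = (2s) * (4 eta_eff A k_B T / pi)
             * Int_{q_min}^{q_max} dq /
               [ (4 eta_eff (2 pi f))^2 + (kappa q^3 + sigma q + gamma/q)^2 ]

where s = 1 for the one-sided density (the default here, matching the
estimators in :func:`compute_psd`, which satisfy Parseval on the one-sided
grid) and s = 1/2 for the two-sided form.  Bending rigidity kappa is fixed
at 15 k_B T; the active temperature A, effective cytoplasmic viscosity
eta_eff, tension sigma and confinement gamma are the fitting parameters.

Integration bounds default to the geometric mode cutoffs of the analysed
window: q_min = pi/L (L the window side) and q_max = pi/pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares

from .constants import K_B, DEFAULT_TEMPERATURE, NM, kappa_default

__all__ = ["PSDCurve", "FitConfig", "MechanicalFit", "compute_psd",
           "average_psd", "model_psd", "fit_psd", "map_mechanics"]


@dataclass
class PSDCurve:
    """One-sided PSD estimate: frequency (Hz) vs power (nm^2/Hz)."""

    frequency: np.ndarray
    power: np.ndarray
    provenance: str = "pixel"      # "pixel" | "fbr-average"
    estimator: str = "fft"         # "fft" | "covariance"

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequency.ndim != 1 or self.frequency.shape != self.power.shape:
            raise ValueError("frequency and power must be matching 1-d arrays")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class FitConfig:
    """Configuration of the PSD model fit.

    ``q_min``/``q_max`` in 1/m; ``f_band`` in Hz (None -> 0.1 Hz to
    0.8*Nyquist, excluding the lowest 3 frequency bins against drift).
    Bounds are (low, high) tuples on the natural scale; the multi-start grid
    places ``n_starts_per_param`` log-spaced initial guesses per parameter.
    """

    q_min: float = np.pi / 866.4e-9        # 12 px x 72.2 nm window
    q_max: float = np.pi / 72.2e-9
    f_band: tuple[float, float] | None = None
    drop_lowest_bins: int = 3
    kappa_fixed: float | None = None       # J; None -> 15 k_B T
    temperature: float = DEFAULT_TEMPERATURE
    bounds_A: tuple[float, float] = (0.05, 200.0)
    bounds_eta: tuple[float, float] = (1e-3, 30.0)       # Pa s
    bounds_sigma: tuple[float, float] = (1e-9, 1e-3)     # N/m
    bounds_gamma: tuple[float, float] = (1.0, 1e10)      # N/m^3
    fit_eta: bool = False                  # see note below
    eta_fixed: float = 0.1                 # Pa s, used when fit_eta=False
    sampling_kernel: bool = True           # fit the sampled-process spectrum
    sample_rate: float | None = None       # Hz; None -> 2 * max(frequency)
    discrete_modes: bool = False           # sum the known finite mode grid
                                           # (synthetic domains) instead of
                                           # the continuum integral
    fold_model: bool = False               # model the interference-folded
                                           # observation (heights wrapped
                                           # onto the first branch)
    fold_mean_nm: float = 51.0             # mean height entering the fold
    branch_span_nm: float = 546.0 / (4.0 * 1.335)
    camera_noise_norm_sd: float = 0.0      # camera noise / amplitude, for
                                           # the folded-observation model
    n_record: int = 2048                   # frames per record (Bartlett
                                           # taper of the expectation)
    n_starts_per_param: int = 3
    quad_rtol: float = 1e-6
    subtract_noise_floor: bool = False
    fit_floor: bool = False                # add a free constant floor to the
                                           # model (camera noise, residual
                                           # broadband distortion)
    bounds_floor: tuple[float, float] = (1e-8, 1e2)      # nm^2/Hz
    weights: str = "evar"                  # "evar" | "counts" | "uniform"
                                           # residual weighting on log10(power)
    evar_fallback: str = "median"          # small-bin relative-sd fallback:
                                           # "median" of other bins | "chi2"
    bin_log_bias: bool = False             # digamma correction of binned
                                           # log-power
    sigma_profile: bool = False            # report the profile-posterior
                                           # mean of ln(sigma) instead of
                                           # the ridge's global minimum;
                                           # only meaningful when the data
                                           # exclude sigma ~ 0 decisively,
                                           # otherwise the log-flat prior
                                           # over the flat ridge dominates
    sigma_profile_points: int = 61
    log_bins: int = 40                     # log-spaced bins over fit band;
                                           # 0 fits the raw grid

    def __post_init__(self) -> None:
        if self.kappa_fixed is None:
            self.kappa_fixed = kappa_default(self.temperature)
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")


@dataclass
class MechanicalFit:
    """Fitted membrane-mechanical parameters for one pixel or FBR."""

    A: float
    eta_eff: float
    sigma: float
    gamma: float
    kappa: float
    r_squared: float
    converged: bool = True
    noise_floor: float = 0.0
    location: tuple | None = None

    @property
    def sigma_pN_per_um(self) -> float:
        return self.sigma / 1e-6


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def compute_psd(series: np.ndarray, frame_rate: float,
                estimator: str = "fft", nperseg: int | None = None
                ) -> PSDCurve:
    """One-sided PSD (nm^2/Hz) of a height time series (nm).

    The mean is removed first.  ``estimator="fft"`` is the raw periodogram
    (exactly Parseval: sum(power)*df = variance); ``estimator="covariance"``
    is a Blackman-Tukey estimate (Bartlett-windowed autocovariance transform,
    maximum lag N/4) evaluated on the same frequency grid.  ``nperseg``
    switches the fft estimator to a mean of non-overlapping segment
    periodograms (shorter grid, chi^2 dof proportional to the segment
    count), which the model-fitting pipeline uses to tame scatter.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 256:
        raise ValueError("need a 1-d series of at least 256 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    n = x.size
    x = x - x.mean()
    dt = 1.0 / frame_rate

    if estimator == "fft" and nperseg is not None and nperseg < n:
        nseg = n // nperseg
        segs = x[:nseg * nperseg].reshape(nseg, nperseg)
        segs = segs - segs.mean(axis=1, keepdims=True)
        freqs = np.fft.rfftfreq(nperseg, d=dt)
        X = np.fft.rfft(segs, axis=1)
        power = (np.abs(X) ** 2).mean(axis=0) * dt / nperseg
        power[1:] *= 2.0
        if nperseg % 2 == 0:
            power[-1] /= 2.0
        return PSDCurve(frequency=freqs[1:], power=power[1:], estimator="fft")

    freqs = np.fft.rfftfreq(n, d=dt)

    if estimator == "fft":
        X = np.fft.rfft(x)
        power = (np.abs(X) ** 2) * dt / n
        power[1:] *= 2.0                       # one-sided fold
        if n % 2 == 0:
            power[-1] /= 2.0                   # Nyquist bin is unpaired
    elif estimator == "covariance":
        max_lag = n // 4
        acf = np.correlate(x, x, mode="full")[n - 1:n + max_lag] / n
        lags = np.arange(max_lag + 1)
        w = 1.0 - lags / (max_lag + 1)         # Bartlett window
        c = acf * w
        # S(f) = 2*dt*(c0 + 2*sum_k c_k cos(2 pi f k dt)), one-sided
        power = 2.0 * dt * (c[0] + 2.0 * (
            c[1:, None] * np.cos(2.0 * np.pi * freqs[None, :]
                                 * lags[1:, None] * dt)).sum(axis=0))
        power = np.maximum(power, 0.0)
        # normalise so the one-sided Parseval identity holds exactly on the
        # discrete grid (the half-grid cosine sums leave a ~1% deficit)
        df = freqs[1] - freqs[0]
        total = power[1:].sum() * df
        if total > 0:
            power = power * (np.var(x) / total)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return PSDCurve(frequency=freqs[1:], power=power[1:], estimator=estimator)


def average_psd(curves: list[PSDCurve]) -> PSDCurve:
    """Pointwise arithmetic mean of PSDs on an identical frequency grid
    (the per-FBR spectrum is the mean over its member pixels)."""
    if not curves:
        raise ValueError("no curves to average")
    f0 = curves[0].frequency
    for c in curves[1:]:
        if c.frequency.shape != f0.shape or not np.allclose(c.frequency, f0):
            raise ValueError("curves must share one frequency grid")
    power = np.mean([c.power for c in curves], axis=0)
    return PSDCurve(frequency=f0.copy(), power=power,
                    provenance="fbr-average", estimator=curves[0].estimator)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

_LEGGAUSS_CACHE: dict = {}


def _leggauss(n: int):
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = leggauss(n)
    return _LEGGAUSS_CACHE[n]


def _model_integral(f: np.ndarray, A: float, eta_eff: float, sigma: float,
                    gamma: float, kappa: float, q_min: float, q_max: float,
                    n_nodes: int) -> np.ndarray:
    """Gauss-Legendre evaluation of the mode integral in u = ln q."""
    u_nodes, u_weights = _leggauss(n_nodes)
    lo, hi = np.log(q_min), np.log(q_max)
    u = 0.5 * (hi - lo) * u_nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * u_weights
    q = np.exp(u)
    bracket = kappa * q ** 3 + sigma * q + gamma / q
    f = np.atleast_1d(np.asarray(f, dtype=float))
    drive = (4.0 * eta_eff * 2.0 * np.pi * f[:, None]) ** 2
    integrand = q[None, :] / (drive + bracket[None, :] ** 2)  # q: du = dq/q
    return integrand @ w


def _sampled_model(f: np.ndarray, A: float, eta_eff: float, sigma: float,
                   gamma: float, kappa: float, q_min: float, q_max: float,
                   temperature: float, fs: float, n_nodes: int) -> np.ndarray:
    """Expectation one-sided PSD (nm^2/Hz per unit A) of the height field
    sampled at ``fs``: continuum of modes, each contributing its exact
    discrete-time OU (AR(1)) spectrum instead of a continuous Lorentzian.

    S_q(f) = 2 dt V_q (1 - a^2) / (1 + a^2 - 2 a cos(2 pi f dt)),
    a = exp(-omega_q dt); radial mode density q dq / (2 pi).
    """
    u_nodes, u_weights = _leggauss(n_nodes)
    lo, hi = np.log(q_min), np.log(q_max)
    u = 0.5 * (hi - lo) * u_nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * u_weights
    q = np.exp(u)
    E = kappa * q ** 4 + sigma * q ** 2 + gamma
    V = K_B * temperature / E                       # per unit A, times L^-2
    omega = (kappa * q ** 3 + sigma * q + gamma / q) / (4.0 * eta_eff)
    dt = 1.0 / fs
    a = np.exp(-omega * dt)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    cosf = np.cos(2.0 * np.pi * f[:, None] * dt)
    kern = 2.0 * dt * (V * (1.0 - a ** 2))[None, :] / (
        1.0 + (a ** 2)[None, :] - 2.0 * a[None, :] * cosf)
    integrand = kern * (q ** 2 / (2.0 * np.pi))[None, :]  # q du = dq; q/(2pi)
    return (integrand @ w) / NM ** 2


def _discrete_mode_bins(q_min: float, q_max: float):
    """Histogram of |q| over the square mode grid with spacing q_min
    (fundamental 2 pi / L) extending to the Nyquist mode q_max = pi/pixel.

    Returns (q_values, counts); zero mode excluded.  Binning identical-|q|
    modes keeps the discrete-sum kernel cheap inside the optimiser.
    """
    dq = q_min
    M = int(round(q_max / (dq / 2.0) / 2.0))  # q_max = pi N / L = (N/2) dq
    k = np.arange(-M, M + 1)
    mm, nn = np.meshgrid(k, k, indexing="ij")
    q = dq * np.hypot(mm, nn).ravel()
    q = q[q > 0]
    edges = np.logspace(np.log10(q.min() * 0.999), np.log10(q.max() * 1.001),
                        800)
    counts, _ = np.histogram(q, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    sel = counts > 0
    # use the mean |q| within each occupied bin for accuracy at low q
    sums, _ = np.histogram(q, bins=edges, weights=q)
    qv = sums[sel] / counts[sel]
    return qv, counts[sel].astype(float), centers  # centers unused


_MODE_BIN_CACHE: dict = {}


def _sampled_model_discrete(f: np.ndarray, A: float, eta_eff: float,
                            sigma: float, gamma: float, kappa: float,
                            q_min: float, q_max: float, temperature: float,
                            fs: float) -> np.ndarray:
    """Discrete-grid analogue of :func:`_sampled_model`: the AR(1) kernel
    summed over the finite Fourier-mode grid of a simulated periodic domain
    of side L = 2 pi / q_min (per unit A), in nm^2/Hz."""
    key = (round(q_min, 3), round(q_max, 3))
    if key not in _MODE_BIN_CACHE:
        _MODE_BIN_CACHE[key] = _discrete_mode_bins(q_min, q_max)
    qv, counts, _ = _MODE_BIN_CACHE[key]
    L = 2.0 * np.pi / q_min
    E = kappa * qv ** 4 + sigma * qv ** 2 + gamma
    V = K_B * temperature / (L ** 2 * E)
    omega = (kappa * qv ** 3 + sigma * qv + gamma / qv) / (4.0 * eta_eff)
    dt = 1.0 / fs
    a = np.exp(-omega * dt)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    cosf = np.cos(2.0 * np.pi * f[:, None] * dt)
    kern = 2.0 * dt * (V * (1.0 - a ** 2))[None, :] / (
        1.0 + (a ** 2)[None, :] - 2.0 * a[None, :] * cosf)
    return (kern * counts[None, :]).sum(axis=1) / NM ** 2


_HERMEGAUSS_CACHE: dict = {}


def _hermegauss_cached(n: int):
    if n not in _HERMEGAUSS_CACHE:
        from numpy.polynomial.hermite_e import hermegauss
        _HERMEGAUSS_CACHE[n] = hermegauss(n)
    return _HERMEGAUSS_CACHE[n]


def _hermite_fold_coeffs(mean: float, sd: float, span: float,
                         noise_sd_u: float = 0.0,
                         n_terms: int = 60, n_quad: int = 160,
                         n_noise_quad: int = 32):
    """Hermite coefficients of the interference fold map applied to a
    Gaussian height N(mean, sd^2), optionally with camera noise.

    The fold maps a height h onto the first branch: g(h) = span *
    arccos(cos(pi h / span)) / pi (even, period 2*span).  With camera noise
    the observation is G(h, eps) = span * arccos(clip(cos(pi h/span) +
    eps)) / pi, eps ~ N(0, noise_sd_u^2) white in time and independent of
    h.  Because eps is white, the lagged autocovariance of G involves only
    the noise-averaged map gbar(h) = E_eps[G]: ACF(tau > 0) =
    sum_m>=1 c_m^2 rho(tau)^m with c_m the Hermite coefficients of gbar
    (Mehler's expansion), while the equal-time variance additionally
    carries the white term E[Var_eps(G | h)].

    Returns (c, white_var): coefficients (c[0] is the mean) and the white
    variance (0 when noise_sd_u = 0).
    """
    z, w = _hermegauss_cached(n_quad)
    w = w / np.sqrt(2.0 * np.pi)
    x = mean + sd * z
    u = np.cos(np.pi * x / span)
    if noise_sd_u > 0:
        ze, we = _hermegauss_cached(n_noise_quad)
        we = we / np.sqrt(2.0 * np.pi)
        uu = np.clip(u[:, None] + noise_sd_u * ze[None, :], -1.0, 1.0)
        G = span * np.arccos(uu) / np.pi
        g = G @ we                            # gbar(h)
        white_var = float(np.sum(w * ((G ** 2) @ we - g ** 2)))
    else:
        g = span * np.arccos(u) / np.pi
        white_var = 0.0
    # probabilists' Hermite polynomials He_m by recurrence:
    # He_{m+1} = z He_m - m He_{m-1}
    c = np.empty(n_terms + 1)
    c[0] = np.sum(w * g)
    He_prev, He = np.ones_like(z), z.copy()
    fact = 1.0
    for m in range(1, n_terms + 1):
        fact *= m
        c[m] = np.sum(w * g * He) / np.sqrt(fact)
        He_prev, He = He, z * He - m * He_prev
    return c, white_var


def _folded_model_psd(f: np.ndarray, A: float, eta_eff: float, sigma: float,
                      gamma: float, kappa: float, q_min: float, q_max: float,
                      temperature: float, fs: float, mean_nm: float,
                      span_nm: float, n_record: int,
                      noise_sd_u: float = 0.0,
                      max_lag: int = 256) -> np.ndarray:
    """Expectation one-sided PSD (nm^2/Hz) of the interference-FOLDED height
    observation: Gaussian mode field wrapped onto the first branch.

    Route: discrete-mode sampled autocovariance of the true field ->
    Mehler/Hermite transform to the folded process -> Bartlett-tapered
    cosine transform (matching the raw-periodogram expectation).
    """
    key = (round(q_min, 3), round(q_max, 3))
    if key not in _MODE_BIN_CACHE:
        _MODE_BIN_CACHE[key] = _discrete_mode_bins(q_min, q_max)
    qv, counts, _ = _MODE_BIN_CACHE[key]
    L = 2.0 * np.pi / q_min
    E = kappa * qv ** 4 + sigma * qv ** 2 + gamma
    V = A * K_B * temperature / (L ** 2 * E) / NM ** 2       # nm^2
    omega = (kappa * qv ** 3 + sigma * qv + gamma / qv) / (4.0 * eta_eff)
    dt = 1.0 / fs
    k = np.arange(max_lag + 1)
    # sampled ACF of the true field (exact for OU modes)
    r = (V * counts) @ np.exp(-np.outer(omega, k * dt))      # nm^2
    var = r[0]
    sd = np.sqrt(var)
    rho = np.clip(r / var, -1.0, 1.0)
    c, white_var = _hermite_fold_coeffs(mean_nm, sd, span_nm, noise_sd_u)
    c2 = c[1:] ** 2                                           # m = 1..M
    m = np.arange(1, c2.size + 1)
    rg = (rho[None, :] ** m[:, None] * c2[:, None]).sum(axis=0)
    taper = 1.0 - k / float(n_record)
    taper = np.maximum(taper, 0.0)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    cosmat = np.cos(2.0 * np.pi * f[:, None] * (k[None, 1:] * dt))
    S = 2.0 * dt * (rg[0] * taper[0]
                    + 2.0 * (cosmat @ (rg[1:] * taper[1:])))
    # camera noise: white in time, so it adds a flat one-sided density
    S = S + 2.0 * dt * white_var
    return np.maximum(S, 1e-300)


def model_psd(f, A: float, eta_eff: float, sigma: float, gamma: float,
              kappa: float | None = None,
              q_min: float = np.pi / 866.4e-9,
              q_max: float = np.pi / 72.2e-9,
              temperature: float = DEFAULT_TEMPERATURE,
              rtol: float = 1e-6, two_sided: bool = False):
    """Model temporal PSD (nm^2/Hz) at frequencies ``f`` (Hz).

    Evaluates the mode integral by adaptive Gauss-Legendre quadrature in
    u = ln q, doubling the node count until successive evaluations agree to
    ``rtol`` (relative).  Strictly decreasing in f and strictly increasing
    in A; A = 0 gives identically zero.
    """
    if min(A, eta_eff, sigma, gamma) < 0:
        raise ValueError("parameters must be non-negative")
    if not 0 < q_min < q_max:
        raise ValueError("need 0 < q_min < q_max")
    if kappa is None:
        kappa = kappa_default(temperature)
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    scalar = np.isscalar(f) or (hasattr(f, "ndim") and f.ndim == 0)

    prefactor = 4.0 * eta_eff * A * K_B * temperature / np.pi
    if not two_sided:
        prefactor *= 2.0  # one-sided density integrates to the variance
    if A == 0.0:
        out = np.zeros_like(f_arr)
        return float(out[0]) if scalar else out

    n = 64
    prev = _model_integral(f_arr, A, eta_eff, sigma, gamma, kappa,
                           q_min, q_max, n)
    while True:
        n *= 2
        cur = _model_integral(f_arr, A, eta_eff, sigma, gamma, kappa,
                              q_min, q_max, n)
        err = np.max(np.abs(cur - prev) / np.maximum(np.abs(cur), 1e-300))
        if err < rtol:
            break
        if n >= 8192:
            raise RuntimeError(
                f"quadrature did not converge to rtol={rtol} "
                f"(A={A}, eta={eta_eff}, sigma={sigma}, gamma={gamma})")
        prev = cur
    out = prefactor * cur / NM ** 2  # m^2/Hz -> nm^2/Hz
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_band_mask(curve: PSDCurve, config: FitConfig) -> np.ndarray:
    f = curve.frequency
    if config.f_band is not None:
        lo, hi = config.f_band
    else:
        lo, hi = 0.1, 0.8 * f[-1]
    mask = (f >= lo) & (f <= hi) & (curve.power > 0)
    mask[:config.drop_lowest_bins] = False
    return mask


def estimate_noise_floor(curve: PSDCurve) -> float:
    """Constant noise floor estimated as the median power over the top
    half-decade of frequencies (where the membrane spectrum has decayed)."""
    f = curve.frequency
    sel = f >= f[-1] / np.sqrt(10.0)
    return float(np.median(curve.power[sel]))


def fit_psd(curve: PSDCurve, config: FitConfig | None = None) -> MechanicalFit:
    """Fit the membrane model to a PSD curve.

    Least squares on log10(power) vs log10(f) over the fit band, with the
    free parameters searched in log space from a fixed multi-start grid
    (``n_starts_per_param`` per axis, log spaced within bounds); the lowest
    final cost wins, ties broken by the smaller fitted sigma.  R^2 is
    computed on log10(power).  Non-convergence of every start returns a
    flagged fit with ``r_squared = nan``.

    By default the effective cytoplasmic viscosity is held at
    ``config.eta_fixed`` and only (A, sigma, gamma) are fit.  With kappa
    fixed, a joint rescaling of (A, eta_eff, sigma, gamma) changes the
    model curve over an experimentally accessible band by less than typical
    periodogram scatter, so the absolute scale of a free 4-parameter fit is
    not identifiable; pinning the viscosity anchors that scaling.  Set
    ``config.fit_eta = True`` for the unconstrained 4-parameter fit.
    """
    config = config or FitConfig()
    fs = config.sample_rate or 2.0 * float(curve.frequency[-1])
    mask = _fit_band_mask(curve, config)
    if mask.sum() < 20:
        raise ValueError("need at least 20 PSD points inside the fit band")
    f = curve.frequency[mask]
    p_obs = curve.power[mask]
    floor = estimate_noise_floor(curve) if config.subtract_noise_floor else 0.0
    p_obs = p_obs - floor
    good = p_obs > 0
    f, p_obs = f[good], p_obs[good]
    if f.size < 20:
        raise ValueError("fit band collapsed after noise-floor subtraction")
    w_res = np.ones_like(f)
    sd_log_cal = None
    y_corr = 0.0
    if config.log_bins and f.size > config.log_bins:
        # geometric-mean binning equalises the leverage of each decade and
        # tames periodogram scatter before the nonlinear fit
        edges = np.logspace(np.log10(f[0]), np.log10(f[-1]),
                            config.log_bins + 1)
        idx = np.clip(np.searchsorted(edges, f, side="right") - 1,
                      0, config.log_bins - 1)
        fb, pb, nb, sb = [], [], [], []
        for b in range(config.log_bins):
            sel = idx == b
            if sel.any():
                fb.append(np.exp(np.mean(np.log(f[sel]))))
                pb.append(np.mean(p_obs[sel]))
                nb.append(sel.sum())
                sb.append(np.std(p_obs[sel]) if sel.sum() >= 4 else np.nan)
        f, p_obs = np.array(fb), np.array(pb)
        nb = np.array(nb, dtype=float)
        if config.weights == "counts":
            # the variance of a binned log-periodogram scales as 1/n_bin
            w_res = np.sqrt(nb)
        elif config.weights == "evar":
            # GLS-style: sd of each binned mean estimated from the within-bin
            # scatter of the (pixel-averaged) periodogram; this credits the
            # large effective dof that pixel averaging buys at mid and high
            # frequencies, where many spatial modes contribute
            sb = np.array(sb)
            rel = sb / p_obs                       # relative sd of raw points
            if config.evar_fallback == "chi2":
                # lowest-frequency bins: raw periodogram ~ chi^2_2
                rel = np.where(np.isfinite(rel), rel, 1.0)
            else:
                med_rel = np.nanmedian(rel)
                rel = np.where(np.isfinite(rel), rel,
                               med_rel if np.isfinite(med_rel) else 1.0)
            sd_log = np.maximum(rel / np.sqrt(nb) / np.log(10.0), 1e-3)
            sd_log_cal = sd_log                    # kept for chi^2 use
            w_res = 1.0 / sd_log
            w_res = w_res / w_res.max() * np.sqrt(nb.max())  # scale-stable
            if config.bin_log_bias:
                # log of a noisy chi^2-like mean is biased low by
                # psi(k/2) - ln(k/2) nats (k = effective dof of the mean)
                from scipy.special import digamma
                rel_mean = np.clip(rel / np.sqrt(nb), 1e-6, 1.2)
                k_eff = 2.0 / rel_mean ** 2
                y_corr = -(digamma(k_eff / 2.0) - np.log(k_eff / 2.0)) \
                    / np.log(10.0)                 # positive shift
    y_obs = np.log10(p_obs) + y_corr

    kappa = config.kappa_fixed
    # fixed nodes during optimisation (validated against the adaptive path)
    n_nodes = 128
    pref0 = 8.0 * K_B * config.temperature / np.pi / NM ** 2

    def unpack(theta):
        th = 10.0 ** np.asarray(theta)
        floor_fit = th[-1] if config.fit_floor else 0.0
        if config.fit_eta:
            A, eta, sigma, gamma = th[0], th[1], th[2], th[3]
        else:
            A, sigma, gamma = th[0], th[1], th[2]
            eta = config.eta_fixed
        return A, eta, sigma, gamma, floor_fit

    def eval_model(A, eta, sigma, gamma):
        if config.fold_model:
            return _folded_model_psd(
                f, A, eta, sigma, gamma, kappa, config.q_min, config.q_max,
                config.temperature, fs, config.fold_mean_nm,
                config.branch_span_nm, config.n_record,
                config.camera_noise_norm_sd)
        if config.sampling_kernel:
            # expectation spectrum of the process sampled at fs: each mode's
            # continuous Lorentzian is replaced by its exact AR(1) spectrum,
            # which accounts for all Nyquist folding of fast modes
            if config.discrete_modes:
                return A * _sampled_model_discrete(
                    f, A, eta, sigma, gamma, kappa, config.q_min,
                    config.q_max, config.temperature, fs)
            return A * _sampled_model(f, A, eta, sigma, gamma, kappa,
                                      config.q_min, config.q_max,
                                      config.temperature, fs, n_nodes)
        return pref0 * eta * A * _model_integral(
            f, A, eta, sigma, gamma, kappa, config.q_min, config.q_max,
            n_nodes)

    def residuals(theta):
        A, eta, sigma, gamma, floor_fit = unpack(theta)
        val = eval_model(A, eta, sigma, gamma)
        return (np.log10(np.maximum(val + floor_fit, 1e-300)) - y_obs) * w_res

    bounds_nat = [config.bounds_A, config.bounds_eta,
                  config.bounds_sigma, config.bounds_gamma]
    if not config.fit_eta:
        del bounds_nat[1]
    if config.fit_floor:
        bounds_nat.append(config.bounds_floor)
    lo = np.log10([b[0] for b in bounds_nat])
    hi = np.log10([b[1] for b in bounds_nat])
    k = config.n_starts_per_param
    axes = [np.linspace(l + 0.15 * (h - l), h - 0.15 * (h - l), k)
            for l, h in zip(lo, hi)]

    sigma_axis = 3 if config.fit_eta else 1
    best = None
    for start in product(*axes):
        try:
            res = least_squares(residuals, np.array(start),
                                bounds=(lo, hi), method="trf",
                                xtol=1e-9, ftol=1e-9, max_nfev=200)
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        key = (res.cost, 10.0 ** res.x[sigma_axis])  # cost, then smaller sigma
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return MechanicalFit(A=np.nan, eta_eff=np.nan, sigma=np.nan,
                             gamma=np.nan, kappa=kappa, r_squared=np.nan,
                             converged=False, noise_floor=floor)
    res = best[1]
    A, eta, sigma, gamma, floor_fit = unpack(res.x)
    if config.fit_floor:
        floor = floor_fit

    if config.sigma_profile and sd_log_cal is not None and not config.fit_eta:
        # The (sigma, gamma) trade-off is a nearly flat likelihood ridge:
        # the global minimum slides along it with realisation noise.  A
        # stabler point estimate marginalises over the ridge: profile the
        # calibrated chi^2 over a log grid of sigma (re-optimising the
        # other parameters, warm-started), scale by the reduced chi^2
        # against overdispersion, and take the posterior mean of ln sigma
        # under a log-flat prior.
        w_cal = 1.0 / sd_log_cal

        def chi2_at(log10_sigma, start):
            def res_fix(theta2):
                th = np.concatenate(([theta2[0]], [log10_sigma], theta2[1:]))
                A2, eta2, s2, g2, fl2 = unpack(th)
                return residuals_full(A2, eta2, s2, g2, fl2) * w_cal
            lo2 = np.delete(lo, 1)
            hi2 = np.delete(hi, 1)
            r = least_squares(res_fix, start, bounds=(lo2, hi2),
                              method="trf", xtol=1e-8, ftol=1e-8,
                              max_nfev=100)
            return 2.0 * r.cost, r.x

        def residuals_full(A2, eta2, s2, g2, fl2):
            val = eval_model(A2, eta2, s2, g2)
            return np.log10(np.maximum(val + fl2, 1e-300)) - y_obs

        grid = np.linspace(np.log10(config.bounds_sigma[0]),
                           np.log10(config.bounds_sigma[1]),
                           config.sigma_profile_points)
        start = np.delete(res.x, 1)
        # sweep outward from the MLE's nearest grid point for warm starts
        i0 = int(np.argmin(np.abs(grid - np.log10(max(sigma, 1e-300)))))
        chi2 = np.empty(grid.size)
        xs = [None] * grid.size
        chi2[i0], xs[i0] = chi2_at(grid[i0], start)
        for i in range(i0 + 1, grid.size):
            chi2[i], xs[i] = chi2_at(grid[i], xs[i - 1])
        for i in range(i0 - 1, -1, -1):
            chi2[i], xs[i] = chi2_at(grid[i], xs[i + 1])
        dof = max(y_obs.size - 3, 1)
        scale = max(chi2.min() / dof, 1.0)
        logL = -(chi2 - chi2.min()) / (2.0 * scale)
        w = np.exp(logL - logL.max())
        sigma = float(10.0 ** (np.sum(w * grid) / np.sum(w)))
    # weighted R^2: binned log-periodogram points have variance ~ 1/n_bin,
    # so goodness of fit uses the same weights as the estimator
    w2 = w_res ** 2
    ybar = float(np.sum(w2 * y_obs) / np.sum(w2))
    ss_res = float(np.sum(res.fun ** 2))
    ss_tot = float(np.sum(w2 * (y_obs - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return MechanicalFit(A=A, eta_eff=eta, sigma=sigma, gamma=gamma,
                         kappa=kappa, r_squared=r2, converged=True,
                         noise_floor=floor)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def map_mechanics(movie, fbrs, config: FitConfig | None = None,
                  mode: str = "fbr", estimator: str = "fft"):
    """Fit the PSD model across a height movie and map parameters back onto
    the image geometry.

    ``movie`` is a :class:`~memfluct.synthetic.HeightMovie`; ``fbrs`` a list
    of FBR windows (see :mod:`memfluct.irm`).  ``mode="fbr"`` fits the
    pixel-averaged PSD of each window; ``mode="pixel"`` fits every member
    pixel individually.  Returns ``(fits, maps)`` where ``maps`` is a dict
    of float images (sigma, A, eta_eff, gamma, r_squared) aligned to the
    movie with NaN where nothing was fit.
    """
    config = config or FitConfig()
    frame_rate = 1.0 / movie.frame_interval_s
    ny, nx = movie.h.shape[1:]
    maps = {k: np.full((ny, nx), np.nan)
            for k in ("sigma", "A", "eta_eff", "gamma", "r_squared")}
    fits = []
    for fbr in fbrs:
        r0, c0, side = fbr.origin[0], fbr.origin[1], fbr.side_pixels
        block = movie.h[:, r0:r0 + side, c0:c0 + side]
        L = side * movie.pixel_size_nm * NM
        cfg = dataclasses_replace(config, q_min=np.pi / L,
                                  q_max=np.pi / (movie.pixel_size_nm * NM))
        if mode == "fbr":
            curves = [compute_psd(block[:, i, j], frame_rate, estimator)
                      for i in range(side) for j in range(side)
                      if np.all(np.isfinite(block[:, i, j]))]
            if not curves:
                continue
            fit = fit_psd(average_psd(curves), cfg)
            fit.location = (r0, c0, side)
            fits.append(fit)
            sl = (slice(r0, r0 + side), slice(c0, c0 + side))
            for key, val in (("sigma", fit.sigma), ("A", fit.A),
                             ("eta_eff", fit.eta_eff), ("gamma", fit.gamma),
                             ("r_squared", fit.r_squared)):
                maps[key][sl] = val
        elif mode == "pixel":
            for i in range(side):
                for j in range(side):
                    series = block[:, i, j]
                    if not np.all(np.isfinite(series)):
                        continue
                    fit = fit_psd(compute_psd(series, frame_rate, estimator),
                                  cfg)
                    fit.location = (r0 + i, c0 + j)
                    fits.append(fit)
                    for key, val in (("sigma", fit.sigma), ("A", fit.A),
                                     ("eta_eff", fit.eta_eff),
                                     ("gamma", fit.gamma),
                                     ("r_squared", fit.r_squared)):
                        maps[key][r0 + i, c0 + j] = val
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return fits, maps


def dataclasses_replace(config, **kw):
    import dataclasses
    return dataclasses.replace(config, **kw)
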