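"""Flicker-noise spectroscopy of giant unilamellar vesicles.

Thermally driven shape fluctuations of a quasi-spherical vesicle encode the
membrane bending rigidity κ.  In the Helfrich (Milner–Safran) description
the spherical-harmonic mode amplitudes obey equipartition,

    ⟨|u_lm|²⟩ = k_B T / [ κ (l−1)(l+2) (l(l+1) + σ̄) ],

with σ̄ a dimensionless reduced tension.  The pipeline here mirrors the
experimental workflow: the equatorial rim contour r(φ, t) is extracted from
grayscale image stacks (bright-rim detection along radial rays with
subpixel refinement), the angular autocorrelation ξ(γ) of r − R is built,
and the spectrum is obtained either by Legendre decomposition of ξ (the
average-based approach; the addition theorem maps the equatorial
correlation to Σ_l (2l+1)/(4π) ⟨|u_l|²⟩ P_l(cos γ)) or by per-frame Fourier
decomposition with an exponential-law fit to each mode's amplitude
histogram (the statistical approach).  A least-squares fit of the model
over a mode window (default l = 3–20) yields κ with σ̄ as a nuisance
parameter.

Because an equatorial Fourier mode m collects every spherical-harmonic
degree l ≥ m through |Y_lm(π/2)|², the statistical-approach model is the
summed spectrum; the average-based path resolves l directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .units import thermal_energy


@dataclass
class ContourSeries:
    """Radial vesicle contour r(φ_i, t_j) on a uniform angle grid (µm)."""

    r: np.ndarray  # (n_frames, n_phi), µm; NaN marks a missing ray
    pixel_size: float  # µm
    frame_interval: float  # s
    temperature: float = 295.15  # K
    dropped_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[1] < 64:
            raise ValueError("contours need at least 64 angular samples per frame")
        if np.any(self.r[np.isfinite(self.r)] <= 0):
            raise ValueError("radial positions must be positive")

    @property
    def n_frames(self) -> int:
        return self.r.shape[0]

    @property
    def n_phi(self) -> int:
        return self.r.shape[1]

    @property
    def phi(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_phi) / self.n_phi

    @property
    def mean_radius(self) -> float:
        """Grand mean radius R (µm)."""
        return float(np.nanmean(self.r))


@dataclass
class FluctuationSpectrum:
    """Mean-square fluctuation amplitudes per mode."""

    modes: np.ndarray  # integer l (average) or equatorial m (statistical)
    amplitude_mean: np.ndarray  # dimensionless mean-square amplitudes
    approach: str  # 'average' | 'statistical'
    mean_radius: float  # µm
    temperature: float  # K
    legendre_coefficients: np.ndarray | None = None  # B_l of ξ/R²
    amplitude_histograms: dict[int, tuple[np.ndarray, np.ndarray]] | None = None


@dataclass
class RigidityFit:
    """Bending rigidity fit with reduced tension as nuisance."""

    kappa: float  # J
    kappa_err: float  # J
    sigma_bar: float
    mode_range: tuple[int, int]
    approach: str
    units: str = "J"


# --------------------------------------------------------------------------
# contour I/O


def write_contours_csv(contours: ContourSeries, path) -> None:
    """CSV contour matrix: one row per frame, one column per φ sample (µm),
    with a header comment carrying calibration."""
    header = (
        f"pixel_size_um={contours.pixel_size!r} "
        f"frame_interval_s={contours.frame_interval!r} "
        f"temperature_K={contours.temperature!r}"
    )
    np.savetxt(path, contours.r, delimiter=",", header=header)


def read_contours_csv(
    path, pixel_size=None, frame_interval=None, temperature=None
) -> ContourSeries:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                key, val = token.split("=")
                meta[key] = float(val)
    r = np.loadtxt(path, delimiter=",")
    return ContourSeries(
        np.atleast_2d(r),
        pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0),
        frame_interval if frame_interval is not None else meta.get("frame_interval_s", 1.0),
        temperature if temperature is not None else meta.get("temperature_K", 295.15),
    )


# --------------------------------------------------------------------------
# contour extraction


def _detect_rim(image, center, n_phi, min_peak_fraction):
    """Radial rim positions (px) along n_phi rays from a fixed center."""
    h, w = image.shape
    cx, cy = center
    r_max = int(min(cx, cy, w - 1 - cx, h - 1 - cy)) - 1
    if r_max < 4:
        return np.full(n_phi, np.nan), np.zeros(n_phi)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    radii = np.arange(1, r_max + 1, dtype=float)
    xs = cx + radii[None, :] * np.cos(phi)[:, None]
    ys = cy + radii[None, :] * np.sin(phi)[:, None]
    profiles = map_coordinates(image.astype(float), [ys, xs], order=1, mode="nearest")
    peak_idx = np.argmax(profiles, axis=1)
    peak_val = profiles[np.arange(n_phi), peak_idx]
    threshold = min_peak_fraction * float(image.max())
    r_rim = np.full(n_phi, np.nan)
    weights = np.zeros(n_phi)
    for i in range(n_phi):
        k = peak_idx[i]
        if peak_val[i] < threshold or k == 0 or k == len(radii) - 1:
            continue
        y0, y1, y2 = profiles[i, k - 1 : k + 2]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        r_rim[i] = radii[k] + np.clip(shift, -0.5, 0.5)
        weights[i] = peak_val[i]
    return r_rim, weights


def extract_contour(
    image_stack: np.ndarray,
    pixel_size: float,
    frame_interval: float = 0.16,
    center_guess=None,
    n_phi: int = 180,
    temperature: float = 295.15,
    min_peak_fraction: float = 0.3,
    max_missing_fraction: float = 0.1,
    max_iter: int = 25,
    tol_px: float = 0.01,
) -> ContourSeries:
    """Extract the vesicle rim contour from a grayscale image stack.

    Per frame, the center is refined iteratively as the intensity-weighted
    centroid of the detected rim; along each of ``n_phi`` rays the rim is
    the radial intensity maximum with 3-point parabolic subpixel
    refinement.  Rays without a detectable rim are marked missing; frames
    with more than ``max_missing_fraction`` missing rays are dropped and
    logged in ``dropped_frames``.
    """
    stack = np.asarray(image_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    rows: list[np.ndarray] = []
    dropped: list[int] = []
    for t in range(stack.shape[0]):
        img = stack[t]
        if center_guess is None:
            total = img.sum()
            yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
            center = (float((img * xx).sum() / total), float((img * yy).sum() / total))
        else:
            center = (float(center_guess[0]), float(center_guess[1]))
        r_rim = np.full(n_phi, np.nan)
        for _ in range(max_iter):
            r_rim, wts = _detect_rim(img, center, n_phi, min_peak_fraction)
            good = np.isfinite(r_rim)
            if good.sum() < max(8, n_phi // 4):
                break
            phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
            xs = center[0] + r_rim[good] * np.cos(phi[good])
            ys = center[1] + r_rim[good] * np.sin(phi[good])
            w = wts[good]
            # intensity-weighted least-squares circle through the rim points
            # (robust to partial arcs when the current center is far off)
            design = np.column_stack([2 * xs, 2 * ys, np.ones_like(xs)])
            target = xs**2 + ys**2
            sw = np.sqrt(w)
            sol, *_ = np.linalg.lstsq(design * sw[:, None], target * sw, rcond=None)
            new_center = (float(sol[0]), float(sol[1]))
            shift = np.hypot(new_center[0] - center[0], new_center[1] - center[1])
            center = new_center
            if shift < tol_px:
                break
        missing = np.count_nonzero(~np.isfinite(r_rim)) / n_phi
        if missing > max_missing_fraction:
            dropped.append(t)
            continue
        rows.append(r_rim * pixel_size)
    if not rows:
        raise ValueError("no frame yielded a usable contour")
    return ContourSeries(
        np.array(rows), pixel_size, frame_interval, temperature, dropped
    )


# --------------------------------------------------------------------------
# autocorrelation and spectra


@dataclass
class AngularAutocorrelation:
    """ξ(γ) = ⟨(r(φ+γ) − R)(r(φ) − R)⟩ over φ and t."""

    gamma: np.ndarray  # rad, uniform grid over [0, 2π)
    xi: np.ndarray  # µm²
    mean_radius: float  # µm
    temperature: float

    @property
    def xi_rel(self) -> np.ndarray:
        """Dimensionless autocorrelation of u = (r − R)/R."""
        return self.xi / self.mean_radius**2


def angular_autocorrelation(contours: ContourSeries) -> AngularAutocorrelation:
    """Time- and angle-averaged angular autocorrelation of the contour.

    Uses circular FFT correlation when all rays are present and a
    pairwise-complete masked average otherwise.
    """
    R = contours.mean_radius
    u = contours.r - R
    n = contours.n_phi
    if np.nanstd(contours.r) == 0:
        warnings.warn("degenerate (constant) contours; ξ ≡ 0")
        return AngularAutocorrelation(
            contours.phi, np.zeros(n), R, contours.temperature
        )
    if np.all(np.isfinite(u)):
        spec = np.fft.rfft(u, axis=1)
        xi = np.fft.irfft(spec * np.conj(spec), n=n, axis=1).mean(axis=0) / n
    else:
        xi = np.empty(n)
        for k in range(n):
            prod = u * np.roll(u, -k, axis=1)
            xi[k] = np.nanmean(prod)
    return AngularAutocorrelation(contours.phi, xi, R, contours.temperature)


def legendre_equatorial_matrix(n_modes: int) -> np.ndarray:
    """Fourier-cosine coefficients of P_l on the equator.

    By the addition theorem applied to two equatorial points,
    P_l(cos γ) = 4π/(2l+1) Σ_m |Y_lm(π/2)|² e^{imγ}, so
    P_l(cos γ) = Σ_m T[m, l] cos(mγ) with
    T[m, l] = 4π/(2l+1) |Y_lm(π/2)|² (doubled for m ≥ 1).  The matrix is
    upper triangular in l ≥ m with the parity structure of Y_lm(π/2).
    """
    w = _equatorial_weights(n_modes)
    modes = np.arange(n_modes + 1)
    t = 4.0 * np.pi / (2.0 * modes[None, :] + 1.0) * w.T
    t[1:, :] *= 2.0
    return t


def spectrum_average(
    xi: AngularAutocorrelation, n_modes: int = 25
) -> FluctuationSpectrum:
    """Legendre decomposition of the angular autocorrelation.

    The autocorrelation on the uniform angle grid is an exact cosine
    series, and each Legendre polynomial has an exact equatorial cosine
    expansion (see :func:`legendre_equatorial_matrix`); projecting ξ̃ on
    the P_l therefore reduces to a back-substitution of the triangular
    system relating the two bases — equivalent to the orthogonality
    integral B_l = (2l+1)/2 ∫ ξ̃ P_l d(cos γ) but exact for band-limited
    data.  Mean-square amplitudes follow from the addition theorem,
    ⟨|u_l|²⟩ = 4π B_l / (2l+1).
    """
    n = xi.gamma.size
    if n_modes > n // 2:
        raise ValueError("n_modes may not exceed half the angular sampling")
    spec = np.fft.rfft(xi.xi_rel)
    a = np.empty(n_modes + 1)
    a[0] = spec[0].real / n
    a[1:] = 2.0 * spec[1 : n_modes + 1].real / n
    t = legendre_equatorial_matrix(n_modes)
    b = np.zeros(n_modes + 1)
    for l in range(n_modes, -1, -1):
        b[l] = (a[l] - t[l, l + 1 :] @ b[l + 1 :]) / t[l, l]
    modes = np.arange(n_modes + 1)
    amp = 4.0 * np.pi * b / (2 * modes + 1)
    return FluctuationSpectrum(
        modes, amp, "average", xi.mean_radius, xi.temperature, legendre_coefficients=b
    )


def _exponential_histogram_mean(power: np.ndarray, n_bins: int) -> tuple[float, tuple]:
    """Mean of an exponential law fitted to the amplitude histogram.

    The equilibrium distribution of a mode's squared amplitude is
    exponential; a Poisson-weighted straight-line fit to the log-counts
    gives the decay constant.  Returns (mean, (edges, counts)); raises on a
    degenerate histogram.
    """
    # bin up to the 98th percentile: sparse tail bins carry asymmetric
    # log-count noise that biases the slope
    hi = np.quantile(power, 0.98)
    if hi <= 0:
        raise ValueError("degenerate amplitude histogram")
    counts, edges = np.histogram(power, bins=n_bins, range=(0.0, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("degenerate amplitude histogram")
    slope, _ = np.polyfit(
        centers[keep], np.log(counts[keep]), 1, w=np.sqrt(counts[keep])
    )
    if slope >= 0:
        raise ValueError("non-decaying amplitude histogram")
    return -1.0 / slope, (edges, counts)


def spectrum_statistical(
    contours: ContourSeries,
    n_modes: int = 25,
    min_frames_for_fit: int = 50,
    n_bins: int | None = None,
) -> FluctuationSpectrum:
    """Per-frame Fourier decomposition with histogram-based amplitudes.

    Each frame's relative contour u(φ) = (r − R)/R is Fourier decomposed;
    for each equatorial mode m the per-frame squared amplitudes |c_m|² are
    histogrammed and the mode's mean-square amplitude estimated from the
    histogram's exponential-law fit (falling back to the raw mean, with a
    warning, when frames are too few or the histogram degenerate).
    """
    if n_modes > contours.n_phi // 2:
        raise ValueError("n_modes may not exceed half the angular sampling")
    R = contours.mean_radius
    u = (contours.r - R) / R
    complete = np.all(np.isfinite(u), axis=1)
    u = u[complete]
    if u.shape[0] == 0:
        raise ValueError("no complete frames for Fourier decomposition")
    coeff = np.fft.rfft(u, axis=1) / contours.n_phi
    power = np.abs(coeff[:, : n_modes + 1]) ** 2
    n_frames = u.shape[0]
    if n_bins is None:
        n_bins = max(8, n_frames // 40)
    amp = np.empty(n_modes + 1)
    hists: dict[int, tuple] = {}
    for m in range(n_modes + 1):
        raw_mean = float(np.mean(power[:, m]))
        if n_frames < min_frames_for_fit:
            warnings.warn("too few frames for histogram fit; using raw mean")
            amp[m] = raw_mean
            continue
        try:
            amp[m], hists[m] = _exponential_histogram_mean(power[:, m], n_bins)
        except ValueError:
            warnings.warn(f"mode {m}: degenerate histogram; using raw mean")
            amp[m] = raw_mean
    return FluctuationSpectrum(
        np.arange(n_modes + 1), amp, "statistical", R, contours.temperature,
        amplitude_histograms=hists,
    )


# --------------------------------------------------------------------------
# rigidity fit


@lru_cache(maxsize=8)
def _equatorial_weights(l_max: int) -> np.ndarray:
    """|Y_lm(π/2, 0)|² table, shape (l_max+1, l_max+1); zero for m > l."""
    from scipy.special import sph_harm_y

    w = np.zeros((l_max + 1, l_max + 1))
    for l in range(l_max + 1):
        for m in range(l + 1):
            w[l, m] = np.abs(sph_harm_y(l, m, np.pi / 2.0, 0.0)) ** 2
    return w


def helfrich_mode_variance(l, kappa: float, sigma_bar: float, temperature: float):
    """Milner–Safran equipartition variance of spherical-harmonic mode l."""
    l = np.asarray(l, dtype=float)
    return thermal_energy(temperature) / (
        kappa * (l - 1.0) * (l + 2.0) * (l * (l + 1.0) + sigma_bar)
    )


def equatorial_fourier_power(
    m, kappa: float, sigma_bar: float, temperature: float, l_max: int = 30
):
    """Model power of equatorial Fourier mode m: Σ_{l≥max(m,2)} |Y_lm(π/2)|²⟨|u_l|²⟩."""
    weights = _equatorial_weights(l_max)
    m_arr = np.atleast_1d(np.asarray(m, dtype=int))
    out = np.empty(m_arr.size)
    ls = np.arange(2, l_max + 1)
    hv = helfrich_mode_variance(ls, kappa, sigma_bar, temperature)
    for i, mm in enumerate(m_arr):
        sel = ls >= max(mm, 2)
        out[i] = np.sum(weights[ls[sel], mm] * hv[sel])
    return out if np.ndim(m) else float(out[0])


def fit_bending_rigidity(
    spectrum: FluctuationSpectrum,
    mode_range: tuple[int, int] = (3, 20),
    temperature: float | None = None,
    l_max_model: int = 30,
) -> RigidityFit:
    """Least-squares fit of the Helfrich spectrum for κ and reduced tension.

    The average-based spectrum is fitted with the per-degree model
    ⟨|u_l|²⟩ = k_B T/[κ(l−1)(l+2)(l(l+1)+σ̄)]; the statistical (Fourier)
    spectrum with the degree-summed equatorial model.  The fit is performed
    on log amplitudes with κ parametrized as exp(ln κ) so it stays
    positive; a failure to converge raises with residual diagnostics.
    """
    if temperature is None:
        temperature = spectrum.temperature
    lo, hi = mode_range
    mask = (spectrum.modes >= lo) & (spectrum.modes <= hi)
    modes = spectrum.modes[mask]
    data = spectrum.amplitude_mean[mask]
    if modes.size < 4:
        raise ValueError("rigidity fit needs at least 4 modes in range")
    if np.any(data <= 0):
        raise ValueError("non-positive spectrum amplitudes in the fit range")
    kbt = thermal_energy(temperature)
    l0 = float(modes[0])
    kappa0 = kbt / (data[0] * (l0 - 1) * (l0 + 2) * l0 * (l0 + 1))
    sigma_floor = -(lo * (lo + 1.0)) + 1e-3

    if spectrum.approach == "statistical":
        def model(kappa, sigma_bar):
            return equatorial_fourier_power(
                modes, kappa, sigma_bar, temperature, l_max_model
            )
    else:
        def model(kappa, sigma_bar):
            return helfrich_mode_variance(modes, kappa, sigma_bar, temperature)

    def residuals(params):
        kappa = np.exp(params[0])
        sigma_bar = params[1]
        return np.log(model(kappa, sigma_bar)) - np.log(data)

    res = least_squares(
        residuals,
        x0=[np.log(kappa0), 0.0],
        bounds=([np.log(kappa0) - 10.0, sigma_floor], [np.log(kappa0) + 10.0, 1e5]),
    )
    if not res.success:
        raise ValueError(
            f"rigidity fit did not converge; residuals {res.fun}"
        )
    kappa = float(np.exp(res.x[0]))
    # covariance of (ln κ, σ̄) from the Gauss-Newton approximation
    dof = max(1, modes.size - 2)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * 2.0 * res.cost / dof
        kappa_err = kappa * float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        kappa_err = float("nan")
    return RigidityFit(
        kappa, kappa_err, float(res.x[1]), (int(lo), int(hi)), spectrum.approach
    )
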