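"""Ground-truth generators for every analysis stage.

Each generator draws from the same statistical model its analysis
counterpart assumes, with all physical targets given in the units the
analyses report, so parameter recovery can be tested end to end without MD
trajectories or microscopy data: jittered-lattice membranes with prescribed
area per lipid, thickness and diffusion; Boltzmann tilt/splay samples at
prescribed moduli; Gaussian thickness fluctuations at prescribed K_A;
parametric isotherms with closed-form mixing behavior; and
Helfrich-spectrum quasi-spherical vesicle contours, optionally rendered as
bright-rim image stacks.  Every generator is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flicker import ContourSeries, _equatorial_weights, helfrich_mode_variance
from .isotherms import Isotherm
from .mechanics import ThicknessFluctuationSeries, TiltSplaySamples
from .membrane_model import (
    FrameSeries,
    LipidTopology,
    minimal_lipid_topology,
    wrap_coordinates,
)
from .units import A2_PER_NS_PER_UM2_PER_S, MNM_PER_J_PER_A2, thermal_energy


@dataclass
class SyntheticMembrane:
    """A generated lattice membrane plus its ground truth."""

    frames: FrameSeries
    topologies: dict[str, LipidTopology]
    leaflet_truth: dict[int, str]
    true_apl: float  # Å²
    true_thickness: float  # Å (P-plane to P-plane)
    true_diffusion: float  # µm²/s
    unwrapped_heads: np.ndarray  # (n_frames, n_lipids, 2), Å, noise-free COM frame


def _lattice_dimensions(n: int) -> tuple[int, int]:
    """Divisor pair (nx, ny) of n making the hexagonal box closest to square."""
    best = (n, 1)
    best_cost = np.inf
    for nx in range(1, n + 1):
        if n % nx:
            continue
        ny = n // nx
        lx, ly = nx, ny * np.sqrt(3.0) / 2.0
        cost = abs(np.log(lx / ly))
        if cost < best_cost:
            best_cost = cost
            best = (nx, ny)
    return best


def make_lattice_membrane(
    n_lipids_per_leaflet: int = 324,
    apl: float = 60.7,
    thickness: float = 37.8,
    z_sigma: float = 0.0,
    xy_sigma: float = 0.0,
    d_coeff: float = 0.0,
    n_frames: int = 10,
    dt: float = 0.1,
    seed: int = 0,
    temperature: float = 303.15,
    tilt_sigma: float = 0.0,
    head_drop: float = 2.0,
    tail_length: float | None = None,
    vdw_radius: float = 2.0,
) -> SyntheticMembrane:
    """Jittered hexagonal bilayer of minimal three-atom lipids.

    Each leaflet is a hexagonal lattice with exactly ``apl`` Å² per site;
    the P atoms sit at ±thickness/2 about the box midplane (so the
    generated P–P thickness equals ``thickness`` exactly before jitter),
    C2 sits ``head_drop`` Å inward, and the terminal carbon continues along
    the director (≈ ∓z, with optional angular jitter ``tilt_sigma`` in
    radians).  Per frame the whole lipid gets independent Gaussian z jitter
    and its xy position follows a 2D random walk with per-step variance
    4·D·dt per the Einstein relation.
    """
    if min(apl, thickness, dt) <= 0 or n_lipids_per_leaflet < 16:
        raise ValueError("parameters must be positive and n >= 16")
    a = np.sqrt(2.0 * apl / np.sqrt(3.0))  # lattice constant
    if a < 2.0 * vdw_radius:
        raise ValueError(
            f"area per lipid {apl} Å² too small for vdW radius {vdw_radius} Å"
        )
    rng = np.random.default_rng(seed)
    topo = minimal_lipid_topology(vdw_radius=vdw_radius)
    nx, ny = _lattice_dimensions(n_lipids_per_leaflet)
    lx, ly = nx * a, ny * a * np.sqrt(3.0) / 2.0
    lz = 2.0 * thickness + 20.0
    n = n_lipids_per_leaflet
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    base_x = (ii + 0.5 * (jj % 2)).ravel() * a
    base_y = jj.ravel() * a * np.sqrt(3.0) / 2.0
    base = np.stack([base_x, base_y], axis=1)

    tail_len = 0.4 * thickness if tail_length is None else tail_length
    coords = np.empty((n_frames, 2 * n * 3, 3))
    lipid_ids = np.empty(2 * n * 3, dtype=int)
    atom_names = np.empty(2 * n * 3, dtype=object)
    species = np.full(2 * n * 3, topo.species_name, dtype=object)
    leaflet_truth: dict[int, str] = {}
    unwrapped = np.empty((n_frames, 2 * n, 2))

    step_sigma = np.sqrt(2.0 * d_coeff * A2_PER_NS_PER_UM2_PER_S * dt)  # per axis, Å
    for leaf_idx, (label, z_sign) in enumerate((("upper", 1.0), ("lower", -1.0))):
        jitter0 = rng.normal(scale=xy_sigma, size=(n, 2)) if xy_sigma > 0 else 0.0
        start = base + jitter0
        steps = (
            rng.normal(scale=step_sigma, size=(n_frames - 1, n, 2))
            if step_sigma > 0 and n_frames > 1
            else np.zeros((max(n_frames - 1, 0), n, 2))
        )
        tracks = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
        zj = (
            rng.normal(scale=z_sigma, size=(n_frames, n))
            if z_sigma > 0
            else np.zeros((n_frames, n))
        )
        if tilt_sigma > 0:
            tx = rng.normal(scale=tilt_sigma, size=(n_frames, n))
            ty = rng.normal(scale=tilt_sigma, size=(n_frames, n))
        else:
            tx = ty = np.zeros((n_frames, n))
        z_p = lz / 2.0 + z_sign * thickness / 2.0 + zj
        # director ≈ -z_sign with small-angle in-plane components
        dz = -z_sign * np.sqrt(np.clip(1.0 - tx**2 - ty**2, 1e-6, 1.0))
        for k, lid in enumerate(range(leaf_idx * n, (leaf_idx + 1) * n)):
            leaflet_truth[lid] = label
            base_atom = lid * 3
            lipid_ids[base_atom : base_atom + 3] = lid
            atom_names[base_atom : base_atom + 3] = ["P", "C2", "CT"]
            xy = tracks[:, k, :]
            unwrapped[:, lid, :] = xy
            p = np.column_stack([xy[:, 0], xy[:, 1], z_p[:, k]])
            d = np.column_stack([tx[:, k], ty[:, k], dz[:, k]])
            c2 = p + head_drop * d
            head_mid = 0.5 * (p + c2)
            ct = head_mid + tail_len * d
            coords[:, base_atom, :] = p
            coords[:, base_atom + 1, :] = c2
            coords[:, base_atom + 2, :] = ct
    box = np.tile(np.array([lx, ly, lz]), (n_frames, 1))
    frames = FrameSeries(
        wrap_coordinates(coords, box[:, None, :]),
        box,
        dt,
        lipid_ids,
        species,
        atom_names,
        temperature,
    )
    return SyntheticMembrane(
        frames,
        {topo.species_name: topo},
        leaflet_truth,
        apl,
        thickness,
        d_coeff,
        unwrapped,
    )


# --------------------------------------------------------------------------


def sample_tilt_splay(
    kappa: float = 1.12e-19,
    kappa_tilt: float = 2.86e-20,
    temperature: float = 303.15,
    n: int = 100_000,
    seed: int = 0,
) -> TiltSplaySamples:
    """Boltzmann tilt and splay samples at prescribed moduli.

    θ is rejection-sampled from p(θ) ∝ sin θ · exp(−κ_tilt θ²/(2 k_B T)) on
    [0, π/2); S is Gaussian with variance k_B T/χ where χ = κ/2 is the
    monolayer modulus of the package's splay convention.
    """
    if n < 100:
        raise ValueError("need at least 100 samples")
    rng = np.random.default_rng(seed)
    kbt = thermal_energy(temperature)
    a = kappa_tilt / (2.0 * kbt)
    # proposal ∝ θ exp(−aθ²) (Rayleigh); accept with prob sin θ / θ
    samples = np.empty(0)
    while samples.size < n:
        need = n - samples.size
        theta = rng.rayleigh(scale=1.0 / np.sqrt(2.0 * a), size=int(need * 1.4) + 16)
        accept = (theta < np.pi / 2) & (
            rng.uniform(size=theta.size) < np.sin(theta) / np.maximum(theta, 1e-300)
        )
        samples = np.concatenate([samples, theta[accept]])
    tilts = samples[:n]
    chi = kappa / 2.0
    splays = rng.normal(scale=np.sqrt(kbt / chi), size=n)
    return TiltSplaySamples(tilts, splays, {"accepted": n}, temperature)


def sample_thickness_series(
    ka: float = 235.0,
    a0: float = 60.7,
    t0: float = 3.78,
    temperature: float = 303.15,
    n: int = 10_000,
    seed: int = 0,
) -> ThicknessFluctuationSeries:
    """Gaussian thickness fluctuations at a prescribed K_A (mN/m).

    Relative deviations x are Gaussian with variance k_B T/(a0 K_A) (K_A
    converted to J/Å²) and t = t0 (1 − x).
    """
    rng = np.random.default_rng(seed)
    ka_J = ka / MNM_PER_J_PER_A2
    sigma = np.sqrt(thermal_energy(temperature) / (a0 * ka_J))
    x = rng.normal(scale=sigma, size=n)
    return ThicknessFluctuationSeries(t0 * (1.0 - x), a0, temperature, t0=t0)


# --------------------------------------------------------------------------


def make_isotherm(
    form: str = "exponential",
    params: dict | None = None,
    noise_sigma: float = 0.0,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    pi_grid=None,
    temperature: float = 295.15,
) -> Isotherm:
    """Analytic π–A isotherm sampled on a pressure grid plus area noise.

    Forms: ``exponential`` A(π) = A0 exp(−π/k) (params A0, k);
    ``linear`` A(π) = A0 − m·π (params A0, m); ``tabulated`` (params
    ``area``, ``pressure``).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if pi_grid is None:
        pi_grid = np.linspace(0.0, 45.0, 200)
    pi_grid = np.asarray(pi_grid, dtype=float)
    if form == "exponential":
        a0, k = params.get("A0", 90.0), params.get("k", 40.0)
        area = a0 * np.exp(-pi_grid / k)
    elif form == "linear":
        a0, m = params.get("A0", 90.0), params.get("m", 1.0)
        area = a0 - m * pi_grid
    elif form == "tabulated":
        area = np.asarray(params["area"], dtype=float)
        pi_grid = np.asarray(params["pressure"], dtype=float)
    else:
        raise ValueError(f"unknown isotherm form {form!r}")
    if noise_sigma > 0:
        area = area + rng.normal(scale=noise_sigma, size=area.shape)
        # keep the record strictly decreasing after noise
        area = np.minimum.accumulate(area) - 1e-9 * np.arange(area.size)
    return Isotherm(
        area,
        pi_grid,
        composition or {"A": 1.0},
        temperature,
    )


def make_mixed_isotherm(
    components: list[Isotherm],
    fractions: list[float],
    deviation=0.0,
    composition: dict[str, float] | None = None,
) -> Isotherm:
    """Mixture isotherm: ideal mole-fraction mean plus a deviation δ(π).

    ``deviation`` is a constant (Å²) or a callable δ(π); with δ ≡ 0 the
    mixture is ideal and ΔG_m^ex vanishes identically, and with constant δ
    the closed form is ΔG_m^ex = N_A·δ·(π − π₀).
    """
    from .isotherms import ideal_mixed_apl

    grid, ideal = ideal_mixed_apl(components, fractions)
    delta = deviation(grid) if callable(deviation) else float(deviation)
    if composition is None:
        composition = {}
        for x, iso in zip(fractions, components):
            for sp, xs in iso.composition.items():
                composition[sp] = composition.get(sp, 0.0) + x * xs
    return Isotherm(ideal + delta, grid, composition, components[0].temperature)


# --------------------------------------------------------------------------


def make_fluctuating_vesicle(
    kappa: float = 1.9e-19,
    sigma_bar: float = 10.0,
    radius: float = 5.0,
    temperature: float = 295.15,
    n_frames: int = 1200,
    l_max: int = 30,
    n_phi: int = 256,
    seed: int = 0,
    frame_interval: float = 0.16,
    render: bool = False,
    pixel_size: float = 0.1,
    psf_sigma: float = 1.2,
    peak_counts: float = 200.0,
    background_counts: float = 10.0,
    image_margin: float = 1.4,
):
    """Quasi-spherical Helfrich vesicle contours at prescribed rigidity.

    Spherical-harmonic amplitudes are drawn Gaussian, independently per
    frame, with the Milner–Safran variance
    k_B T/[κ(l−1)(l+2)(l(l+1)+σ̄)], and the equatorial section
    r(φ) = R(1 + u(φ)) is assembled directly in Fourier space up to
    ``l_max``.  With ``render=True`` a grayscale image stack is returned
    alongside the ground-truth contours: a bright rim of Gaussian radial
    cross-section (``psf_sigma`` px) over a dark background with
    Poisson counting noise.

    Returns a :class:`ContourSeries`, or ``(stack, ContourSeries)`` when
    rendering.
    """
    if not (1.0 <= radius <= 50.0):
        import warnings

        warnings.warn("vesicle radius outside the typical 1-50 µm range")
    rng = np.random.default_rng(seed)
    weights = _equatorial_weights(l_max)  # |Y_lm(pi/2)|²
    ls = np.arange(2, l_max + 1)
    hv = helfrich_mode_variance(ls, kappa, sigma_bar, temperature)
    n_half = n_phi // 2 + 1
    r = np.empty((n_frames, n_phi))
    for t in range(n_frames):
        c = np.zeros(n_half, dtype=complex)
        for l, var in zip(ls, hv):
            sd = np.sqrt(var)
            u_l0 = rng.normal(scale=sd)
            c[0] += u_l0 * np.sqrt(weights[l, 0])
            m_hi = min(l, n_half - 1)
            ms = np.arange(1, m_hi + 1)
            re = rng.normal(scale=sd / np.sqrt(2.0), size=ms.size)
            im = rng.normal(scale=sd / np.sqrt(2.0), size=ms.size)
            c[1 : m_hi + 1] += (re + 1j * im) * np.sqrt(weights[l, ms])
        u = np.fft.irfft(c * n_phi, n=n_phi)
        r[t] = radius * (1.0 + u)
    contours = ContourSeries(r, pixel_size, frame_interval, temperature)
    if not render:
        return contours
    # render bright-rim equatorial sections
    extent = int(np.ceil(image_margin * radius / pixel_size))
    size = 2 * extent + 1
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = float(extent)
    rho = np.hypot(xx - cx, yy - cy)
    phi_px = np.mod(np.arctan2(yy - cy, xx - cx), 2.0 * np.pi)
    phi_grid = contours.phi
    stack = np.empty((n_frames, size, size), dtype=np.uint16)
    for t in range(n_frames):
        r_px = np.interp(
            phi_px, np.concatenate([phi_grid, [2.0 * np.pi]]),
            np.concatenate([r[t], [r[t, 0]]]),
        ) / pixel_size
        intensity = background_counts + peak_counts * np.exp(
            -((rho - r_px) ** 2) / (2.0 * psf_sigma**2)
        )
        stack[t] = rng.poisson(intensity).astype(np.uint16)
    return stack, contours
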