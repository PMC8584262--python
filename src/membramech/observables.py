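"""Structural and dynamic bilayer observables.

Area per lipid comes from a periodic Voronoi tessellation of head points in
the bilayer plane; the system value is the mean of a Gaussian fitted to the
pooled per-lipid area histogram.  Membrane thickness is the separation of
the mean atom planes of opposite leaflets (for a chosen reference atom: the
phosphorus plane gives the conventional MT_P-P).  Lateral diffusion uses
Einstein's relation on the mean-square displacement of unwrapped head-point
tracks after removing per-leaflet center-of-mass motion.  Interdigitation is
the width of the mass-overlap region of the two leaflet density profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._voronoi import periodic_voronoi_areas
from .membrane_model import (
    FrameSeries,
    LeafletAssignment,
    LipidTopology,
    minimum_image,
    reference_points,
)
from .units import A2_PER_NS_PER_UM2_PER_S, NM_PER_A


@dataclass
class APLResult:
    """Area per lipid. Units: Å²."""

    system_apl: float
    system_apl_err: float  # Gaussian-fit standard error of the mean
    per_species: dict[str, tuple[float, float]]  # species -> (mean, sd)
    per_frame_values: np.ndarray  # pooled individual cell areas
    gaussian_fit: bool
    units: str = "Å²"


@dataclass
class MTResult:
    """Membrane thickness between opposite-leaflet atom planes. Units: nm."""

    thickness_nm: float
    sd_nm: float
    atom_tag: str
    per_frame_nm: np.ndarray
    units: str = "nm"

    @property
    def label(self) -> str:
        return f"MT_{self.atom_tag}-{self.atom_tag}"


@dataclass
class DiffusionResult:
    """Lateral (2D) diffusion coefficient. Units: µm²/s."""

    d_um2_per_s: float
    d_err: float
    msd_lags_ns: np.ndarray
    msd_A2: np.ndarray
    fit_window_ns: tuple[float, float]
    units: str = "µm²/s"


@dataclass
class InterdigitationResult:
    """Leaflet mass-overlap width. Units: Å."""

    width_A: float
    sd_A: float
    z_centers: np.ndarray
    density_upper: np.ndarray  # frame-averaged mass density vs z
    density_lower: np.ndarray
    units: str = "Å"


# --------------------------------------------------------------------------


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _freedman_diaconis_bins(values: np.ndarray) -> int:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 10
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    return max(10, int(np.ceil((values.max() - values.min()) / width)))


def fit_gaussian_to_histogram(values: np.ndarray) -> tuple[float, float, bool]:
    """Least-squares Gaussian on a Freedman–Diaconis histogram.

    Returns ``(mean, standard error of the mean, fitted)``; falls back to
    the sample mean ± sd/√n with a warning when the fit does not converge.
    """
    counts, edges = np.histogram(values, bins=_freedman_diaconis_bins(values))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (counts.max(), float(np.mean(values)), float(np.std(values) + 1e-12))
    try:
        popt, pcov = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
        mu_err = float(np.sqrt(pcov[1, 1]))
        if not np.isfinite(mu_err):
            raise RuntimeError("singular fit covariance")
        return float(popt[1]), mu_err, True
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian fit did not converge; falling back to sample mean ± sd")
        return float(np.mean(values)), float(np.std(values) / np.sqrt(len(values))), False


def area_per_lipid(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
) -> APLResult:
    """Per-lipid Voronoi areas pooled over frames and leaflets.

    Head points are projected onto the xy-plane and tessellated with their
    periodic images per leaflet and frame; cell areas of primary-image seeds
    are exact partitions of the box cross-section.
    """
    lids, heads, _ = reference_points(frames, topologies)
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    idx_of = {int(lid): j for j, lid in enumerate(lids)}
    pooled: list[np.ndarray] = []
    pooled_species: list[np.ndarray] = []
    species_of = np.array([frames.lipid_species(int(lid)) for lid in lids], dtype=object)
    for label in ("upper", "lower"):
        members = [idx_of[lid] for lid in leaflets.lipids(label)]
        if len(members) < 3:
            raise ValueError(f"{label} leaflet has fewer than 3 lipids")
        for f in range(frames.n_frames):
            areas = periodic_voronoi_areas(
                heads[f, members, :2], frames.box[f, :2]
            )
            pooled.append(areas)
            pooled_species.append(species_of[members])
    values = np.concatenate(pooled)
    value_species = np.concatenate(pooled_species)
    mu, mu_err, ok = fit_gaussian_to_histogram(values)
    per_species = {
        str(sp): (
            float(np.mean(values[value_species == sp])),
            float(np.std(values[value_species == sp])),
        )
        for sp in np.unique(value_species.astype(str))
    }
    return APLResult(mu, mu_err, per_species, values, ok)


def membrane_thickness(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    atom_tag: str = "P",
) -> MTResult:
    """Thickness between the mean z of tag atoms in opposite leaflets.

    ``atom_tag`` is one of P, C1, C2 (sterol species use their declared
    surrogates).  Reported as mean ± sd over frames, in nm.
    """
    per_leaflet_idx: dict[str, list[int]] = {"upper": [], "lower": []}
    for lid, leaf in leaflets.leaflet.items():
        sp = frames.lipid_species(lid)
        atom = topologies[sp].tag_atom(atom_tag)
        per_leaflet_idx[leaf].append(frames.atom_index(lid, atom))
    for leaf, idx in per_leaflet_idx.items():
        if not idx:
            raise ValueError(f"{leaf} leaflet has no lipids")
    z_up = frames.coords[:, per_leaflet_idx["upper"], 2].mean(axis=1)
    z_lo = frames.coords[:, per_leaflet_idx["lower"], 2].mean(axis=1)
    per_frame = (z_up - z_lo) * NM_PER_A
    return MTResult(
        float(np.mean(per_frame)), float(np.std(per_frame)), atom_tag, per_frame
    )


# --------------------------------------------------------------------------
# diffusion


def unwrap_tracks(xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from (n_frames, n_lipids, 2) tracks.

    Consecutive displacements are taken minimum-image (valid as long as no
    particle moves more than half a box length per frame) and accumulated.
    """
    steps = minimum_image(np.diff(xy, axis=0), box_xy[1:, None, :])
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(steps, axis=0)
    return out


def mean_square_displacement(tracks: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged MSD of (n_frames, n_lipids, 2) tracks, lags 0..max_lag."""
    n = tracks.shape[0]
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        d = tracks[lag:] - tracks[:-lag]
        msd[lag] = np.mean(np.sum(d**2, axis=-1))
    return msd


def lateral_diffusion(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    species: str | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> DiffusionResult:
    """Einstein-relation lateral diffusion coefficient of a species.

    Head-point xy tracks are unwrapped across the periodic boundaries, the
    center-of-mass motion of each leaflet is subtracted, and the MSD is
    averaged over lipids and time origins.  D = slope/4 of a least-squares
    line fitted on ``fit_window`` (as fractions of the maximum lag).
    """
    if frames.n_frames < 20:
        raise ValueError("lateral diffusion needs at least 20 frames")
    lids, heads, _ = reference_points(frames, topologies)
    xy = unwrap_tracks(heads[:, :, :2], frames.box[:, :2])
    idx_of = {int(lid): j for j, lid in enumerate(lids)}
    # per-leaflet center-of-mass subtraction
    corrected = np.empty_like(xy)
    for label in ("upper", "lower"):
        members = [idx_of[lid] for lid in leaflets.lipids(label)]
        if not members:
            continue
        com = xy[:, members, :].mean(axis=1, keepdims=True)
        corrected[:, members, :] = xy[:, members, :] - com
    if species is not None:
        keep = [
            idx_of[int(lid)]
            for lid in lids
            if frames.lipid_species(int(lid)) == species
        ]
        if not keep:
            raise ValueError(f"species {species!r} not present")
        corrected = corrected[:, keep, :]
    max_lag = frames.n_frames - 1
    lo = int(round(fit_window[0] * max_lag))
    hi = int(round(fit_window[1] * max_lag))
    if lo < 1 or hi > max_lag or hi <= lo:
        raise ValueError(f"fit window {fit_window} outside available lags (1..{max_lag})")
    msd = mean_square_displacement(corrected, hi)
    lags_ns = np.arange(hi + 1) * frames.dt
    tau = lags_ns[lo : hi + 1]
    y = msd[lo : hi + 1]
    (slope, intercept), cov = np.polyfit(tau, y, 1, cov=True)
    d_A2_ns = slope / 4.0
    d_err_A2_ns = float(np.sqrt(cov[0, 0])) / 4.0
    return DiffusionResult(
        d_A2_ns / A2_PER_NS_PER_UM2_PER_S,
        d_err_A2_ns / A2_PER_NS_PER_UM2_PER_S,
        lags_ns,
        msd,
        (float(tau[0]), float(tau[-1])),
    )


# --------------------------------------------------------------------------
# interdigitation


def overlap_width(rho_u: np.ndarray, rho_l: np.ndarray, dz: float) -> float:
    """Mass-overlap width w = ∫ 4 ρ_u ρ_l / (ρ_u + ρ_l)² dz (Å)."""
    rho_u = np.asarray(rho_u, dtype=float)
    rho_l = np.asarray(rho_l, dtype=float)
    total = rho_u + rho_l
    integrand = np.zeros_like(total)
    mask = total > 0
    integrand[mask] = 4.0 * rho_u[mask] * rho_l[mask] / total[mask] ** 2
    return float(np.sum(integrand) * dz)


def interdigitation(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    n_bins: int = 100,
) -> InterdigitationResult:
    """Width of the leaflet mass-density overlap region along z."""
    masses = np.array(
        [
            topologies[sp].mass(name)
            for sp, name in zip(frames.species, frames.atom_names)
        ]
    )
    leaflet_of = np.array(
        [leaflets.leaflet[int(lid)] for lid in frames.lipid_ids], dtype=object
    )
    up = leaflet_of == "upper"
    lo = leaflet_of == "lower"
    if not up.any() or not lo.any():
        raise ValueError("empty leaflet")
    widths = np.empty(frames.n_frames)
    acc_u = np.zeros(n_bins)
    acc_l = np.zeros(n_bins)
    lz = float(frames.box[:, 2].max())
    edges = np.linspace(0.0, lz, n_bins + 1)
    dz = edges[1] - edges[0]
    for f in range(frames.n_frames):
        z = frames.coords[f, :, 2]
        rho_u, _ = np.histogram(z[up], bins=edges, weights=masses[up])
        rho_l, _ = np.histogram(z[lo], bins=edges, weights=masses[lo])
        widths[f] = overlap_width(rho_u / dz, rho_l / dz, dz)
        acc_u += rho_u / dz
        acc_l += rho_l / dz
    centers = 0.5 * (edges[:-1] + edges[1:])
    return InterdigitationResult(
        float(np.mean(widths)),
        float(np.std(widths)),
        centers,
        acc_u / frames.n_frames,
        acc_l / frames.n_frames,
    )
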