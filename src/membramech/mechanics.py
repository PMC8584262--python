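"""Membrane mechanics from real-space fluctuations.

Bending rigidity κ and tilt modulus κ_tilt come from the real-space
fluctuation (RSF) analysis of lipid directors: the tilt angle θ of each
director against the leaflet normal and the splay S of weakly correlated
neighbor pairs are pooled over lipids and frames, their Boltzmann-inverted
potentials of mean force (PMF) are fitted with quadratics, and the
curvatures give the moduli.  The area compressibility K_A comes from the
thickness-fluctuation PMF: relative thickness deviations x = (t0 − t)/t0
are binned, −(2 k_B T / a0) ln p(x) is fitted with K_A x² + C′.

The three fits are exposed as scikit-learn style estimators
(:class:`TiltModulusEstimator`, :class:`SplayRigidityEstimator`,
:class:`AreaCompressibilityEstimator`) so they compose with sklearn
tooling; the module-level functions are thin wrappers returning the
package's result records.

Unit convention for splay: S carries 1/Å, and the quadratic PMF coefficient
χ is taken numerically as the monolayer modulus on a 1-Å² patch (the
bilayer value is 2χ).  The synthetic generators share the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._voronoi import periodic_voronoi_neighbors
from .membrane_model import (
    FrameSeries,
    LeafletAssignment,
    LipidTopology,
    minimum_image,
    reference_points,
)
from .units import MNM_PER_J_PER_A2, thermal_energy


@dataclass
class TiltSplaySamples:
    """Pooled per-lipid tilt angles and per-pair splay values.

    tilts in radians (0 ≤ θ < π/2 after filtering), splays in 1/Å;
    ``pair_filter_log`` counts accepted and rejected neighbor pairs by
    rejection reason.
    """

    tilts: np.ndarray
    splays: np.ndarray
    pair_filter_log: dict[str, int] = field(default_factory=dict)
    temperature: float = 303.15


@dataclass
class ModulusResult:
    """A fitted modulus (κ or κ_tilt) in J with PMF diagnostics."""

    value: float  # J
    uncertainty: float  # J, from fit covariance
    kind: str  # 'tilt' or 'bending'
    pmf_bins: np.ndarray  # bin centers (rad or 1/Å)
    pmf_kbt: np.ndarray  # PMF in kBT units
    fit_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)
    units: str = "J"


@dataclass
class ThicknessFluctuationSeries:
    """Instantaneous membrane thickness per frame (nm) with context."""

    t: np.ndarray  # nm
    a0: float  # area per lipid, Å²
    temperature: float  # K
    t0: float | None = None  # equilibrium thickness, nm; default mean(t)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(self.t <= 0):
            raise ValueError("all thickness samples must be positive")
        if self.t0 is None:
            self.t0 = float(np.mean(self.t))


@dataclass
class KAResult:
    """Area compressibility coefficient from thickness fluctuations."""

    ka_mN_per_m: float
    uncertainty: float
    offset: float  # fitted C', J/Å²
    pmf_x: np.ndarray  # relative-deviation bin centers
    pmf_J_per_A2: np.ndarray
    units: str = "mN/m"
    #: the method's output is read as a whole-membrane value; the original
    #: formulation was per-leaflet and the literature is not unanimous.
    scope: str = "whole_membrane"


# --------------------------------------------------------------------------
# PMF machinery


def _pmf_from_histogram(
    samples: np.ndarray,
    n_bins: int | None,
    jacobian=None,
):
    """Histogram samples and Boltzmann-invert to a PMF in ln-probability units.

    Returns (centers, neg_log_p, counts) over populated bins; ``jacobian``
    optionally divides the density (e.g. sin θ for polar angles).
    """
    samples = np.asarray(samples, dtype=float)
    if n_bins is None:
        n_bins = max(20, min(200, int(np.sqrt(samples.size) / 2)))
    counts, edges = np.histogram(samples, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    centers, counts = centers[keep], counts[keep]
    density = counts / (samples.size * (edges[1] - edges[0]))
    if jacobian is not None:
        density = density / jacobian(centers)
    neg_log_p = -np.log(density)
    return centers, neg_log_p, counts


def _select_fit_range(neg_log_p: np.ndarray, window: float, min_bins: int):
    """Bins within ``window`` (in kBT, i.e. ln-probability units) of the PMF
    minimum."""
    rel = neg_log_p - neg_log_p.min()
    mask = rel <= window
    if mask.sum() < min_bins:
        raise ValueError(
            f"fewer than {min_bins} populated bins within {window} kBT of the PMF minimum"
        )
    return mask


def _weighted_polyfit(x, y, deg, counts):
    """Least squares with Poisson weights (w = sqrt(counts)); returns
    coefficients (highest power first) and their standard errors."""
    coef, cov = np.polyfit(x, y, deg, w=np.sqrt(counts), cov=True)
    return coef, np.sqrt(np.diag(cov))


# --------------------------------------------------------------------------
# estimators


class TiltModulusEstimator(BaseEstimator):
    """Tilt modulus from the quadratic PMF of director tilt angles.

    The sin θ Jacobian of the polar angle is removed before inversion so the
    small-angle PMF is quadratic: PMF(θ) = ½ κ_tilt θ² + c.  ``fit`` expects
    a 1-D array (or single-column matrix) of tilt angles in radians.

    Attributes (after ``fit``): ``tilt_modulus_`` (J), ``tilt_modulus_err_``,
    ``pmf_theta_``, ``pmf_kbt_``, ``fit_range_``.
    """

    def __init__(self, temperature=303.15, n_bins=None, fit_window_kbt=2.0, min_bins=5):
        self.temperature = temperature
        self.n_bins = n_bins
        self.fit_window_kbt = fit_window_kbt
        self.min_bins = min_bins

    def fit(self, X, y=None):
        theta = np.asarray(X, dtype=float).reshape(-1)
        if theta.size < 1000:
            raise ValueError("tilt PMF fit needs at least 1000 samples")
        if np.any(theta < 0) or np.any(theta >= np.pi / 2):
            raise ValueError("tilt angles must lie in [0, π/2)")
        kbt = thermal_energy(self.temperature)
        centers, nlp, counts = _pmf_from_histogram(theta, self.n_bins, jacobian=np.sin)
        mask = _select_fit_range(nlp, self.fit_window_kbt, self.min_bins)
        coef, err = _weighted_polyfit(
            centers[mask] ** 2, nlp[mask] * kbt, 1, counts[mask]
        )
        if coef[0] <= 0:
            raise ValueError("non-convex tilt PMF on the fit range")
        self.tilt_modulus_ = float(2.0 * coef[0])
        self.tilt_modulus_err_ = float(2.0 * err[0])
        self.pmf_theta_ = centers
        self.pmf_kbt_ = nlp - nlp.min()
        self.fit_range_ = (float(centers[mask].min()), float(centers[mask].max()))
        return self


class SplayRigidityEstimator(BaseEstimator):
    """Bending rigidity from the quadratic PMF of neighbor-pair splay.

    PMF(S) = ½ χ S² + b S + c; the curvature χ is the monolayer modulus and
    the bilayer rigidity is κ = 2χ (the linear term is retained as a
    symmetry diagnostic).  ``area_per_lipid`` (Å²) is recorded as metadata.

    Attributes: ``kappa_`` (bilayer, J), ``kappa_err_``,
    ``kappa_monolayer_``, ``linear_coef_``, ``pmf_splay_``, ``pmf_kbt_``,
    ``fit_range_``.
    """

    def __init__(
        self,
        temperature=303.15,
        n_bins=None,
        fit_window_kbt=2.0,
        min_bins=5,
        area_per_lipid=None,
    ):
        self.temperature = temperature
        self.n_bins = n_bins
        self.fit_window_kbt = fit_window_kbt
        self.min_bins = min_bins
        self.area_per_lipid = area_per_lipid

    def fit(self, X, y=None):
        splay = np.asarray(X, dtype=float).reshape(-1)
        if splay.size < 1000:
            raise ValueError("splay PMF fit needs at least 1000 samples")
        kbt = thermal_energy(self.temperature)
        centers, nlp, counts = _pmf_from_histogram(splay, self.n_bins)
        mask = _select_fit_range(nlp, self.fit_window_kbt, self.min_bins)
        coef, err = _weighted_polyfit(centers[mask], nlp[mask] * kbt, 2, counts[mask])
        if coef[0] <= 0:
            raise ValueError("non-convex splay PMF on the fit range")
        chi = 2.0 * coef[0]
        self.kappa_monolayer_ = float(chi)
        self.kappa_ = float(2.0 * chi)
        self.kappa_err_ = float(2.0 * 2.0 * err[0])
        self.linear_coef_ = float(coef[1])
        self.pmf_splay_ = centers
        self.pmf_kbt_ = nlp - nlp.min()
        self.fit_range_ = (float(centers[mask].min()), float(centers[mask].max()))
        return self


class AreaCompressibilityEstimator(BaseEstimator):
    """Area compressibility K_A from thickness-fluctuation statistics.

    Relative deviations x = (t0 − t)/t0 are binned, the PMF
    −(2 k_B T / a0) ln p(x) is fitted with K_A x² + C′ over the central
    range, and K_A is converted from J/Å² to mN/m.

    Attributes: ``ka_`` (mN/m), ``ka_err_``, ``offset_`` (C′, J/Å²),
    ``pmf_x_``, ``pmf_J_per_A2_``.
    """

    def __init__(
        self,
        area_per_lipid=60.0,
        temperature=303.15,
        equilibrium_thickness=None,
        n_bins=None,
        fit_window_kbt=2.0,
        min_bins=5,
    ):
        self.area_per_lipid = area_per_lipid
        self.temperature = temperature
        self.equilibrium_thickness = equilibrium_thickness
        self.n_bins = n_bins
        self.fit_window_kbt = fit_window_kbt
        self.min_bins = min_bins

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        if t.size < 500:
            raise ValueError("thickness PMF fit needs at least 500 samples")
        t0 = (
            float(np.mean(t))
            if self.equilibrium_thickness is None
            else float(self.equilibrium_thickness)
        )
        if np.std(t) <= 1e-10 * abs(t0):
            raise ValueError("degenerate thickness distribution (constant series)")
        x = (t0 - t) / t0
        kbt = thermal_energy(self.temperature)
        scale = 2.0 * kbt / self.area_per_lipid  # J/Å² per ln-unit
        centers, nlp, counts = _pmf_from_histogram(x, self.n_bins)
        mask = _select_fit_range(nlp, self.fit_window_kbt, self.min_bins)
        if mask.sum() < 5:
            raise ValueError("fewer than 5 populated bins in the fit range")
        coef, err = _weighted_polyfit(
            centers[mask] ** 2, nlp[mask] * scale, 1, counts[mask]
        )
        if coef[0] <= 0:
            raise ValueError("non-convex thickness PMF on the fit range")
        self.ka_ = float(coef[0] * MNM_PER_J_PER_A2)
        self.ka_err_ = float(err[0] * MNM_PER_J_PER_A2)
        self.offset_ = float(coef[1])
        self.pmf_x_ = centers
        self.pmf_J_per_A2_ = (nlp - nlp.min()) * scale
        self.t0_ = t0
        return self


# --------------------------------------------------------------------------
# frame-level sampling


DEFAULT_NEIGHBOR_RULE = {"d_min": 5.0, "d_max": 12.0, "max_angle_deg": 60.0}


def lipid_directors(
    frames: FrameSeries,
    topologies: dict[str, LipidTopology],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit directors (head point → tail point) per lipid per frame.

    Returns ``(lipid_ids, heads, directors)`` with arrays of shape
    (n_frames, n_lipids, 3).
    """
    lids, heads, tails = reference_points(frames, topologies)
    vec = minimum_image(tails - heads, frames.box[:, None, :])
    norm = np.linalg.norm(vec, axis=-1)
    if np.any(norm < 1e-9):
        f, j = np.argwhere(norm < 1e-9)[0]
        raise ValueError(
            f"zero-length director for lipid {int(lids[j])} in frame {int(f)}"
        )
    return lids, heads, vec / norm[..., None]


def tilt_splay_samples(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    neighbor_rule: dict | None = None,
) -> TiltSplaySamples:
    """Pool tilt and splay samples over all lipids, frames and leaflets.

    Tilt: angle between the director and the inward leaflet normal.  Splay
    of a Voronoi-neighbor pair: projected finite-difference divergence of
    the in-plane director components along the inter-head axis,
    S = (d_j⊥ − d_i⊥)·ê_ij / |r_ij|.  Pairs outside the weak-correlation
    window (head separation in [d_min, d_max] Å, director angle below
    ``max_angle_deg``) are rejected and logged.
    """
    rule = {**DEFAULT_NEIGHBOR_RULE, **(neighbor_rule or {})}
    lids, heads, directors = lipid_directors(frames, topologies)
    idx_of = {int(lid): j for j, lid in enumerate(lids)}
    tilts: list[np.ndarray] = []
    splays: list[float] = []
    log = {"accepted": 0, "rejected_distance": 0, "rejected_angle": 0}
    for label, nz in (("upper", -1.0), ("lower", 1.0)):
        members = np.array([idx_of[lid] for lid in leaflets.lipids(label)], dtype=int)
        if members.size == 0:
            continue
        normal = np.array([0.0, 0.0, nz])
        cos_t = np.clip(directors[:, members, :] @ normal, -1.0, 1.0)
        tilts.append(np.arccos(cos_t).ravel())
        for f in range(frames.n_frames):
            pts = heads[f, members, :2]
            box_xy = frames.box[f, :2]
            for a, b in periodic_voronoi_neighbors(pts, box_xy):
                ia, ib = members[a], members[b]
                rij = minimum_image(heads[f, ib, :2] - heads[f, ia, :2], box_xy)
                dist = float(np.hypot(*rij))
                if not (rule["d_min"] <= dist <= rule["d_max"]):
                    log["rejected_distance"] += 1
                    continue
                di, dj = directors[f, ia], directors[f, ib]
                angle = np.degrees(np.arccos(np.clip(np.dot(di, dj), -1.0, 1.0)))
                if angle >= rule["max_angle_deg"]:
                    log["rejected_angle"] += 1
                    continue
                e_ij = rij / dist
                splays.append(float(np.dot(dj[:2] - di[:2], e_ij) / dist))
                log["accepted"] += 1
    return TiltSplaySamples(
        np.concatenate(tilts) if tilts else np.empty(0),
        np.asarray(splays),
        log,
        frames.temperature,
    )


# --------------------------------------------------------------------------
# function wrappers


def fit_tilt_modulus(
    samples: TiltSplaySamples | np.ndarray, temperature: float | None = None, **kwargs
) -> ModulusResult:
    """Fit the tilt modulus (J) from pooled tilt angles."""
    theta = samples.tilts if isinstance(samples, TiltSplaySamples) else np.asarray(samples)
    if temperature is None:
        temperature = getattr(samples, "temperature", 303.15)
    est = TiltModulusEstimator(temperature=temperature, **kwargs).fit(theta)
    return ModulusResult(
        est.tilt_modulus_,
        est.tilt_modulus_err_,
        "tilt",
        est.pmf_theta_,
        est.pmf_kbt_,
        est.fit_range_,
    )


def fit_bending_rigidity_rsf(
    samples: TiltSplaySamples | np.ndarray,
    temperature: float | None = None,
    apl: float | None = None,
    **kwargs,
) -> ModulusResult:
    """Fit the bilayer bending rigidity κ (J) from pooled splay samples."""
    splay = samples.splays if isinstance(samples, TiltSplaySamples) else np.asarray(samples)
    if temperature is None:
        temperature = getattr(samples, "temperature", 303.15)
    est = SplayRigidityEstimator(
        temperature=temperature, area_per_lipid=apl, **kwargs
    ).fit(splay)
    return ModulusResult(
        est.kappa_,
        est.kappa_err_,
        "bending",
        est.pmf_splay_,
        est.pmf_kbt_,
        est.fit_range_,
        metadata={
            "monolayer_kappa_J": est.kappa_monolayer_,
            "linear_coef": est.linear_coef_,
            "area_per_lipid_A2": apl,
            "convention": "bilayer = 2 x monolayer",
        },
    )


def area_compressibility(series: ThicknessFluctuationSeries, **kwargs) -> KAResult:
    """Fit K_A (mN/m) from a thickness-fluctuation series."""
    est = AreaCompressibilityEstimator(
        area_per_lipid=series.a0,
        temperature=series.temperature,
        equilibrium_thickness=series.t0,
        **kwargs,
    ).fit(series.t)
    return KAResult(est.ka_, est.ka_err_, est.offset_, est.pmf_x_, est.pmf_J_per_A2_)


def thickness_fluctuation_series(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    a0: float,
    atom_tag: str = "P",
) -> ThicknessFluctuationSeries:
    """Instantaneous per-frame thickness as input for the K_A fit."""
    from .observables import membrane_thickness

    mt = membrane_thickness(frames, leaflets, topologies, atom_tag=atom_tag)
    return ThicknessFluctuationSeries(mt.per_frame_nm, a0, frames.temperature)
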