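"""Hydrophobic defect (acyl-chain accessibility) analysis.

A leaflet surface is rasterized on a ~0.5 Å grid: each grid point takes the
head/tail label of the outermost atom whose van der Waals disc covers it,
or stays empty.  F_exp is the fraction of the map showing acyl chain.  The
sphere-probe analysis then keeps only hydrophobic patches large enough to
admit a probe disc of a given radius: a point is a defect-candidate center
when every grid point within the probe radius is tail-labeled, and the
defect set is the union of the probe discs of all centers (a morphological
opening of the tail mask on the periodic grid).  Empty (uncovered) cells
count in the denominator and block probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .membrane_model import (
    FrameSeries,
    LeafletAssignment,
    LipidTopology,
    minimum_image,
)

EMPTY, HEAD, TAIL = 0, 1, 2


@dataclass
class SurfaceGrid:
    """Labeled 2D occupancy map of one leaflet surface."""

    labels: np.ndarray  # int array (nx, ny), values EMPTY/HEAD/TAIL
    spacing: tuple[float, float]  # Å per cell along x and y
    leaflet: str
    frame_index: int


@dataclass
class DefectCurve:
    """Defect fraction vs probe radius, plus the probe-free exposed fraction."""

    radii_nm: np.ndarray
    fraction: np.ndarray
    f_exp: float
    fraction_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def occupancy_grid(
    frames: FrameSeries,
    frame_index: int,
    leaflet: str,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    spacing: float = 0.5,
) -> SurfaceGrid:
    """Rasterize one leaflet of one frame into head/tail/empty cells.

    Atoms are sorted from the bilayer midplane outward and painted in that
    order, so the outermost covering atom decides each cell (ties broken by
    larger vdW radius, then lower atom index).  An atom's footprint is the
    disc of its full vdW radius around its xy position, periodic in xy.
    """
    box = frames.box[frame_index]
    nx = max(1, int(round(box[0] / spacing)))
    ny = max(1, int(round(box[1] / spacing)))
    sx, sy = box[0] / nx, box[1] / ny

    in_leaflet = np.array(
        [leaflets.leaflet[int(lid)] == leaflet for lid in frames.lipid_ids]
    )
    idx = np.flatnonzero(in_leaflet)
    if idx.size == 0:
        raise ValueError(f"no atoms in {leaflet!r} leaflet")
    coords = frames.coords[frame_index, idx]
    radii = np.array(
        [
            topologies[frames.species[i]].vdw_radius(frames.atom_names[i])
            for i in idx
        ]
    )
    is_head = np.array(
        [
            topologies[frames.species[i]].is_head_atom(frames.atom_names[i])
            for i in idx
        ]
    )
    # outward distance from the fixed midplane, periodic-safe in z
    dz = np.abs(minimum_image(coords[:, 2] - leaflets.midplane_z, box[2]))
    order = np.lexsort((-idx, radii, dz))  # paint outermost (largest key) last

    labels = np.full((nx, ny), EMPTY, dtype=np.uint8)

    def _axis_window(pos, r, spacing, n):
        half = int(np.ceil(r / spacing))
        if 2 * half + 1 >= n:
            idx = np.arange(n)
        else:
            center = int(np.round(pos / spacing))
            idx = np.arange(center - half, center + half + 1) % n
        length = n * spacing
        delta = minimum_image(idx * spacing - pos, length)
        return idx, delta

    for k in order:
        r = radii[k]
        ii, dx = _axis_window(coords[k, 0], r, sx, nx)
        jj, dy = _axis_window(coords[k, 1], r, sy, ny)
        mask = dx[:, None] ** 2 + dy[None, :] ** 2 <= r**2
        if not mask.any():
            continue
        lab = HEAD if is_head[k] else TAIL
        sub = np.ix_(ii, jj)
        labels[sub] = np.where(mask, lab, labels[sub])
    return SurfaceGrid(labels, (sx, sy), leaflet, frame_index)


def exposed_fraction(grid: SurfaceGrid) -> float:
    """F_exp: tail cells over all cells (empty cells count in the total)."""
    return float(np.count_nonzero(grid.labels == TAIL) / grid.labels.size)


def _disc_footprint(radius_A: float, sx: float, sy: float) -> np.ndarray:
    ni = int(np.floor(radius_A / sx))
    nj = int(np.floor(radius_A / sy))
    di = np.arange(-ni, ni + 1)[:, None] * sx
    dj = np.arange(-nj, nj + 1)[None, :] * sy
    return (di**2 + dj**2) <= radius_A**2


def probe_defect_fraction(
    grid: SurfaceGrid, radii_nm=None
) -> DefectCurve:
    """Defect fraction as a function of sphere-probe radius.

    For each radius, candidate centers are grid points whose entire
    periodic neighborhood within the radius is tail-labeled; all points
    covered by a candidate's probe disc are defects.  Radii below the grid
    spacing degrade to the probe-free exposed fraction (with a warning).
    """
    if radii_nm is None:
        radii_nm = np.arange(0.1, 0.5001, 0.05)
    radii_nm = np.asarray(radii_nm, dtype=float)
    box_min = min(
        grid.labels.shape[0] * grid.spacing[0], grid.labels.shape[1] * grid.spacing[1]
    )
    if np.any(radii_nm * 10.0 >= box_min / 4):
        raise ValueError("probe radius must be below a quarter of the box extent")
    tail = grid.labels == TAIL
    f_exp = exposed_fraction(grid)
    fractions = np.empty(radii_nm.size)
    for k, r_nm in enumerate(radii_nm):
        r_A = r_nm * 10.0
        if r_A < min(grid.spacing):
            warnings.warn(
                f"probe radius {r_nm} nm below grid spacing; degenerates to F_exp"
            )
            fractions[k] = f_exp
            continue
        fp = _disc_footprint(r_A, *grid.spacing)
        centers = minimum_filter(tail.astype(np.uint8), footprint=fp, mode="wrap")
        defect = maximum_filter(centers, footprint=fp, mode="wrap")
        fractions[k] = defect.sum() / defect.size
    return DefectCurve(radii_nm, fractions, f_exp)


def defect_curve(
    frames: FrameSeries,
    leaflets: LeafletAssignment,
    topologies: dict[str, LipidTopology],
    leaflet: str = "upper",
    radii_nm=None,
    spacing: float = 0.5,
    frame_indices=None,
) -> DefectCurve:
    """Frame-averaged defect curve (mean ± sd over the analyzed frames)."""
    if frame_indices is None:
        frame_indices = range(frames.n_frames)
    per_frame = []
    f_exps = []
    radii = None
    for f in frame_indices:
        grid = occupancy_grid(frames, f, leaflet, leaflets, topologies, spacing)
        curve = probe_defect_fraction(grid, radii_nm)
        per_frame.append(curve.fraction)
        f_exps.append(curve.f_exp)
        radii = curve.radii_nm
    stack = np.array(per_frame)
    return DefectCurve(
        radii,
        stack.mean(axis=0),
        float(np.mean(f_exps)),
        fraction_sd=stack.std(axis=0),
        meta={"n_frames": len(per_frame), "leaflet": leaflet},
    )
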