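"""Core data model for lipid membrane frames.

Holds per-species topologies (which atoms form the headgroup and the acyl
chains, and which atoms serve as geometric reference points), time-ordered
coordinate frames with orthorhombic periodic boxes, and leaflet bookkeeping.
Readers cover multi-frame PDB/GRO/XYZ (through MDAnalysis) and the package's
own plain-text "native" frame format, which is documented in
:func:`write_native_frames` and designed so synthetic data needs no
third-party writer.

Geometry conventions: coordinates in Å; boxes orthorhombic with the
minimum-image convention for all distances; the lipid *head point* is the
midpoint between the phosphorus (or its sterol surrogate) and C2 atoms, the
*tail point* the midpoint of the terminal chain carbons.  Midpoints are
evaluated with minimum-image displacements so a lipid split across a
periodic boundary is handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


class TopologyError(ValueError):
    """Raised when coordinates cannot be matched to a declared topology."""


class MonolayerError(ValueError):
    """Raised when a bilayer operation receives single-leaflet input."""


# --------------------------------------------------------------------------
# topology


@dataclass
class LipidTopology:
    """Per-species atom declaration.

    The headgroup comprises all atoms down to and including the glycerol C2
    atom; everything else belongs to the acyl chains.  ``p_atom`` is the
    phosphorus atom (for cholesterol-like sterols the C3 surrogate) and is,
    with ``c2_atom``, the reference pair defining the head point.
    """

    species_name: str
    head_atoms: list[str]
    tail_atoms: list[list[str]]  # one list per acyl chain
    p_atom: str
    c2_atom: str
    terminal_atoms: list[str]  # last carbon of each chain
    c1_atom: str | None = None  # C1 (or sterol surrogate) for thickness readout
    vdw_radii: dict[str, float] = field(default_factory=dict)  # Å
    masses: dict[str, float] = field(default_factory=dict)  # amu; default 1.0

    def __post_init__(self) -> None:
        flat_tails = [a for chain in self.tail_atoms for a in chain]
        overlap = set(self.head_atoms) & set(flat_tails)
        if overlap:
            raise TopologyError(
                f"{self.species_name}: head and tail atom sets overlap: {sorted(overlap)}"
            )
        for atom in (self.p_atom, self.c2_atom):
            if atom not in self.head_atoms:
                raise TopologyError(
                    f"{self.species_name}: reference atom {atom!r} is not a head atom"
                )
        for atom in self.terminal_atoms:
            if atom not in flat_tails:
                raise TopologyError(
                    f"{self.species_name}: terminal atom {atom!r} is not a tail atom"
                )

    def tag_atom(self, tag: str) -> str:
        """Resolve a thickness atom tag (P, C1 or C2) to an atom name."""
        resolved = {"P": self.p_atom, "C2": self.c2_atom, "C1": self.c1_atom}.get(tag)
        if resolved is None:
            raise TopologyError(
                f"{self.species_name}: atom tag {tag!r} has no declared atom or surrogate"
            )
        return resolved

    @property
    def all_atoms(self) -> list[str]:
        """Declared atom names, heads first then chains in order."""
        return list(self.head_atoms) + [a for chain in self.tail_atoms for a in chain]

    @property
    def n_atoms(self) -> int:
        return len(self.all_atoms)

    def is_head_atom(self, name: str) -> bool:
        return name in self.head_atoms

    def vdw_radius(self, name: str) -> float:
        try:
            return self.vdw_radii[name]
        except KeyError:
            raise TopologyError(
                f"{self.species_name}: no van der Waals radius declared for {name!r}"
            ) from None

    def mass(self, name: str) -> float:
        return self.masses.get(name, 1.0)


def minimal_lipid_topology(
    species_name: str = "LIP",
    vdw_radius: float = 2.0,
    head_mass: float = 100.0,
    tail_mass: float = 100.0,
) -> LipidTopology:
    """Three-atom lipid (P, C2, CT) — the smallest structure exercising every
    reference-point rule.  Used by the synthetic generators."""
    return LipidTopology(
        species_name=species_name,
        head_atoms=["P", "C2"],
        tail_atoms=[["CT"]],
        p_atom="P",
        c2_atom="C2",
        terminal_atoms=["CT"],
        vdw_radii={"P": vdw_radius, "C2": vdw_radius, "CT": vdw_radius},
        masses={"P": head_mass / 2, "C2": head_mass / 2, "CT": tail_mass},
    )


def load_topologies(path) -> dict[str, LipidTopology]:
    """Read a YAML topology file: one stanza per species.

    Expected keys per species: ``head_atoms``, ``tail_atoms`` (list of
    per-chain lists), ``p_atom``, ``c2_atom``, ``terminal_atoms``,
    ``vdw_radii`` (map), optional ``masses`` (map).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    topologies = {}
    for name, stanza in raw.items():
        topologies[name] = LipidTopology(
            species_name=name,
            head_atoms=list(stanza["head_atoms"]),
            tail_atoms=[list(c) for c in stanza["tail_atoms"]],
            p_atom=stanza["p_atom"],
            c2_atom=stanza["c2_atom"],
            terminal_atoms=list(stanza["terminal_atoms"]),
            c1_atom=stanza.get("c1_atom"),
            vdw_radii=dict(stanza.get("vdw_radii", {})),
            masses=dict(stanza.get("masses", {})),
        )
    return topologies


# --------------------------------------------------------------------------
# frames


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box (broadcasts)."""
    return delta - box * np.round(delta / box)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary image [0, L) per axis."""
    return np.mod(coords, box)


@dataclass
class FrameSeries:
    """Time-ordered coordinate frames of a lipid assembly.

    coords: (n_frames, n_atoms, 3) Å; box: (n_frames, 3) Å; dt in ns;
    labels are parallel per-atom arrays.  Frames must share atom count and
    label order.
    """

    coords: np.ndarray
    box: np.ndarray
    dt: float
    lipid_ids: np.ndarray  # (n_atoms,) int
    species: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray  # (n_atoms,) str
    temperature: float = 303.15  # K

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] == 0:
            raise ValueError("frame count 0")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box dimensions must be strictly positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.coords.shape[1]
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        for arr, what in (
            (self.lipid_ids, "lipid_ids"),
            (self.species, "species"),
            (self.atom_names, "atom_names"),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{what} must have shape (n_atoms,)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def unique_lipids(self) -> np.ndarray:
        """Lipid ids in first-appearance order."""
        _, idx = np.unique(self.lipid_ids, return_index=True)
        return self.lipid_ids[np.sort(idx)]

    def atom_index(self, lipid_id: int, atom_name: str) -> int:
        mask = (self.lipid_ids == lipid_id) & (self.atom_names == atom_name)
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise TopologyError(
                f"lipid {lipid_id}: reference atom {atom_name!r} not present"
            )
        return int(hits[0])

    def lipid_species(self, lipid_id: int) -> str:
        return str(self.species[np.flatnonzero(self.lipid_ids == lipid_id)[0]])

    def wrapped(self) -> "FrameSeries":
        """Copy with coordinates wrapped into the primary box image."""
        coords = wrap_coordinates(self.coords, self.box[:, None, :])
        return FrameSeries(
            coords, self.box.copy(), self.dt,
            self.lipid_ids.copy(), self.species.copy(), self.atom_names.copy(),
            self.temperature,
        )


@dataclass
class LeafletAssignment:
    """Map lipid_id → leaflet label ('upper' / 'lower'), with a log of
    lipids whose head crossed the fixed midplane during the window."""

    leaflet: dict[int, str]
    midplane_z: float
    crossings: list[int] = field(default_factory=list)

    def lipids(self, label: str) -> list[int]:
        return [lid for lid, leaf in self.leaflet.items() if leaf == label]

    def swapped(self) -> "LeafletAssignment":
        flip = {"upper": "lower", "lower": "upper"}
        return LeafletAssignment(
            {lid: flip[leaf] for lid, leaf in self.leaflet.items()},
            self.midplane_z, list(self.crossings),
        )


# --------------------------------------------------------------------------
# reference points and leaflets


def _pair_midpoint(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Midpoint of two atom positions across frames, minimum-image safe."""
    return a + 0.5 * minimum_image(b - a, box)


def reference_points(
    frames: FrameSeries, topologies: dict[str, LipidTopology]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-lipid head and tail points for every frame.

    Head point: midpoint of the P (or sterol surrogate) and C2 atoms.
    Tail point: midpoint of the terminal carbon of each chain.  Returns
    ``(lipid_ids, heads, tails)`` with point arrays of shape
    (n_frames, n_lipids, 3) in Å, in ``lipid_ids`` order.
    """
    lids = frames.unique_lipids
    heads = np.empty((frames.n_frames, lids.size, 3))
    tails = np.empty_like(heads)
    box = frames.box[:, None, :]
    for j, lid in enumerate(lids):
        sp = frames.lipid_species(lid)
        if sp not in topologies:
            raise TopologyError(f"no topology declared for species {sp!r}")
        topo = topologies[sp]
        ip = frames.atom_index(lid, topo.p_atom)
        ic2 = frames.atom_index(lid, topo.c2_atom)
        heads[:, j, :] = _pair_midpoint(
            frames.coords[:, ip, :], frames.coords[:, ic2, :], frames.box
        )
        term = [frames.atom_index(lid, t) for t in topo.terminal_atoms]
        ref = frames.coords[:, term[0], :]
        acc = np.zeros_like(ref)
        for it in term:
            acc += minimum_image(frames.coords[:, it, :] - ref, frames.box)
        tails[:, j, :] = ref + acc / len(term)
    # wrap the derived points back into the primary image
    heads = wrap_coordinates(heads, box)
    tails = wrap_coordinates(tails, box)
    return lids, heads, tails


def assign_leaflets(
    frames: FrameSeries, topologies: dict[str, LipidTopology]
) -> LeafletAssignment:
    """Partition lipids into leaflets by head-point z relative to the
    bilayer midplane of the first analyzed frame.

    The midplane is held fixed across the window; a lipid whose head later
    crosses it is flagged in ``crossings`` but not reassigned (flip-flop is
    not analyzed here).
    """
    lids, heads, _ = reference_points(frames, topologies)
    if lids.size < 2:
        raise ValueError("leaflet assignment needs at least 2 lipids")
    z0 = heads[0, :, 2]
    midplane = float(np.mean(z0))
    upper = z0 > midplane
    if np.all(upper) or np.all(~upper):
        raise MonolayerError("monolayer input: all lipid heads on one side of the midplane")
    leaflet = {
        int(lid): ("upper" if up else "lower") for lid, up in zip(lids, upper)
    }
    crossings = [
        int(lid)
        for j, lid in enumerate(lids)
        if np.any((heads[:, j, 2] > midplane) != upper[j])
    ]
    return LeafletAssignment(leaflet, midplane, crossings)


# --------------------------------------------------------------------------
# native format


NATIVE_HEADER = "# membramech native frames v1"


def write_native_frames(frames: FrameSeries, path) -> None:
    """Write the plain-text native frame format.

    Layout::

        # membramech native frames v1
        natoms <n> dt <ns> temperature <K>
        frame <index>
        box <Lx> <Ly> <Lz>
        <lipid_id> <species> <atom_name> <x> <y> <z>   (one line per atom, Å)
        frame <index+1>
        ...
    """
    with open(path, "w") as fh:
        fh.write(NATIVE_HEADER + "\n")
        fh.write(
            f"natoms {frames.n_atoms} dt {frames.dt:.10g} "
            f"temperature {frames.temperature:.10g}\n"
        )
        for f in range(frames.n_frames):
            fh.write(f"frame {f}\n")
            fh.write("box " + " ".join(format(float(v), ".10g") for v in frames.box[f]) + "\n")
            for i in range(frames.n_atoms):
                x, y, z = frames.coords[f, i]
                fh.write(
                    f"{frames.lipid_ids[i]} {frames.species[i]} "
                    f"{frames.atom_names[i]} {x:.10g} {y:.10g} {z:.10g}\n"
                )


def _read_native(path, temperature=None, dt=None) -> FrameSeries:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty native frame file")
    meta = lines[0].split()
    natoms = int(meta[meta.index("natoms") + 1])
    dt_file = float(meta[meta.index("dt") + 1])
    temp_file = float(meta[meta.index("temperature") + 1])
    frames_coords, boxes = [], []
    lipid_ids, species, atom_names = [], [], []
    i = 1
    first = True
    while i < len(lines):
        if not lines[i].startswith("frame"):
            raise ValueError(f"{path}: expected 'frame' record, got {lines[i]!r}")
        box = np.array([float(v) for v in lines[i + 1].split()[1:4]])
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            if first:
                lipid_ids.append(int(parts[0]))
                species.append(parts[1])
                atom_names.append(parts[2])
            coords[k] = [float(v) for v in parts[3:6]]
        frames_coords.append(coords)
        boxes.append(box)
        first = False
        i += 2 + natoms
    return FrameSeries(
        np.array(frames_coords), np.array(boxes),
        dt if dt is not None else dt_file,
        np.array(lipid_ids), np.array(species, dtype=object),
        np.array(atom_names, dtype=object),
        temperature if temperature is not None else temp_file,
    )


# --------------------------------------------------------------------------
# standard-format readers (MDAnalysis-backed)


def _read_mdanalysis(path, fmt, dt, temperature) -> FrameSeries:
    import MDAnalysis as mda

    u = mda.Universe(str(path), format=fmt, to_guess=())
    coords, boxes = [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            boxes.append(ts.dimensions[:3].astype(float).copy())
        else:
            boxes.append(None)
    if any(b is None for b in boxes):
        raise ValueError(f"{path}: no box dimensions found in file")
    return FrameSeries(
        np.array(coords), np.array(boxes), dt,
        np.asarray(u.atoms.resids, dtype=int),
        np.asarray(u.atoms.resnames, dtype=object),
        np.asarray(u.atoms.names, dtype=object),
        temperature,
    )


def _read_xyz(path, topologies, dt, temperature) -> FrameSeries:
    """Multi-frame XYZ with the box on the comment line ('box Lx Ly Lz').

    XYZ carries no residue information, so lipids are recovered by greedily
    matching consecutive atom names against each species' declared atom
    order."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    coords_frames, boxes = [], []
    names = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        comment = lines[i + 1].split()
        if "box" not in comment:
            raise ValueError(f"{path}: XYZ comment line must carry 'box Lx Ly Lz'")
        j = comment.index("box")
        boxes.append([float(v) for v in comment[j + 1 : j + 4]])
        frame_names, coords = [], []
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            frame_names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = frame_names
        coords_frames.append(coords)
        i += 2 + natoms
    # greedy species matching
    lipid_ids, species = [], []
    pos, lid = 0, 0
    while pos < len(names):
        for sp, topo in topologies.items():
            k = topo.n_atoms
            if names[pos : pos + k] == topo.all_atoms:
                lipid_ids += [lid] * k
                species += [sp] * k
                pos += k
                lid += 1
                break
        else:
            raise TopologyError(
                f"{path}: atom run starting with {names[pos]!r} at index {pos} "
                "matches no declared topology"
            )
    return FrameSeries(
        np.array(coords_frames, dtype=float), np.array(boxes, dtype=float), dt,
        np.array(lipid_ids), np.array(species, dtype=object),
        np.array(names, dtype=object), temperature,
    )


def load_frames(
    path,
    topologies: dict[str, LipidTopology],
    format: str = "native",
    dt: float = 1.0,
    temperature: float = 303.15,
) -> FrameSeries:
    """Load a coordinate frame series and resolve labels against topologies.

    ``format`` is one of ``native``, ``pdb``, ``gro``, ``xyz``.  Coordinates
    are wrapped into the primary box image.  Every residue/species name must
    map to a declared topology and every atom name must be declared for its
    species; offenders are named in the raised error.
    """
    if format == "native":
        frames = _read_native(path)
    elif format in ("pdb", "gro"):
        frames = _read_mdanalysis(path, format.upper(), dt, temperature)
    elif format == "xyz":
        frames = _read_xyz(path, topologies, dt, temperature)
    else:
        raise ValueError(f"unknown format {format!r}")
    # validate labels
    for sp in np.unique(np.asarray(frames.species, dtype=str)):
        if sp not in topologies:
            raise TopologyError(f"residue {sp!r} is absent from the declared topologies")
    declared = {sp: set(t.all_atoms) for sp, t in topologies.items()}
    for sp, name in zip(frames.species, frames.atom_names):
        if name not in declared[sp]:
            raise TopologyError(f"atom {name!r} is not declared for species {sp!r}")
    return frames.wrapped()
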