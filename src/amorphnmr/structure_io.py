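"""Periodic snapshot I/O and geometry primitives.

This module defines the in-memory model shared by the whole package: a
periodic :class:`UnitCell`, labelled :class:`AtomRecord` entries grouped into
molecules, and :class:`Snapshot` objects holding one frame of an amorphous
cell.  It reads and writes extended XYZ (``Lattice=`` + ``Properties=``
header) and PDB (``CRYST1``), and provides the minimum-image displacement
used by every distance criterion downstream.

All coordinates are Cartesian angstroms internally; fractional coordinates
appear only inside the minimum-image computation and at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
import yaml

__all__ = [
    "UnitCell",
    "AtomRecord",
    "Snapshot",
    "TopologySpec",
    "minimum_image_displacement",
    "mic_displacements",
    "read_snapshot",
    "write_snapshot",
    "infer_molecules",
]

_KNOWN_ELEMENTS = {"C", "H", "N", "O", "S"}

# Covalent-bond search cutoffs used when assigning molecule membership.
# Any pair involving hydrogen must be a genuine covalent bond (<= ~1.1 A);
# the 1.25 A ceiling keeps intermolecular H-bond contacts (>= ~1.6 A) out.
_H_BOND_CUTOFF = 1.25
_HEAVY_BOND_CUTOFF = 2.75


@dataclass(frozen=True)
class UnitCell:
    """Periodic cell given by row-wise lattice vectors a, b, c in angstrom."""

    lattice: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lattice, dtype=float)
        if lat.shape != (3, 3):
            raise ValueError("lattice must be a 3x3 matrix of row vectors")
        if not np.all(np.isfinite(lat)):
            raise ValueError("lattice vectors must be finite")
        object.__setattr__(self, "lattice", lat)
        if self.volume <= 0.0:
            raise ValueError("cell volume must be positive (right-handed, non-degenerate)")

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.lattice))

    @property
    def widths(self) -> np.ndarray:
        """Perpendicular width along each lattice direction (V / face area)."""
        lat = self.lattice
        cross = np.stack(
            [
                np.cross(lat[1], lat[2]),
                np.cross(lat[2], lat[0]),
                np.cross(lat[0], lat[1]),
            ]
        )
        return np.abs(self.volume) / np.linalg.norm(cross, axis=1)

    def supports_cutoff(self, cutoff: float) -> bool:
        """True when the minimum-image convention is valid at this cutoff."""
        periodic = np.asarray(self.periodic)
        if not periodic.any():
            return True
        return bool(np.all(self.widths[periodic] > 2.0 * cutoff))

    def require_cutoff(self, cutoff: float) -> None:
        if not self.supports_cutoff(cutoff):
            raise ValueError(
                f"cell too small for the minimum-image convention at cutoff {cutoff} A "
                f"(perpendicular widths {np.round(self.widths, 3)})"
            )

    def fractional(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ np.linalg.inv(self.lattice)

    def cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.lattice

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        """Cell lengths (A) and angles (deg) in the a, b, c, alpha, beta, gamma order."""
        a, b, c = (np.linalg.norm(v) for v in self.lattice)

        def _angle(u: np.ndarray, v: np.ndarray) -> float:
            cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

        alpha = _angle(self.lattice[1], self.lattice[2])
        beta = _angle(self.lattice[0], self.lattice[2])
        gamma = _angle(self.lattice[0], self.lattice[1])
        return float(a), float(b), float(c), alpha, beta, gamma

    @classmethod
    def from_parameters(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "UnitCell":
        """Build the standard-orientation lattice from lengths and angles."""
        cell = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
        orth = np.array(cell.orth.mat.tolist(), dtype=float)
        return cls(lattice=orth.T.copy())

    @classmethod
    def cubic(cls, edge: float) -> "UnitCell":
        return cls(lattice=np.eye(3) * float(edge))


@dataclass
class AtomRecord:
    """One atom: element, structural site label, molecule membership, position."""

    atom_id: int
    element: str
    site_label: str
    molecule_id: int
    molecule_kind: str  # "API" or "water"
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite position")
        if self.molecule_id < 0:
            raise ValueError(f"atom {self.atom_id}: molecule_id must be non-negative")


@dataclass
class Snapshot:
    """One periodic frame: a cell plus an ordered list of labelled atoms."""

    cell: UnitCell
    atoms: list[AtomRecord]
    time_ps: float = 0.0
    source_tag: str = ""

    def __post_init__(self) -> None:
        self._positions: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None or len(self._positions) != len(self.atoms):
            self._positions = np.array([a.position for a in self.atoms], dtype=float)
        return self._positions

    def invalidate_cache(self) -> None:
        self._positions = None

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms], dtype=int)

    def molecules(self) -> dict[int, list[int]]:
        """Map molecule_id -> atom indices (in file order)."""
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.molecule_id, []).append(i)
        return out

    def site_index(self) -> dict[int, dict[str, int]]:
        """Per molecule: site label -> atom index.  Labels are unique per molecule."""
        out: dict[int, dict[str, int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.molecule_id, {})[a.site_label] = i
        return out


@dataclass
class TopologySpec:
    """Site-level topology: donor N-H pairs, acceptor labels and covalent bonds.

    ``acceptors`` lists the non-water acceptor site labels (carbonyl oxygens,
    ring nitrogen); the water oxygen label is always treated as an acceptor as
    well.  ``covalent_bonds`` drives molecule-membership inference.
    """

    donors: list[tuple[str, str]]
    acceptors: list[str]
    covalent_bonds: list[tuple[str, str]]
    water_oxygen: str = "OW"
    water_hydrogens: tuple[str, str] = ("HW1", "HW2")
    element_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bondset = {frozenset(b) for b in self.covalent_bonds}
        for n_label, h_label in self.donors:
            if frozenset((n_label, h_label)) not in bondset:
                raise ValueError(
                    f"donor H {h_label!r} is not covalently bonded to its donor N {n_label!r}"
                )
        for lab in self.acceptors:
            el = self.element_of.get(lab, lab[0].upper())
            if el not in ("O", "N"):
                raise ValueError(f"acceptor {lab!r} must be an O or N site (got {el})")

    @property
    def acceptor_labels(self) -> set[str]:
        return set(self.acceptors) | {self.water_oxygen}

    @property
    def donor_h_labels(self) -> set[str]:
        return {h for _, h in self.donors}

    def known_labels(self) -> set[str]:
        labels = {self.water_oxygen, *self.water_hydrogens}
        labels.update(self.acceptors)
        for n, h in self.donors:
            labels.update((n, h))
        for a, b in self.covalent_bonds:
            labels.update((a, b))
        return labels

    def to_yaml(self, path) -> None:
        payload = {
            "donors": [list(d) for d in self.donors],
            "acceptors": list(self.acceptors),
            "bonds": [list(b) for b in self.covalent_bonds],
            "water_oxygen": self.water_oxygen,
            "water_hydrogens": list(self.water_hydrogens),
        }
        if self.element_of:
            payload["elements"] = dict(self.element_of)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TopologySpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            donors=[tuple(d) for d in payload["donors"]],
            acceptors=list(payload["acceptors"]),
            covalent_bonds=[tuple(b) for b in payload["bonds"]],
            water_oxygen=payload.get("water_oxygen", "OW"),
            water_hydrogens=tuple(payload.get("water_hydrogens", ("HW1", "HW2"))),
            element_of=dict(payload.get("elements", {})),
        )


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def mic_displacements(cell: UnitCell, dvec: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for raw Cartesian difference vectors.

    Uses fractional rounding, which returns the true nearest image whenever
    that image is closer than half the smallest perpendicular cell width —
    guaranteed for every analysis cutoff via :meth:`UnitCell.require_cutoff`.
    """
    dvec = np.asarray(dvec, dtype=float)
    frac = dvec @ np.linalg.inv(cell.lattice)
    periodic = np.asarray(cell.periodic)
    frac = np.where(periodic, frac - np.round(frac), frac)
    return frac @ cell.lattice


def minimum_image_displacement(
    cell: UnitCell, r_from: np.ndarray, r_to: np.ndarray
) -> np.ndarray:
    """Displacement from ``r_from`` to the nearest periodic image of ``r_to``.

    After fractional rounding the 27 adjacent image candidates are scanned,
    so the result is the exact nearest image even for skewed cells and for
    separations beyond half the cell width.
    """
    d = np.asarray(r_to, dtype=float) - np.asarray(r_from, dtype=float)
    base = mic_displacements(cell, d)
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
        dtype=float,
    )
    mask = np.asarray(cell.periodic, dtype=float)
    cands = base + (shifts * mask) @ cell.lattice
    return cands[np.argmin(np.linalg.norm(cands, axis=1))]


# ---------------------------------------------------------------------------
# molecule inference
# ---------------------------------------------------------------------------


def infer_molecules(
    atoms: list[AtomRecord], cell: UnitCell, topology: TopologySpec
) -> None:
    """Assign molecule_id / molecule_kind by covalent-bond connected components.

    Bonds are instantiated geometrically: for every covalent label pair in the
    topology, each atom is linked to its nearest partner of the matching label
    within a covalent cutoff.  Nearest-partner matching keeps intermolecular
    hydrogen-bond contacts from merging molecules.  Components whose label
    multiset is {water O, 2 water H} become water molecules and must have
    exactly three atoms.
    """
    known = topology.known_labels()
    for a in atoms:
        if a.site_label not in known:
            raise ValueError(
                f"atom {a.atom_id} has site label {a.site_label!r} not resolvable "
                "against the topology"
            )
    positions = np.array([a.position for a in atoms], dtype=float)
    by_label: dict[str, np.ndarray] = {}
    for i, a in enumerate(atoms):
        by_label.setdefault(a.site_label, []).append(i)  # type: ignore[arg-type]
    by_label = {k: np.asarray(v, dtype=int) for k, v in by_label.items()}

    graph = nx.Graph()
    graph.add_nodes_from(range(len(atoms)))
    for la, lb in topology.covalent_bonds:
        ia = by_label.get(la)
        ib = by_label.get(lb)
        if ia is None or ib is None or la == lb:
            continue
        h_involved = atoms[ia[0]].element == "H" or atoms[ib[0]].element == "H"
        cutoff = _H_BOND_CUTOFF if h_involved else _HEAVY_BOND_CUTOFF
        disp = mic_displacements(
            cell, positions[ib][None, :, :] - positions[ia][:, None, :]
        )
        dist = np.linalg.norm(disp, axis=-1)
        # link each atom to its nearest partner of the complementary label
        for row, j_near in enumerate(np.argmin(dist, axis=1)):
            if dist[row, j_near] < cutoff:
                graph.add_edge(int(ia[row]), int(ib[j_near]))
        for col, i_near in enumerate(np.argmin(dist, axis=0)):
            if dist[i_near, col] < cutoff:
                graph.add_edge(int(ia[i_near]), int(ib[col]))

    components = sorted(nx.connected_components(graph), key=min)
    water_labels = {topology.water_oxygen: 1, topology.water_hydrogens[0]: 1,
                    topology.water_hydrogens[1]: 1}
    for mol_id, comp in enumerate(components):
        labels = sorted(atoms[i].site_label for i in comp)
        is_water = sorted(water_labels) == labels
        if topology.water_oxygen in labels and not is_water:
            raise ValueError(
                f"molecule {mol_id}: water oxygen present but component is not "
                f"an O + 2H water (labels {labels})"
            )
        kind = "water" if is_water else "API"
        for i in comp:
            atoms[i].molecule_id = mol_id
            atoms[i].molecule_kind = kind


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KEYVAL_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _write_extxyz(snapshot: Snapshot, path) -> None:
    lat = " ".join(f"{x:.10f}" for x in snapshot.cell.lattice.reshape(-1))
    props = "species:S:1:pos:R:3:site_label:S:1"
    pbc = " ".join("T" if p else "F" for p in snapshot.cell.periodic)
    comment = (
        f'Lattice="{lat}" Properties={props} pbc="{pbc}" '
        f"Time={snapshot.time_ps:.6f}"
    )
    if snapshot.source_tag:
        comment += f' source_tag="{snapshot.source_tag}"'
    lines = [str(snapshot.n_atoms), comment]
    for a in snapshot.atoms:
        x, y, z = a.position
        lines.append(
            f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f} {a.site_label}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_extxyz(path, topology: TopologySpec) -> Snapshot:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated extended-XYZ file")
    n_atoms = int(lines[0].split()[0])
    comment = lines[1]
    m = _LATTICE_RE.search(comment)
    if m is None:
        raise ValueError(f"{path}: no cell (missing Lattice= record)")
    lat = np.array([float(x) for x in m.group(1).split()], dtype=float).reshape(3, 3)
    keyvals = {k: (quoted if quoted else bare) for k, quoted, bare in _KEYVAL_RE.findall(comment)}
    pbc = tuple(tok.upper().startswith("T") for tok in keyvals.get("pbc", "T T T").split()) \
        if "pbc" in keyvals else (True, True, True)
    if len(pbc) != 3:
        pbc = (True, True, True)
    time_ps = float(keyvals.get("Time", 0.0))
    source_tag = keyvals.get("source_tag", "")
    cell = UnitCell(lattice=lat, periodic=pbc)  # type: ignore[arg-type]
    atoms: list[AtomRecord] = []
    for i, line in enumerate(lines[2 : 2 + n_atoms]):
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}: atom line {i} lacks a site_label column")
        el, x, y, z, label = parts[0], *parts[1:4], parts[4]
        atoms.append(
            AtomRecord(
                atom_id=i,
                element=el,
                site_label=label,
                molecule_id=0,
                molecule_kind="API",
                position=np.array([float(x), float(y), float(z)]),
            )
        )
    if len(atoms) != n_atoms:
        raise ValueError(f"{path}: expected {n_atoms} atoms, found {len(atoms)}")
    infer_molecules(atoms, cell, topology)
    return Snapshot(cell=cell, atoms=atoms, time_ps=time_ps, source_tag=source_tag)


# ---------------------------------------------------------------------------
# PDB (via gemmi)
# ---------------------------------------------------------------------------


def _write_pdb(snapshot: Snapshot, path) -> None:
    st = gemmi.Structure()
    st.name = snapshot.source_tag or "snapshot"
    a, b, c, al, be, ga = snapshot.cell.parameters()
    st.cell = gemmi.UnitCell(a, b, c, al, be, ga)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for mol_id, idxs in sorted(snapshot.molecules().items()):
        res = gemmi.Residue()
        res.name = "HOH" if snapshot.atoms[idxs[0]].molecule_kind == "water" else "API"
        res.seqid = gemmi.SeqId(mol_id + 1, " ")
        for i in idxs:
            at = snapshot.atoms[i]
            atom = gemmi.Atom()
            # PDB atom names are at most 4 characters; drop underscores
            atom.name = at.site_label.replace("_", "")[:4]
            atom.element = gemmi.Element(at.element)
            atom.pos = gemmi.Position(*at.position)
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def _read_pdb(path, topology: TopologySpec) -> Snapshot:
    st = gemmi.read_pdb(str(path))
    cellp = st.cell
    if cellp.a <= 1.0 or cellp.volume <= 1.5:
        raise ValueError(f"{path}: no cell (missing or dummy CRYST1 record)")
    cell = UnitCell.from_parameters(cellp.a, cellp.b, cellp.c, cellp.alpha, cellp.beta, cellp.gamma)
    # PDB atom names lose underscores (4-char field); map back to topology labels
    name_map = {lab.replace("_", "")[:4]: lab for lab in topology.known_labels()}
    atoms: list[AtomRecord] = []
    i = 0
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    atoms.append(
                        AtomRecord(
                            atom_id=i,
                            element=at.element.name,
                            site_label=name_map.get(at.name, at.name),
                            molecule_id=0,
                            molecule_kind="API",
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        )
                    )
                    i += 1
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no atoms")
    infer_molecules(atoms, cell, topology)
    return Snapshot(cell=cell, atoms=atoms)


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------


def read_snapshot(path, fmt: str, topology: TopologySpec) -> Snapshot:
    """Read one periodic snapshot; molecule membership is inferred from bonds."""
    if fmt == "extxyz":
        return _read_extxyz(path, topology)
    if fmt == "pdb":
        return _read_pdb(path, topology)
    raise ValueError(f"unknown snapshot format {fmt!r}")


def write_snapshot(snapshot: Snapshot, path, fmt: str) -> None:
    if snapshot.n_atoms == 0:
        raise ValueError("refusing to write an empty snapshot")
    if fmt == "extxyz":
        _write_extxyz(snapshot, path)
    elif fmt == "pdb":
        _write_pdb(snapshot, path)
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")
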