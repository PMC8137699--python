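"""Synthetic amorphous ensembles with planted, recoverable ground truth.

Real inputs to this pipeline come from molecular dynamics of hydrated
amorphous cells (128 drug molecules plus 0-132 waters), a machine-learned
shielding model and semi-empirical single-point energies.  This module
replaces all three with controllable surrogates:

* :func:`generate_cell` / :func:`generate_trajectory` build periodic cells in
  which every donor group's hydrogen-bond motif is drawn from a target
  probability table and then realized geometrically (acceptor placed at
  1.8-2.3 A from the donor H, near-linear angle, water bridges and secondary
  neighbours included), so the downstream census recovers the planted
  fractions to binomial accuracy.
* :class:`SurrogateShiftModel` maps each donor proton's bonding geometry to a
  1H shift with a known linear law (water acceptors most deshielding).
* :class:`SurrogateEnergyBackend` is a deterministic, size-consistent
  pairwise Morse-well potential whose well depths plant a known energetic
  ordering (water acceptors most favourable).

The drug-molecule surrogate is a rigid ten-site proxy carrying the labelled
donor/acceptor sites (N6-H, N21-H, N28-H, O20, O29, ring N5); the pipeline
consumes labels and positions only, so no chemical realism is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .hbond_motifs import NO_ACCEPTOR, WATER_ACCEPTOR, HBondCriteria, assign_motifs
from .shift_spectra import ShiftRecord
from .structure_io import AtomRecord, Snapshot, TopologySpec, UnitCell, mic_displacements

__all__ = [
    "EnsembleSpec",
    "EnsembleSummary",
    "SurrogateShiftModel",
    "SurrogateEnergyBackend",
    "PlantedMotif",
    "SyntheticTrajectory",
    "default_topology",
    "default_targets",
    "generate_cell",
    "generate_snapshot",
    "generate_trajectory",
    "surrogate_shifts",
    "ensemble_accounting",
    "snapshot_schedule",
]

# ---------------------------------------------------------------------------
# rigid site templates
# ---------------------------------------------------------------------------

_S3 = math.sqrt(3.0) / 2.0
# site -> (element, position); donor N's at 1.9 A from the hub, their H 1 A
# further out, acceptors at 2.5 A.  Keeping every non-acceptor heavy atom
# strictly inside the acceptor radius guarantees that a partner molecule
# approached through one of its acceptors presents no closer heavy atom to
# the donor proton.
API_TEMPLATE: dict[str, tuple[str, np.ndarray]] = {
    "C1": ("C", np.zeros(3)),
    "N6": ("N", np.array([1.9, 0.0, 0.0])),
    "H_N6": ("H", np.array([2.9, 0.0, 0.0])),
    "N21": ("N", 1.9 * np.array([-0.5, _S3, 0.0])),
    "H_N21": ("H", 2.9 * np.array([-0.5, _S3, 0.0])),
    "N28": ("N", 1.9 * np.array([-0.5, -_S3, 0.0])),
    "H_N28": ("H", 2.9 * np.array([-0.5, -_S3, 0.0])),
    # acceptors at 2.4 A from the hub; O20 and O29 are 156.4 deg apart so
    # their separation (4.70 A) matches the two water-H target positions of
    # the same-molecule double-acceptor bridge geometry
    "O20": ("O", 2.4 * np.array([0.0, 0.0, 1.0])),
    "O29": ("O", 2.4 * np.array([math.sin(math.radians(156.4)), 0.0,
                                 math.cos(math.radians(156.4))])),
    "N5": ("N", 2.4 * np.array([-math.sin(math.radians(156.4)), 0.0,
                                math.cos(math.radians(156.4))])),
}
_PAIR_SEPARATION = float(
    np.linalg.norm(API_TEMPLATE["O20"][1] - API_TEMPLATE["O29"][1])
)

_WATER_OH = 0.9572
_WATER_ANGLE_DEG = 104.52

DONOR_SITES = ("N6", "N21", "N28")
ACCEPTOR_SITES = ("O20", "O29", "N5")


def default_topology() -> TopologySpec:
    """Topology of the ten-site drug surrogate plus water."""
    bonds = [("C1", s) for s in ("N6", "N21", "N28", "O20", "O29", "N5")]
    bonds += [("N6", "H_N6"), ("N21", "H_N21"), ("N28", "H_N28")]
    bonds += [("OW", "HW1"), ("OW", "HW2")]
    return TopologySpec(
        donors=[("N6", "H_N6"), ("N21", "H_N21"), ("N28", "H_N28")],
        acceptors=list(ACCEPTOR_SITES),
        covalent_bonds=bonds,
        water_oxygen="OW",
        water_hydrogens=("HW1", "HW2"),
    )


# ---------------------------------------------------------------------------
# specs and bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Composition and snapshot schedule of the amorphous MD ensemble.

    Defaults mirror the study conditions: five cells each of 0, 0.5, 1.0 and
    2.0% w/w water (0/16/32/65 waters beside 128 drug molecules) plus two
    cells of 4% (132 waters), sampled as 1001 snapshots over the final
    100 ns at 100 ps spacing.
    """

    n_api_per_cell: int = 128
    water_counts: list[int] = field(default_factory=lambda: [0, 16, 32, 65, 132])
    cells_per_content: list[int] = field(default_factory=lambda: [5, 5, 5, 5, 2])
    nominal_content_pct: list[float] = field(
        default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 4.0]
    )
    snapshot_window_ns: float = 100.0
    snapshot_spacing_ps: float = 100.0
    seed: int = 0
    grid_spacing_ang: float = 12.0
    jitter_ang: float = 0.05

    def __post_init__(self) -> None:
        n = len(self.water_counts)
        if not (len(self.cells_per_content) == len(self.nominal_content_pct) == n):
            raise ValueError("water_counts, cells_per_content, nominal_content_pct "
                             "must have equal lengths")
        if any(c < 0 for c in self.water_counts) or any(
            c < 0 for c in self.cells_per_content
        ):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_content))


@dataclass
class EnsembleSummary:
    """Composition bookkeeping derived from an :class:`EnsembleSpec`."""

    n_cells: int
    avg_content_pct: float
    api_water_ratio: float
    ratio_infinite: bool
    snapshots_per_trajectory: int
    total_api_molecules_per_frame_set: dict[float, int]
    total_water_molecules_per_frame_set: dict[float, int]
    snapshots_per_content: dict[float, int]


def snapshot_schedule(window_ns: float, spacing_ps: float) -> int:
    """Number of evenly spaced snapshots over a window, endpoints inclusive."""
    if spacing_ps <= 0:
        raise ValueError("spacing must be positive")
    window_ps = window_ns * 1000.0
    if window_ps == 0:
        return 1
    ratio = window_ps / spacing_ps
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"spacing {spacing_ps} ps does not divide the {window_ns} ns window"
        )
    return int(round(ratio)) + 1


def ensemble_accounting(spec: EnsembleSpec) -> EnsembleSummary:
    """Average water content, drug:water ratio and snapshot totals.

    The average content is the unweighted mean of the nominal per-cell
    percentages over all cells; the molecule ratio is total drug molecules
    over total waters across the ensemble.
    """
    cells = np.asarray(spec.cells_per_content, dtype=float)
    pct = np.asarray(spec.nominal_content_pct, dtype=float)
    waters = np.asarray(spec.water_counts, dtype=float)
    n_cells = int(cells.sum())
    if n_cells == 0:
        raise ValueError("spec contains no cells")
    avg_pct = float((cells * pct).sum() / n_cells)
    total_api = n_cells * spec.n_api_per_cell
    total_water = float((cells * waters).sum())
    if total_water == 0:
        ratio, infinite = float("inf"), True
    else:
        ratio, infinite = total_api / total_water, False
    per_traj = snapshot_schedule(spec.snapshot_window_ns, spec.snapshot_spacing_ps)
    api_tot = {float(p): int(c) * per_traj * spec.n_api_per_cell
               for p, c in zip(pct, cells)}
    water_tot = {float(p): int(c) * per_traj * int(w)
                 for p, c, w in zip(pct, cells, waters)}
    snaps = {float(p): int(c) * per_traj for p, c in zip(pct, cells)}
    return EnsembleSummary(
        n_cells=n_cells,
        avg_content_pct=avg_pct,
        api_water_ratio=ratio,
        ratio_infinite=infinite,
        snapshots_per_trajectory=per_traj,
        total_api_molecules_per_frame_set=api_tot,
        total_water_molecules_per_frame_set=water_tot,
        snapshots_per_content=snaps,
    )


def molecule_totals(
    spec: EnsembleSpec, content_pct: float, n_snapshots: int
) -> tuple[int, int]:
    """Drug and water molecule totals over an n-snapshot subset of one content."""
    idx = spec.nominal_content_pct.index(content_pct)
    return (
        n_snapshots * spec.n_api_per_cell,
        n_snapshots * spec.water_counts[idx],
    )


# ---------------------------------------------------------------------------
# motif targets
# ---------------------------------------------------------------------------


def default_targets(n_waters: int, n_api: int) -> dict[str, dict[str, float]]:
    """Per-donor motif probabilities used when the caller supplies none.

    The water-bonding probability scales with the cell's water count, so the
    population of deshielded donor protons grows with hydration; the
    crystal-like N6-H...O20 contact is the most common bonded motif.
    """
    f_w = min(0.30, 0.0022 * n_waters)
    n6 = {
        "N6-H···O20": 0.22,
        "N6-H···O29": 0.08,
        "N6-H···N5": 0.06,
        "N6-H···OH2": 0.50 * f_w,
        "N6-H···OH2···OH2": 0.20 * f_w,
        "N6-H···OH2···O20/OH2": 0.15 * f_w,
        "N6-H···OH2···O20": 0.10 * f_w,
        "N6-H···OH2···O20/O29*": 0.05 * f_w,
    }
    n21 = {
        "N21-H···O29": 0.15,
        "N21-H···O20": 0.10,
        "N21-H···OH2": 0.60 * f_w,
    }
    n28 = {
        "N28-H···O20": 0.12,
        "N28-H···N5": 0.08,
        "N28-H···OH2": 0.60 * f_w,
    }
    return {"N6": n6, "N21": n21, "N28": n28}


def _parse_motif(label: str) -> tuple[str, str, list[str], bool]:
    """Split a canonical motif string into donor, primary, secondaries, star."""
    star = label.endswith("*")
    body = label[:-1] if star else label
    parts = body.split("···")
    donor = parts[0]
    if not donor.endswith("-H"):
        raise ValueError(f"malformed motif label {label!r}")
    donor = donor[:-2]
    primary = parts[1] if len(parts) > 1 else NO_ACCEPTOR
    secondaries = parts[2].split("/") if len(parts) > 2 else []
    return donor, primary, secondaries, star


@dataclass(frozen=True)
class PlantedMotif:
    snapshot_id: int
    molecule_id: int
    donor_site: str
    label: str


class SyntheticTrajectory(NamedTuple):
    snapshots: list[Snapshot]
    planted: list[PlantedMotif]


# ---------------------------------------------------------------------------
# geometric construction
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, math.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= u * np.dot(v, u)
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


class _CellBuilder:
    """Incrementally places molecules while policing unplanned H-bond contacts.

    Every placement is screened against two safety rules before being
    committed: no heavy-atom pair of different molecules below 1.8 A, and no
    unplanned donor-H/acceptor pair inside a guard band (distance < 2.6 A
    with donor angle > 125 deg) slightly wider than the detection criteria.
    Failed placements are retried with fresh random orientations.
    """

    HEAVY_MIN = 1.8
    H_HEAVY_MIN = 1.6  # no unplanned intermolecular H-to-heavy contact below this
    GUARD_DIST = 2.6
    GUARD_ANGLE = 115.0

    def __init__(self, cell: UnitCell, topology: TopologySpec, rng: np.random.Generator):
        self.cell = cell
        self.topology = topology
        self.rng = rng
        self.elements: list[str] = []
        self.labels: list[str] = []
        self.positions: list[np.ndarray] = []
        self.molecule_of: list[int] = []
        self.kinds: list[str] = []  # per molecule
        self.donor_h: list[int] = []  # global indices of donor-capable H atoms
        self.donor_parent: list[int] = []  # matching heavy-atom indices
        self.acceptors: list[int] = []
        self.planned: set[tuple[int, int]] = set()
        self._acc_labels = topology.acceptor_labels
        self._don_h_labels = set(topology.donor_h_labels) | set(topology.water_hydrogens)

    @property
    def n_molecules(self) -> int:
        return len(self.kinds)

    def _screen(
        self,
        new_labels: list[str],
        new_elements: list[str],
        new_pos: np.ndarray,
        new_parent_of_h: dict[int, int],
        planned_local: set[tuple[int, int]],
        exclude_mol: int | None = None,
    ) -> bool:
        """True when the candidate atoms violate no packing/H-bond guard.

        ``exclude_mol`` ignores the current atoms of one molecule, allowing a
        placed molecule to be screened for relocation against everything else.
        """
        old_pos = np.array(self.positions) if self.positions else np.zeros((0, 3))

        def live(i: int) -> bool:
            return exclude_mol is None or self.molecule_of[i] != exclude_mol

        # heavy-atom steric clash against existing molecules
        new_heavy = np.array([i for i, e in enumerate(new_elements) if e != "H"], dtype=int)
        old_heavy = np.array(
            [i for i, e in enumerate(self.elements) if e != "H" and live(i)], dtype=int
        )
        if new_heavy.size and old_heavy.size:
            disp = mic_displacements(
                self.cell, old_pos[old_heavy][None, :, :] - new_pos[new_heavy][:, None, :]
            )
            if (np.linalg.norm(disp, axis=-1) < self.HEAVY_MIN).any():
                return False
        # no intermolecular H-to-heavy contact closer than the planned bonds
        new_hyd = np.array([i for i, e in enumerate(new_elements) if e == "H"], dtype=int)
        old_hyd = np.array(
            [i for i, e in enumerate(self.elements) if e == "H" and live(i)], dtype=int
        )
        for a_idx, a_pos, b_idx, b_pos in (
            (new_hyd, new_pos, old_heavy, old_pos),
            (new_heavy, new_pos, old_hyd, old_pos),
        ):
            if a_idx.size and b_idx.size:
                disp = mic_displacements(
                    self.cell, b_pos[b_idx][None, :, :] - a_pos[a_idx][:, None, :]
                )
                if (np.linalg.norm(disp, axis=-1) < self.H_HEAVY_MIN).any():
                    return False

        def guard(h_pos, parent_pos, acc_pos) -> np.ndarray:
            disp = mic_displacements(self.cell, acc_pos - h_pos)
            dist = np.linalg.norm(disp, axis=-1)
            close = dist < self.GUARD_DIST
            if not close.any():
                return close
            hn = mic_displacements(self.cell, parent_pos - h_pos)
            hn = hn / np.linalg.norm(hn)
            cosang = (disp[close] @ hn) / dist[close]
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            out = np.zeros_like(close)
            out[np.where(close)[0][ang > self.GUARD_ANGLE]] = True
            return out

        n_old = len(self.elements)
        new_h = [i for i, l in enumerate(new_labels) if l in self._don_h_labels]
        new_acc = [i for i, l in enumerate(new_labels) if l in self._acc_labels]
        # new donor H vs existing + new acceptors
        for ih in new_h:
            parent = new_pos[new_parent_of_h[ih]]
            acc_global = [a for a in self.acceptors if live(a)]
            acc_pos = [old_pos[a] for a in acc_global] + [new_pos[a] for a in new_acc]
            acc_keys = [(n_old + ih, a) for a in acc_global] + [
                (n_old + ih, n_old + a) for a in new_acc
            ]
            if not acc_pos:
                continue
            hits = guard(new_pos[ih], parent, np.array(acc_pos))
            for hit, key in zip(hits, acc_keys):
                if hit and key not in self.planned and key not in planned_local:
                    return False
        # existing donor H vs new acceptors
        if new_acc:
            acc_pos = np.array([new_pos[a] for a in new_acc])
            for ih, parent in zip(self.donor_h, self.donor_parent):
                if not live(ih):
                    continue
                hits = guard(old_pos[ih], old_pos[parent], acc_pos)
                for hit, a in zip(hits, new_acc):
                    key = (ih, n_old + a)
                    if hit and key not in self.planned and key not in planned_local:
                        return False
        return True

    def commit(
        self,
        kind: str,
        labels: list[str],
        elements: list[str],
        pos: np.ndarray,
        parent_of_h: dict[int, int],
        planned_local: set[tuple[int, int]],
    ) -> int:
        mol_id = self.n_molecules
        base = len(self.elements)
        for lab, el, p in zip(labels, elements, pos):
            idx = len(self.elements)
            self.labels.append(lab)
            self.elements.append(el)
            self.positions.append(np.asarray(p, dtype=float))
            self.molecule_of.append(mol_id)
            if lab in self._acc_labels:
                self.acceptors.append(idx)
            if lab in self._don_h_labels:
                self.donor_h.append(idx)
                self.donor_parent.append(base + parent_of_h[idx - base])
        self.kinds.append(kind)
        self.planned.update(planned_local)
        return mol_id

    # -- placement primitives ------------------------------------------------

    def api_atoms(self, center: np.ndarray, rot: np.ndarray):
        labels = list(API_TEMPLATE)
        elements = [API_TEMPLATE[l][0] for l in labels]
        pos = np.array([center + rot @ API_TEMPLATE[l][1] for l in labels])
        parent = {labels.index(f"H_{n}"): labels.index(n) for n in DONOR_SITES}
        return labels, elements, pos, parent

    def try_place_api(self, center: np.ndarray, max_tries: int = 40) -> int | None:
        for _ in range(max_tries):
            rot = _random_rotation(self.rng)
            labels, elements, pos, parent = self.api_atoms(center, rot)
            if self._screen(labels, elements, pos, parent, set()):
                return self.commit("API", labels, elements, pos, parent, set())
        return None

    def try_place_api_via_acceptor(
        self,
        acceptor_label: str,
        target: np.ndarray,
        approach: np.ndarray,
        h_index: int,
        max_tries: int = 40,
    ) -> int | None:
        """Place a drug molecule so ``acceptor_label`` sits at ``target``.

        The molecular hub is put beyond the acceptor along the approach
        direction, so no other heavy atom of the partner comes nearer to the
        donor proton than the acceptor itself.
        """
        t_acc = API_TEMPLATE[acceptor_label][1]
        r_acc = float(np.linalg.norm(t_acc))
        u = approach / np.linalg.norm(approach)
        base_rot = _rotation_aligning(t_acc / r_acc, -u)
        for _ in range(max_tries):
            spin = _axis_rotation(u, self.rng.uniform(0.0, 2.0 * math.pi))
            rot = spin @ base_rot
            center = target + r_acc * u
            labels, elements, pos, parent = self.api_atoms(center, rot)
            planned = {(h_index, len(self.elements) + labels.index(acceptor_label))}
            if self._screen(labels, elements, pos, parent, planned):
                return self.commit("API", labels, elements, pos, parent, planned)
        return None

    def try_relocate_api_via_acceptor(
        self,
        bmol: int,
        acceptor_label: str,
        target: np.ndarray,
        approach: np.ndarray,
        h_index: int,
        max_tries: int = 10,
    ) -> bool:
        """Move an already-placed, bond-free drug molecule onto a donor.

        Used when the molecule budget is exhausted: a molecule whose donors
        all realized the no-neighbour motif has no geometry depending on it
        and can safely serve as a hydrogen-bond partner elsewhere.
        """
        idxs = [i for i, m in enumerate(self.molecule_of) if m == bmol]
        tmpl_labels = list(API_TEMPLATE)
        if [self.labels[i] for i in idxs] != tmpl_labels:
            return False
        t_acc = API_TEMPLATE[acceptor_label][1]
        r_acc = float(np.linalg.norm(t_acc))
        u = approach / np.linalg.norm(approach)
        base_rot = _rotation_aligning(t_acc / r_acc, -u)
        n_old = len(self.elements)
        local_acc = tmpl_labels.index(acceptor_label)
        for _ in range(max_tries):
            spin = _axis_rotation(u, self.rng.uniform(0.0, 2.0 * math.pi))
            rot = spin @ base_rot
            center = target + r_acc * u
            labels, elements, pos, parent = self.api_atoms(center, rot)
            planned_local = {(h_index, n_old + local_acc)}
            if self._screen(labels, elements, pos, parent, planned_local, exclude_mol=bmol):
                for local, gi in enumerate(idxs):
                    self.positions[gi] = pos[local]
                self.planned.add((h_index, idxs[local_acc]))
                return True
        return False

    def try_place_api_via_acceptor_pair(
        self,
        labels_pair: tuple[str, str],
        targets: tuple[np.ndarray, np.ndarray],
        h_indices: tuple[int, int],
        away_from: np.ndarray,
        max_tries: int = 60,
    ) -> int | None:
        """Place one drug molecule with two acceptor sites on two targets."""
        ta = API_TEMPLATE[labels_pair[0]][1]
        tb = API_TEMPLATE[labels_pair[1]][1]
        seg_t = tb - ta
        seg_x = targets[1] - targets[0]
        if abs(np.linalg.norm(seg_t) - np.linalg.norm(seg_x)) > 0.2:
            return None
        align = _rotation_aligning(seg_t / np.linalg.norm(seg_t), seg_x / np.linalg.norm(seg_x))
        axis = seg_x / np.linalg.norm(seg_x)
        for _ in range(max_tries):
            rot = _axis_rotation(axis, self.rng.uniform(0.0, 2.0 * math.pi)) @ align
            center = targets[0] - rot @ ta
            # prefer orientations that keep the hub away from the bridge water
            if np.dot(center - away_from, center - away_from) < 4.0:
                continue
            labels, elements, pos, parent = self.api_atoms(center, rot)
            base = len(self.elements)
            planned = {
                (h_indices[0], base + labels.index(labels_pair[0])),
                (h_indices[1], base + labels.index(labels_pair[1])),
            }
            if self._screen(labels, elements, pos, parent, planned):
                return self.commit("API", labels, elements, pos, parent, planned)
        return None

    def water_atoms(self, o_pos: np.ndarray, bisector: np.ndarray, roll_perp: np.ndarray):
        half = math.radians(_WATER_ANGLE_DEG / 2.0)
        b = bisector / np.linalg.norm(bisector)
        d1 = math.cos(half) * b + math.sin(half) * roll_perp
        d2 = math.cos(half) * b - math.sin(half) * roll_perp
        pos = np.array([o_pos, o_pos + _WATER_OH * d1, o_pos + _WATER_OH * d2])
        return ["OW", "HW1", "HW2"], ["O", "H", "H"], pos, {1: 0, 2: 0}, (d1, d2)

    def try_place_water(
        self,
        o_pos: np.ndarray,
        bisector: np.ndarray,
        donor_h_index: int | None,
        max_tries: int = 40,
    ):
        """Place one water; returns (mol_id, O index, H dirs) or None."""
        for _ in range(max_tries):
            perp = _perpendicular(bisector / np.linalg.norm(bisector), self.rng)
            labels, elements, pos, parent, dirs = self.water_atoms(o_pos, bisector, perp)
            base = len(self.elements)
            planned = set()
            if donor_h_index is not None:
                planned.add((donor_h_index, base))  # donor H -> this water's O
            if self._screen(labels, elements, pos, parent, planned):
                mol = self.commit("water", labels, elements, pos, parent, planned)
                return mol, base, dirs
        return None


# ---------------------------------------------------------------------------
# snapshot generation
# ---------------------------------------------------------------------------


def _build_snapshot(
    n_api: int,
    n_water: int,
    targets: dict[str, dict[str, float]],
    spacing: float,
    jitter: float,
    topology: TopologySpec,
    rng: np.random.Generator,
    time_ps: float,
    source_tag: str,
) -> tuple[Snapshot, dict[tuple[int, str], str]]:
    n_side = max(int(math.ceil(n_api ** (1.0 / 3.0))), 2)
    edge = n_side * spacing
    cell = UnitCell.cubic(edge)
    cell.require_cutoff(5.0)
    builder = _CellBuilder(cell, topology, rng)

    slots = np.array(
        [
            (i + 0.5, j + 0.5, k + 0.5)
            for i in range(n_side)
            for j in range(n_side)
            for k in range(n_side)
        ]
    ) * spacing
    rng.shuffle(slots, axis=0)
    slot_iter = iter(range(len(slots)))

    waters_left = n_water
    total_placed = 0
    planted: dict[tuple[int, str], str] = {}
    process_queue: list[int] = []

    def next_slot() -> np.ndarray:
        try:
            return slots[next(slot_iter)] + rng.uniform(-0.5, 0.5, size=3)
        except StopIteration as exc:  # pragma: no cover - sized to fit
            raise RuntimeError("packing failure: grid exhausted") from exc

    def donor_geometry(bmol: int, donor_site: str) -> tuple[int, np.ndarray, np.ndarray]:
        labels = list(API_TEMPLATE)
        base = builder.molecule_of.index(bmol)
        h_idx = base + labels.index(f"H_{donor_site}")
        n_idx = base + labels.index(donor_site)
        h = builder.positions[h_idx]
        u = h - builder.positions[n_idx]
        return h_idx, h, u / np.linalg.norm(u)

    def sample_motif(donor_site: str) -> str:
        probs = targets.get(donor_site, {})
        labels = list(probs)
        p = np.array([probs[l] for l in labels], dtype=float)
        if p.sum() > 1.0 + 1e-9:
            raise ValueError(f"target probabilities for {donor_site} exceed 1")
        r = rng.random()
        cum = 0.0
        for lab, pi in zip(labels, p):
            cum += pi
            if r < cum:
                return lab
        return f"{donor_site}-H···{NO_ACCEPTOR}"

    def jittered_direction(u: np.ndarray, max_deg: float = 18.0) -> np.ndarray:
        axis = _perpendicular(u, rng)
        return _axis_rotation(axis, math.radians(rng.uniform(0.0, max_deg))) @ u

    none_pool: set[int] = set()  # processed, bond-free, not serving as acceptor
    serving: set[int] = set()  # molecules whose position some planned bond relies on

    def place_or_recruit(
        exclude: int, acc_label: str, target: np.ndarray, direction: np.ndarray, h_index: int
    ) -> bool:
        """Provide an acceptor at the target: new molecule or recruited free one."""
        nonlocal total_placed
        if total_placed < n_api:
            partner = builder.try_place_api_via_acceptor(
                acc_label, target, direction, h_index, max_tries=12
            )
            if partner is not None:
                total_placed += 1
                serving.add(partner)
                process_queue.append(partner)
                return True
            return False
        candidates = [c for c in sorted(none_pool) if c != exclude]
        if not candidates:
            return False
        rng.shuffle(candidates)
        for cand in candidates[:4]:
            if builder.try_relocate_api_via_acceptor(
                cand, acc_label, target, direction, h_index
            ):
                none_pool.discard(cand)
                serving.add(cand)
                return True
        return False

    def realize_label(bmol: int, donor_site: str, label: str) -> str:
        nonlocal waters_left, total_placed
        donor, primary, secondaries, star = _parse_motif(label)
        none_label = f"{donor_site}-H···{NO_ACCEPTOR}"
        if primary == NO_ACCEPTOR:
            return none_label
        h_idx, h_pos, u = donor_geometry(bmol, donor_site)
        if primary != WATER_ACCEPTOR:
            for attempt in range(10):  # fresh approach direction each attempt
                direction = jittered_direction(u, max_deg=10.0 + 3.0 * attempt)
                target = h_pos + rng.uniform(1.8, 2.3) * direction
                if place_or_recruit(bmol, primary, target, direction, h_idx):
                    return f"{donor_site}-H···{primary}"
            return none_label
        # water-bridged motif
        need = 1 + sum(1 for s in secondaries if s == WATER_ACCEPTOR)
        if waters_left < need:
            return none_label
        placed = None
        for _ in range(8):
            direction = jittered_direction(u)
            target = h_pos + rng.uniform(1.8, 2.3) * direction
            placed = builder.try_place_water(target, direction, h_idx, max_tries=12)
            if placed is not None:
                break
        if placed is None:
            return none_label
        waters_left -= 1
        _, o_base, dirs = placed
        o_pos = builder.positions[o_base]
        realized_sec: list[str] = []
        if star and len(secondaries) == 2 and all(s != WATER_ACCEPTOR for s in secondaries):
            if total_placed >= n_api:
                return f"{donor_site}-H···OH2"
            d2 = _PAIR_SEPARATION / (2.0 * math.sin(math.radians(_WATER_ANGLE_DEG / 2.0))) - _WATER_OH
            t2 = tuple(o_pos + (_WATER_OH + d2) * d for d in dirs)
            hw = (o_base + 1, o_base + 2)
            pair = builder.try_place_api_via_acceptor_pair(
                (secondaries[0], secondaries[1]), t2, hw, away_from=o_pos
            )
            if pair is not None:
                total_placed += 1
                serving.add(pair)
                process_queue.append(pair)
                realized_sec = sorted(secondaries)
                return (
                    f"{donor_site}-H···OH2···" + "/".join(realized_sec) + "*"
                )
            # fall back to the unbridged water motif
            return f"{donor_site}-H···OH2"
        for i, sec in enumerate(secondaries[:2]):
            w = dirs[i]
            hw_idx = o_base + 1 + i
            d2 = rng.uniform(1.8, 2.3)
            t2 = o_pos + (_WATER_OH + d2) * w
            if sec == WATER_ACCEPTOR:
                if waters_left < 1:
                    continue
                placed2 = builder.try_place_water(t2, w, hw_idx)
                if placed2 is not None:
                    waters_left -= 1
                    realized_sec.append(WATER_ACCEPTOR)
            else:
                if place_or_recruit(bmol, sec, t2, w, hw_idx):
                    realized_sec.append(sec)
        if realized_sec:
            return f"{donor_site}-H···OH2···" + "/".join(sorted(realized_sec))
        return f"{donor_site}-H···OH2"

    failed_demands: list[tuple[str, str]] = []

    def process_molecule(bmol: int) -> None:
        for donor_site in DONOR_SITES:
            label = sample_motif(donor_site)
            realized = realize_label(bmol, donor_site, label)
            planted[(bmol, donor_site)] = realized
            if realized.endswith(NO_ACCEPTOR) and not label.endswith(NO_ACCEPTOR):
                failed_demands.append((donor_site, label))
        if bmol not in serving and all(
            planted[(bmol, d)].endswith(NO_ACCEPTOR) for d in DONOR_SITES
        ):
            none_pool.add(bmol)

    def top_up(donor_site: str, label: str) -> None:
        # a blocked donor's demand is re-realized on another free donor of the
        # same site, keeping realized motif counts at the sampled counts
        candidates = [
            m
            for (m, s), lab in planted.items()
            if s == donor_site and lab.endswith(NO_ACCEPTOR)
        ]
        rng.shuffle(candidates)
        for m in candidates[:8]:
            realized = realize_label(m, donor_site, label)
            if not realized.endswith(NO_ACCEPTOR):
                planted[(m, donor_site)] = realized
                none_pool.discard(m)
                return

    while True:
        if process_queue:
            process_molecule(process_queue.pop(0))
        elif total_placed < n_api:
            bmol = builder.try_place_api(next_slot())
            while bmol is None:
                bmol = builder.try_place_api(next_slot())
            total_placed += 1
            process_queue.append(bmol)
        elif failed_demands:
            top_up(*failed_demands.pop(0))
        else:
            break

    # scatter leftover waters far from any donor/acceptor
    tries = 0
    while waters_left > 0:
        tries += 1
        if tries > 400 * max(n_water, 1):
            raise RuntimeError("packing failure: could not place leftover waters")
        o_pos = rng.uniform(0.0, edge, size=3)
        b = rng.normal(size=3)
        if builder.try_place_water(o_pos, b / np.linalg.norm(b), None) is not None:
            waters_left -= 1

    positions = np.array(builder.positions)
    if jitter > 0:
        positions = positions + rng.normal(scale=jitter, size=positions.shape)
    atoms = [
        AtomRecord(
            atom_id=i,
            element=builder.elements[i],
            site_label=builder.labels[i],
            molecule_id=builder.molecule_of[i],
            molecule_kind=builder.kinds[builder.molecule_of[i]],
            position=positions[i],
        )
        for i in range(len(builder.elements))
    ]
    snap = Snapshot(cell=cell, atoms=atoms, time_ps=time_ps, source_tag=source_tag)
    return snap, planted


def _rng_for(spec: EnsembleSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=tuple(key)))


def generate_snapshot(
    spec: EnsembleSpec,
    content_index: int,
    cell_index: int,
    snapshot_index: int = 0,
    targets: dict[str, dict[str, float]] | None = None,
) -> tuple[Snapshot, dict[tuple[int, str], str]]:
    """One synthetic frame plus its planted (molecule, donor) -> motif map."""
    n_water = spec.water_counts[content_index]
    if targets is None:
        targets = default_targets(n_water, spec.n_api_per_cell)
    rng = _rng_for(spec, content_index, cell_index, snapshot_index)
    pct = spec.nominal_content_pct[content_index]
    tag = f"w{pct:g}pct-cell{cell_index}"
    return _build_snapshot(
        n_api=spec.n_api_per_cell,
        n_water=n_water,
        targets=targets,
        spacing=spec.grid_spacing_ang,
        jitter=spec.jitter_ang,
        topology=default_topology(),
        rng=rng,
        time_ps=snapshot_index * spec.snapshot_spacing_ps,
        source_tag=tag,
    )


def generate_cell(
    spec: EnsembleSpec, content_index: int, cell_index: int
) -> Snapshot:
    """A single packed periodic cell at the requested water content."""
    snap, _ = generate_snapshot(spec, content_index, cell_index)
    return snap


def generate_trajectory(
    spec: EnsembleSpec,
    content_index: int,
    cell_index: int,
    n_snapshots: int,
    hbond_target_probabilities: dict[str, dict[str, float]] | None = None,
    resample_motifs: bool = True,
) -> SyntheticTrajectory:
    """A snapshot series whose realized motif fractions approach the targets.

    With ``resample_motifs`` every frame re-draws each donor's motif from the
    target table (frames are exchangeable draws of the same equilibrium
    distribution); without it a single frame is built and replicated with
    positional jitter only — zero jitter then yields identical frames.
    """
    snapshots: list[Snapshot] = []
    planted: list[PlantedMotif] = []
    if resample_motifs:
        for s in range(n_snapshots):
            snap, truth = generate_snapshot(
                spec, content_index, cell_index, s, hbond_target_probabilities
            )
            snapshots.append(snap)
            planted.extend(
                PlantedMotif(s, mol, site, lab) for (mol, site), lab in truth.items()
            )
    else:
        base, truth = generate_snapshot(
            spec, content_index, cell_index, 0, hbond_target_probabilities
        )
        for s in range(n_snapshots):
            rng = _rng_for(spec, content_index, cell_index, 10_000 + s)
            pos = base.positions.copy()
            if spec.jitter_ang > 0 and s > 0:
                pos = pos + rng.normal(scale=spec.jitter_ang, size=pos.shape)
            atoms = [
                AtomRecord(
                    atom_id=a.atom_id,
                    element=a.element,
                    site_label=a.site_label,
                    molecule_id=a.molecule_id,
                    molecule_kind=a.molecule_kind,
                    position=pos[i],
                )
                for i, a in enumerate(base.atoms)
            ]
            snapshots.append(
                Snapshot(
                    cell=base.cell,
                    atoms=atoms,
                    time_ps=s * spec.snapshot_spacing_ps,
                    source_tag=base.source_tag,
                )
            )
            planted.extend(
                PlantedMotif(s, mol, site, lab) for (mol, site), lab in truth.items()
            )
    return SyntheticTrajectory(snapshots=snapshots, planted=planted)


# ---------------------------------------------------------------------------
# surrogate shifts
# ---------------------------------------------------------------------------


@dataclass
class SurrogateShiftModel:
    """Linear structure-to-shift law for donor protons.

    shift = base(donor) + distance_coefficient * (d_HX - 2 A)
            + acceptor_offset(class) + Gaussian noise.

    Water is the most deshielding acceptor class by default, reflecting the
    physics the pipeline is meant to detect.
    """

    base_shift_ppm: dict[str, float] = field(
        default_factory=lambda: {"N6": 9.8, "N21": 8.6, "N28": 8.2}
    )
    distance_coefficient: float = -2.0
    acceptor_offsets_ppm: dict[str, float] = field(
        default_factory=lambda: {
            WATER_ACCEPTOR: 2.4,
            "O20": 1.6,
            "O29": 1.4,
            "N5": 1.1,
            NO_ACCEPTOR: 0.0,
        }
    )
    noise_sd_ppm: float = 0.3
    seed: int = 0

    def expected_shift(self, donor_site: str, acceptor: str, d_hx: float) -> float:
        base = self.base_shift_ppm[donor_site]
        if acceptor == NO_ACCEPTOR:
            return base
        return (
            base
            + self.distance_coefficient * (d_hx - 2.0)
            + self.acceptor_offsets_ppm.get(acceptor, 0.0)
        )


def surrogate_shifts(
    snapshots: list[Snapshot],
    model: SurrogateShiftModel,
    topology: TopologySpec,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[ShiftRecord]:
    """Deterministic (per seed) donor-proton shift records for all frames."""
    records: list[ShiftRecord] = []
    for sid, snap in enumerate(snapshots):
        rng = np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(sid,)))
        for asg in assign_motifs(snap, topology, criteria, snapshot_id=sid):
            acc = asg.motif.primary_acceptor_site
            d = asg.distance_hx if np.isfinite(asg.distance_hx) else 2.0
            value = model.expected_shift(asg.donor_site, acc, d)
            if model.noise_sd_ppm > 0:
                value += rng.normal(scale=model.noise_sd_ppm)
            records.append(
                ShiftRecord(
                    atom_id=asg.donor_H,
                    snapshot_id=sid,
                    element="H",
                    site_label=snap.atoms[asg.donor_H].site_label,
                    value_ppm=float(value),
                    kind="shift",
                    source_tag=snap.source_tag,
                )
            )
    return records


# ---------------------------------------------------------------------------
# surrogate energies
# ---------------------------------------------------------------------------


@dataclass
class SurrogateEnergyBackend:
    """Pairwise-additive Morse-well cluster energy with planted well depths.

    The energy is a sum over intermolecular atom pairs of
    ``D * ((1 - exp(-alpha (r - r0)))^2 - 1)`` truncated beyond ``cutoff``.
    Well depths make donor-H/water-O contacts the deepest, so hydrogen
    bonding to water is planted as the most favourable interaction.  The
    potential is deterministic and size-consistent: infinitely separated
    fragments contribute exactly zero.
    """

    depth_water: float = 5.0
    depth_o20: float = 3.0
    depth_o29: float = 2.8
    depth_n5: float = 2.2
    depth_background: float = 0.05
    alpha: float = 2.0
    r0: float = 2.0
    cutoff: float = 6.0

    _DONOR_H = frozenset({"H_N6", "H_N21", "H_N28", "HW1", "HW2"})

    def _acceptor_depths(self) -> dict[str, float]:
        return {"OW": self.depth_water, "O20": self.depth_o20,
                "O29": self.depth_o29, "N5": self.depth_n5}

    def _depth(self, label_a: str, label_b: str) -> float:
        table = self._acceptor_depths()
        for h, x in ((label_a, label_b), (label_b, label_a)):
            if h in self._DONOR_H and x in table:
                return table[x]
        return self.depth_background

    def _depth_matrix(self, labels_a, labels_b) -> np.ndarray:
        table = self._acceptor_depths()
        don_a = np.array([l in self._DONOR_H for l in labels_a])
        don_b = np.array([l in self._DONOR_H for l in labels_b])
        acc_a = np.array([table.get(l, 0.0) for l in labels_a])
        acc_b = np.array([table.get(l, 0.0) for l in labels_b])
        depth = np.full((len(don_a), len(don_b)), self.depth_background)
        hb = don_a[:, None] & (acc_b[None, :] > 0)
        depth = np.where(hb, acc_b[None, :], depth)
        bh = don_b[None, :] & (acc_a[:, None] > 0)
        return np.where(bh, acc_a[:, None], depth)

    def pair_energy(self, geom_a, geom_b) -> float:
        dist = np.linalg.norm(
            geom_a.positions[:, None, :] - geom_b.positions[None, :, :], axis=-1
        )
        depth = self._depth_matrix(geom_a.site_labels, geom_b.site_labels)
        well = depth * ((1.0 - np.exp(-self.alpha * (dist - self.r0))) ** 2 - 1.0)
        return float(well[dist <= self.cutoff].sum())

    def __call__(self, molecules: list) -> float:
        total = 0.0
        for i in range(len(molecules)):
            for j in range(i + 1, len(molecules)):
                total += self.pair_energy(molecules[i], molecules[j])
        return total
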