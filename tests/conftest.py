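"""Shared fixtures: minimal topologies, hand-built snapshots and 27-image
brute-force oracles used to validate the minimum-image search paths."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from amorphnmr.hbond_motifs import donor_instances
from amorphnmr.structure_io import AtomRecord, Snapshot, TopologySpec, UnitCell


@pytest.fixture
def mini_topology() -> TopologySpec:
    """A toy topology: one N-H donor species, one O acceptor species, water."""
    return TopologySpec(
        donors=[("N1", "H1")],
        acceptors=["OA"],
        covalent_bonds=[("N1", "H1"), ("OW", "HW1"), ("OW", "HW2")],
        water_oxygen="OW",
        water_hydrogens=("HW1", "HW2"),
    )


def make_snapshot(cell: UnitCell, entries: list[tuple]) -> Snapshot:
    """Build a snapshot from (element, site_label, molecule_id, kind, xyz)."""
    atoms = [
        AtomRecord(
            atom_id=i,
            element=el,
            site_label=lab,
            molecule_id=mol,
            molecule_kind=kind,
            position=np.asarray(pos, dtype=float),
        )
        for i, (el, lab, mol, kind, pos) in enumerate(entries)
    ]
    return Snapshot(cell=cell, atoms=atoms)


def donor_acceptor_snapshot(
    cell: UnitCell,
    rng: np.random.Generator,
    n_donors: int,
    n_acceptors: int,
) -> Snapshot:
    """Random N-H donor units plus lone O acceptors inside the cell."""
    frac = rng.random((n_donors + n_acceptors, 3))
    pts = frac @ cell.lattice
    entries = []
    mol = 0
    for i in range(n_donors):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        entries.append(("N", "N1", mol, "API", pts[i]))
        entries.append(("H", "H1", mol, "API", pts[i] + u))
        mol += 1
    for j in range(n_acceptors):
        entries.append(("O", "OA", mol, "API", pts[n_donors + j]))
        mol += 1
    return make_snapshot(cell, entries)


def random_wide_cell(rng: np.random.Generator, min_width: float) -> UnitCell:
    """Random triclinic cell whose perpendicular widths all exceed min_width."""
    while True:
        base = np.diag(rng.uniform(min_width * 1.2, min_width * 1.8, size=3))
        base[1, 0] = rng.uniform(-2.0, 2.0)
        base[2, 0] = rng.uniform(-2.0, 2.0)
        base[2, 1] = rng.uniform(-2.0, 2.0)
        try:
            cell = UnitCell(lattice=base)
        except ValueError:
            continue
        if cell.widths.min() > min_width:
            return cell


def brute_force_mic(cell: UnitCell, r_from: np.ndarray, r_to: np.ndarray) -> np.ndarray:
    """Shortest displacement over the 27 adjacent periodic images."""
    best, best_norm = None, np.inf
    for i, j, k in itertools.product((-1, 0, 1), repeat=3):
        shift = i * cell.lattice[0] + j * cell.lattice[1] + k * cell.lattice[2]
        d = np.asarray(r_to) + shift - np.asarray(r_from)
        n = np.linalg.norm(d)
        if n < best_norm:
            best, best_norm = d, n
    return best


def oracle_hbond_pairs(snapshot, topology, criteria) -> set[tuple[int, int]]:
    """Exhaustive 27-image H-bond detection, returned as (H, acceptor) pairs."""
    acceptor_idx = [
        i
        for i, a in enumerate(snapshot.atoms)
        if a.site_label in topology.acceptor_labels
        and a.element in criteria.acceptor_elements
    ]
    pairs = set()
    for _, _, n_idx, h_idx in donor_instances(snapshot, topology):
        h = snapshot.atoms[h_idx].position
        n = snapshot.atoms[n_idx].position
        hn = brute_force_mic(snapshot.cell, h, n)
        hn = hn / np.linalg.norm(hn)
        for acc in acceptor_idx:
            if acc in (n_idx, h_idx):
                continue
            d = brute_force_mic(snapshot.cell, h, snapshot.atoms[acc].position)
            dist = np.linalg.norm(d)
            if dist >= criteria.hx_max_ang:
                continue
            cosang = float(np.dot(d, hn) / dist)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > criteria.angle_min_deg:
                pairs.add((h_idx, acc))
    return pairs


def oracle_environment(snapshot, probe: int, cutoff: float) -> set[int]:
    """Exhaustive 27-image environment membership for a probe molecule."""
    molecules = snapshot.molecules()
    probe_pos = [snapshot.atoms[i].position for i in molecules[probe]]
    env = set()
    for mol_id, idxs in molecules.items():
        if mol_id == probe:
            continue
        hit = False
        for i in idxs:
            for p in probe_pos:
                d = brute_force_mic(snapshot.cell, p, snapshot.atoms[i].position)
                if np.linalg.norm(d) <= cutoff:
                    hit = True
                    break
            if hit:
                break
        if hit:
            env.add(mol_id)
    return env
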