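"""Local-environment extraction and per-motif relative formation energies.

The environment of a probe molecule is every molecule with at least one atom
within 5 A (minimum image) of any probe atom.  The formation energy of the
resulting intermolecular complex is E(complex) - E(environment), evaluated by
a pluggable single-point backend on identical unwrapped cluster coordinates;
it therefore contains the probe's own ground-state/conformational energy plus
its interaction with the environment.  Relative formation energies subtract
the mean over instances whose selected donor found no acceptor, so the
no-acceptor class averages to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .hbond_motifs import NO_ACCEPTOR, HBondCriteria, MotifLabel, assign_motifs
from .structure_io import Snapshot, TopologySpec, mic_displacements

__all__ = [
    "MoleculeGeometry",
    "EnvironmentComplex",
    "FormationEnergyRecord",
    "EnergyBackend",
    "extract_environment",
    "formation_energy",
    "relative_formation_energies",
    "aggregate_by_motif",
    "export_cluster_xyz",
]

# An energy backend evaluates a non-periodic cluster of molecules and must be
# deterministic for fixed input and size-consistent for separated fragments.
EnergyBackend = Callable[[list["MoleculeGeometry"]], float]


@dataclass(frozen=True)
class MoleculeGeometry:
    """One whole (unwrapped) molecule of a cluster."""

    molecule_id: int
    elements: tuple[str, ...]
    site_labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) Cartesian A


@dataclass
class EnvironmentComplex:
    """A probe molecule plus the molecules within the cutoff of any probe atom."""

    probe_molecule: int
    environment_molecules: frozenset[int]
    snapshot_id: int
    cutoff_ang: float
    cluster: dict[int, MoleculeGeometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probe_molecule in self.environment_molecules:
            raise ValueError("probe molecule cannot be part of its own environment")


@dataclass
class FormationEnergyRecord:
    complex: EnvironmentComplex
    E_complex: float
    E_environment: float
    donor_motifs: dict[str, MotifLabel]
    relative_energy: float | None = None

    @property
    def E_formation(self) -> float:
        return self.E_complex - self.E_environment


def _whole_molecule(snapshot: Snapshot, idxs: list[int]) -> np.ndarray:
    """Unwrap a molecule so no bond crosses the boundary (anchor: first atom)."""
    pos = snapshot.positions[idxs]
    anchor = pos[0]
    return anchor + mic_displacements(snapshot.cell, pos - anchor)


def extract_environment(
    snapshot: Snapshot,
    probe: int,
    cutoff: float = 5.0,
    snapshot_id: int = 0,
) -> EnvironmentComplex:
    """All molecules with any atom within ``cutoff`` of any probe atom.

    Environment molecules are translated to the periodic image closest to the
    probe so the returned cluster is geometrically contiguous and directly
    usable by a non-periodic energy backend.
    """
    snapshot.cell.require_cutoff(cutoff)
    molecules = snapshot.molecules()
    if probe not in molecules:
        raise ValueError(f"no molecule with id {probe}")
    probe_pos = _whole_molecule(snapshot, molecules[probe])

    def geometry(mol_id: int, pos: np.ndarray) -> MoleculeGeometry:
        idxs = molecules[mol_id]
        return MoleculeGeometry(
            molecule_id=mol_id,
            elements=tuple(snapshot.atoms[i].element for i in idxs),
            site_labels=tuple(snapshot.atoms[i].site_label for i in idxs),
            positions=pos,
        )

    cluster = {probe: geometry(probe, probe_pos)}
    env: set[int] = set()
    for mol_id, idxs in molecules.items():
        if mol_id == probe:
            continue
        pos = _whole_molecule(snapshot, idxs)
        # minimum-image displacement of each env atom from each probe atom
        disp = mic_displacements(
            snapshot.cell, pos[None, :, :] - probe_pos[:, None, :]
        )
        dist = np.linalg.norm(disp, axis=-1)
        i_probe, i_env = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i_probe, i_env] > cutoff:
            continue
        env.add(mol_id)
        # translate the whole molecule so its closest atom sits at the
        # minimum-image position relative to the probe
        target = probe_pos[i_probe] + disp[i_probe, i_env]
        shift = target - pos[i_env]
        cluster[mol_id] = geometry(mol_id, pos + shift)
    return EnvironmentComplex(
        probe_molecule=probe,
        environment_molecules=frozenset(env),
        snapshot_id=snapshot_id,
        cutoff_ang=cutoff,
        cluster=cluster,
    )


def formation_energy(
    complex_: EnvironmentComplex,
    snapshot: Snapshot,
    backend: EnergyBackend,
    donor_motifs: dict[str, MotifLabel] | None = None,
    topology: TopologySpec | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> FormationEnergyRecord:
    """E(probe + environment) - E(environment) on identical cluster coordinates."""
    env_geoms = [
        complex_.cluster[m] for m in sorted(complex_.environment_molecules)
    ]
    all_geoms = [complex_.cluster[complex_.probe_molecule]] + env_geoms
    try:
        e_complex = float(backend(all_geoms))
        e_env = float(backend(env_geoms)) if env_geoms else 0.0
    except Exception as exc:  # annotate with the complex identity
        raise RuntimeError(
            f"energy backend failed for probe {complex_.probe_molecule} "
            f"in snapshot {complex_.snapshot_id}: {exc}"
        ) from exc
    if donor_motifs is None:
        if topology is None:
            raise ValueError("provide either donor_motifs or a topology to derive them")
        donor_motifs = {
            asg.donor_site: asg.motif
            for asg in assign_motifs(snapshot, topology, criteria, complex_.snapshot_id)
            if asg.molecule_id == complex_.probe_molecule
        }
    return FormationEnergyRecord(
        complex=complex_,
        E_complex=e_complex,
        E_environment=e_env,
        donor_motifs=donor_motifs,
    )


def relative_formation_energies(
    records: list[FormationEnergyRecord], donor_site: str
) -> list[FormationEnergyRecord]:
    """Subtract the mean formation energy of the donor's no-acceptor instances.

    The baseline is specific to the selected donor site: only instances whose
    motif for that donor is the no-neighbour class enter the mean.
    """
    baseline_vals = [
        r.E_formation
        for r in records
        if donor_site in r.donor_motifs
        and r.donor_motifs[donor_site].primary_acceptor_site == NO_ACCEPTOR
    ]
    if not baseline_vals:
        raise ValueError(
            f"no instances without an acceptor for donor {donor_site}; "
            "relative energies are undefined"
        )
    baseline = float(np.mean(baseline_vals))
    for r in records:
        r.relative_energy = r.E_formation - baseline
    return records


def export_cluster_xyz(complex_: EnvironmentComplex, path) -> None:
    """Write the unwrapped cluster as plain (non-periodic) XYZ.

    Lets an external single-point engine evaluate the same coordinates the
    shipped backend sees; the probe molecule comes first.
    """
    order = [complex_.probe_molecule] + sorted(complex_.environment_molecules)
    lines = []
    for mol in order:
        geom = complex_.cluster[mol]
        for el, (x, y, z) in zip(geom.elements, geom.positions):
            lines.append(f"{el:2s} {x:16.8f} {y:16.8f} {z:16.8f}")
    header = (
        f"probe={complex_.probe_molecule} snapshot={complex_.snapshot_id} "
        f"cutoff={complex_.cutoff_ang}"
    )
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n{header}\n" + "\n".join(lines) + "\n")


def aggregate_by_motif(
    records: list[FormationEnergyRecord],
    donor_site: str,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Mean relative formation energy +/- SEM per primary-acceptor category.

    The intramolecular acceptor (donor bonded within its own molecule) forms
    its own category, suffixed "(intra)".  Categories below ``min_fraction``
    of all instances are flagged ``displayed=False`` but kept in the table;
    callers writing a display table filter on that column.  SEM uses the
    n-1 sample standard deviation.
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        if donor_site not in r.donor_motifs:
            continue
        if r.relative_energy is None:
            raise ValueError("call relative_formation_energies first")
        motif = r.donor_motifs[donor_site]
        cat = motif.primary_acceptor_site
        if motif.intramolecular:
            cat = f"{cat} (intra)"
        groups.setdefault(cat, []).append(r.relative_energy)
    total = sum(len(v) for v in groups.values())
    rows = []
    for cat, vals in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        arr = np.asarray(vals, dtype=float)
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        frac = len(arr) / total
        rows.append(
            {
                "acceptor": cat,
                "n": len(arr),
                "fraction": frac,
                "mean_relative_energy": float(arr.mean()),
                "sem": sem,
                "displayed": frac >= min_fraction,
            }
        )
    return pd.DataFrame(rows)
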