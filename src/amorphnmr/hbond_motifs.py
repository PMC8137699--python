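"""Hydrogen-bond detection, water-bridged motif labelling and census statistics.

A hydrogen bond is an N-H···X contact (X = O or N) with the N-H-X angle
strictly above 130 degrees and the H···X distance strictly below 2.5 A,
both measured under the minimum-image convention.  Each donor group gets at
most one motif per snapshot: the passing acceptor with the shortest H···X
distance.  When the primary acceptor is a water oxygen, the search is
extended through the two water hydrogens to secondary acceptors with the
same criteria, giving water-bridged motifs such as ``N6-H···OH2···O20/OH2``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Snapshot, TopologySpec, mic_displacements

__all__ = [
    "HBondCriteria",
    "HBond",
    "MotifLabel",
    "MotifCensus",
    "DonorAssignment",
    "detect_hbonds",
    "assign_primary_motif",
    "extend_through_water",
    "assign_motifs",
    "census",
    "filter_by_shift",
    "select_top_patterns",
]

NO_ACCEPTOR = "(none)"
WATER_ACCEPTOR = "OH2"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: strict inequalities at both thresholds."""

    angle_min_deg: float = 130.0
    hx_max_ang: float = 2.5
    acceptor_elements: frozenset = frozenset({"O", "N"})

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_min_deg < 180.0:
            raise ValueError("angle_min_deg must lie in (0, 180)")
        if self.hx_max_ang <= 0.0:
            raise ValueError("hx_max_ang must be positive")


@dataclass(frozen=True)
class HBond:
    donor_N: int
    donor_H: int
    acceptor: int
    distance_hx: float
    angle_nhx: float
    donor_molecule: int
    acceptor_molecule: int
    donor_site: str
    acceptor_site: str
    intramolecular: bool


@dataclass(frozen=True)
class MotifLabel:
    """Canonical motif string for one donor instance.

    ``primary_acceptor_site`` is a site label, ``"OH2"`` for water, or
    ``"(none)"``.  ``secondary_sites`` lists water-bridged secondary
    acceptors in lexicographic order; ``same_molecule_secondary`` marks two
    secondary neighbours belonging to one molecule (rendered ``*``).
    """

    donor_site: str
    primary_acceptor_site: str = NO_ACCEPTOR
    secondary_sites: tuple[str, ...] = ()
    same_molecule_secondary: bool = False
    intramolecular: bool = False  # primary acceptor within the donor's own molecule

    @property
    def canonical(self) -> str:
        s = f"{self.donor_site}-H···{self.primary_acceptor_site}"
        if self.secondary_sites:
            s += "···" + "/".join(self.secondary_sites)
            if self.same_molecule_secondary:
                s += "*"
        return s

    def __str__(self) -> str:
        return self.canonical

    @property
    def is_bonded(self) -> bool:
        return self.primary_acceptor_site != NO_ACCEPTOR

    @property
    def involves_water(self) -> bool:
        return self.primary_acceptor_site == WATER_ACCEPTOR or WATER_ACCEPTOR in self.secondary_sites


@dataclass
class MotifCensus:
    """Counts and fractions of motif strings, including the no-neighbour class."""

    counts: dict[str, int]
    total_donor_instances: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total_donor_instances == 0:
            return {}
        return {k: v / self.total_donor_instances for k, v in self.counts.items()}

    def to_frame(self):
        import pandas as pd

        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(rows, columns=["motif", "count"])
        df["fraction"] = df["count"] / max(self.total_donor_instances, 1)
        return df


@dataclass
class DonorAssignment:
    """One donor instance (donor group in one snapshot) and its motif."""

    snapshot_id: int
    molecule_id: int
    donor_site: str
    donor_N: int
    donor_H: int
    motif: MotifLabel
    distance_hx: float = float("nan")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _acceptor_indices(snapshot: Snapshot, topology: TopologySpec) -> np.ndarray:
    labels = topology.acceptor_labels
    return np.array(
        [i for i, a in enumerate(snapshot.atoms) if a.site_label in labels], dtype=int
    )


def _passing_acceptors(
    snapshot: Snapshot,
    n_idx: int,
    h_idx: int,
    acceptor_idx: np.ndarray,
    criteria: HBondCriteria,
    exclude: set[int],
) -> list[tuple[int, float, float]]:
    """Acceptors passing both criteria for one donor group, sorted by distance."""
    cand = np.array([i for i in acceptor_idx if i not in exclude], dtype=int)
    if cand.size == 0:
        return []
    pos = snapshot.positions
    cell = snapshot.cell
    disp_hx = mic_displacements(cell, pos[cand] - pos[h_idx])
    dist_hx = np.linalg.norm(disp_hx, axis=1)
    near = dist_hx < criteria.hx_max_ang
    if not near.any():
        return []
    disp_hn = mic_displacements(cell, pos[n_idx] - pos[h_idx])
    nh = disp_hn / np.linalg.norm(disp_hn)
    cosang = (disp_hx[near] @ nh) / dist_hx[near]
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = angles > criteria.angle_min_deg
    out = [
        (int(c), float(d), float(a))
        for c, d, a in zip(cand[near][ok], dist_hx[near][ok], angles[ok])
    ]
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def donor_instances(
    snapshot: Snapshot, topology: TopologySpec
) -> list[tuple[int, str, int, int]]:
    """All (molecule_id, donor_site, N index, H index) donor groups present."""
    out = []
    for mol_id, sites in sorted(snapshot.site_index().items()):
        for n_label, h_label in topology.donors:
            if n_label in sites and h_label in sites:
                out.append((mol_id, n_label, sites[n_label], sites[h_label]))
    return out


def detect_hbonds(
    snapshot: Snapshot,
    topology: TopologySpec,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """All donor/acceptor contacts passing the geometric criteria.

    Intramolecular bonds are detected and flagged, never dropped.  The donor
    nitrogen itself is excluded from its own acceptor candidates.
    """
    snapshot.cell.require_cutoff(criteria.hx_max_ang)
    acceptor_idx = _acceptor_indices(snapshot, topology)
    el_ok = {i for i in acceptor_idx if snapshot.atoms[i].element in criteria.acceptor_elements}
    acceptor_idx = np.array(sorted(el_ok), dtype=int)
    bonds: list[HBond] = []
    for mol_id, donor_site, n_idx, h_idx in donor_instances(snapshot, topology):
        for acc, dist, ang in _passing_acceptors(
            snapshot, n_idx, h_idx, acceptor_idx, criteria, exclude={n_idx, h_idx}
        ):
            a = snapshot.atoms[acc]
            bonds.append(
                HBond(
                    donor_N=n_idx,
                    donor_H=h_idx,
                    acceptor=acc,
                    distance_hx=dist,
                    angle_nhx=ang,
                    donor_molecule=mol_id,
                    acceptor_molecule=a.molecule_id,
                    donor_site=donor_site,
                    acceptor_site=a.site_label,
                    intramolecular=a.molecule_id == mol_id,
                )
            )
    return bonds


def _acceptor_name(site_label: str, topology: TopologySpec) -> str:
    return WATER_ACCEPTOR if site_label == topology.water_oxygen else site_label


def assign_primary_motif(
    donor: tuple[int, int],
    hbonds: list[HBond],
    topology: TopologySpec,
    snapshot: Snapshot,
) -> MotifLabel:
    """Primary motif for one (N, H) donor pair: shortest passing acceptor wins."""
    n_idx, h_idx = donor
    site = snapshot.atoms[n_idx].site_label
    if (site, snapshot.atoms[h_idx].site_label) not in topology.donors:
        raise ValueError(f"donor pair ({site}, {snapshot.atoms[h_idx].site_label}) not in topology")
    mine = [b for b in hbonds if b.donor_N == n_idx and b.donor_H == h_idx]
    if not mine:
        return MotifLabel(donor_site=site, primary_acceptor_site=NO_ACCEPTOR)
    best = min(mine, key=lambda b: (b.distance_hx, b.acceptor))
    return MotifLabel(
        donor_site=best.donor_site,
        primary_acceptor_site=_acceptor_name(best.acceptor_site, topology),
        intramolecular=best.intramolecular,
    )


def extend_through_water(
    hbond: HBond,
    snapshot: Snapshot,
    topology: TopologySpec,
    criteria: HBondCriteria = HBondCriteria(),
) -> MotifLabel:
    """Extend a donor···water bond through the water hydrogens.

    Each of the two water H atoms is treated as a donor with the same
    geometric criteria; its nearest passing acceptor (if any) becomes a
    secondary neighbour.  Secondary sites are reported in lexicographic
    order; two secondary neighbours on one molecule are starred.
    """
    if snapshot.atoms[hbond.acceptor].site_label != topology.water_oxygen:
        raise ValueError("primary acceptor is not a water oxygen")
    water_mol = hbond.acceptor_molecule
    sites = snapshot.site_index()[water_mol]
    o_idx = sites[topology.water_oxygen]
    acceptor_idx = _acceptor_indices(snapshot, topology)
    secondaries: list[tuple[str, int]] = []
    for h_label in topology.water_hydrogens:
        h_idx = sites[h_label]
        passing = _passing_acceptors(
            snapshot,
            o_idx,
            h_idx,
            acceptor_idx,
            criteria,
            exclude={o_idx, h_idx, hbond.donor_H},
        )
        if passing:
            acc, _, _ = passing[0]
            a = snapshot.atoms[acc]
            secondaries.append((_acceptor_name(a.site_label, topology), a.molecule_id))
    secondaries.sort(key=lambda t: t[0])
    same_mol = len(secondaries) == 2 and secondaries[0][1] == secondaries[1][1]
    return MotifLabel(
        donor_site=hbond.donor_site,
        primary_acceptor_site=WATER_ACCEPTOR,
        secondary_sites=tuple(s for s, _ in secondaries),
        same_molecule_secondary=same_mol,
    )


def assign_motifs(
    snapshot: Snapshot,
    topology: TopologySpec,
    criteria: HBondCriteria = HBondCriteria(),
    snapshot_id: int = 0,
) -> list[DonorAssignment]:
    """One full (possibly water-extended) motif per donor group."""
    hbonds = detect_hbonds(snapshot, topology, criteria)
    by_donor: dict[tuple[int, int], list[HBond]] = {}
    for b in hbonds:
        by_donor.setdefault((b.donor_N, b.donor_H), []).append(b)
    out: list[DonorAssignment] = []
    for mol_id, donor_site, n_idx, h_idx in donor_instances(snapshot, topology):
        mine = by_donor.get((n_idx, h_idx), [])
        if not mine:
            motif = MotifLabel(donor_site=donor_site)
            dist = float("nan")
        else:
            best = min(mine, key=lambda b: (b.distance_hx, b.acceptor))
            dist = best.distance_hx
            if best.acceptor_site == topology.water_oxygen:
                motif = extend_through_water(best, snapshot, topology, criteria)
            else:
                motif = MotifLabel(
                    donor_site=donor_site,
                    primary_acceptor_site=_acceptor_name(best.acceptor_site, topology),
                    intramolecular=best.intramolecular,
                )
        out.append(
            DonorAssignment(
                snapshot_id=snapshot_id,
                molecule_id=mol_id,
                donor_site=donor_site,
                donor_N=n_idx,
                donor_H=h_idx,
                motif=motif,
                distance_hx=dist,
            )
        )
    return out


# ---------------------------------------------------------------------------
# census statistics
# ---------------------------------------------------------------------------


def census(
    snapshots: list[Snapshot],
    topology: TopologySpec,
    criteria: HBondCriteria = HBondCriteria(),
    donor_filter: str | None = None,
) -> MotifCensus:
    """Motif census over snapshots: one instance per donor group per snapshot.

    Fractions include the no-neighbour class and sum to one.  An optional
    ``donor_filter`` restricts the census to a single donor site (e.g. "N6").
    """
    if not snapshots:
        raise ValueError("census requires at least one snapshot")
    counter: Counter[str] = Counter()
    total = 0
    for sid, snap in enumerate(snapshots):
        for asg in assign_motifs(snap, topology, criteria, snapshot_id=sid):
            if donor_filter is not None and asg.donor_site != donor_filter:
                continue
            counter[asg.motif.canonical] += 1
            total += 1
    return MotifCensus(counts=dict(counter), total_donor_instances=total)


def census_from_assignments(
    assignments: list[DonorAssignment], donor_filter: str | None = None
) -> MotifCensus:
    counter: Counter[str] = Counter()
    total = 0
    for asg in assignments:
        if donor_filter is not None and asg.donor_site != donor_filter:
            continue
        counter[asg.motif.canonical] += 1
        total += 1
    return MotifCensus(counts=dict(counter), total_donor_instances=total)


def filter_by_shift(
    donor_instances_with_shifts: list[tuple[DonorAssignment, float]],
    threshold: float = 11.0,
) -> list[tuple[DonorAssignment, float]]:
    """Retain donor instances whose 1H shift is strictly above the threshold."""
    out = []
    for asg, shift in donor_instances_with_shifts:
        if shift is None or (isinstance(shift, float) and np.isnan(shift)):
            raise ValueError(
                f"missing shift for donor {asg.donor_site} in snapshot {asg.snapshot_id}"
            )
        if shift > threshold:
            out.append((asg, shift))
    return out


def select_top_patterns(
    filtered_census: MotifCensus, coverage: float = 0.75
) -> list[str]:
    """Smallest count-descending prefix of motifs covering the requested share.

    Ties are broken lexicographically.  Mirrors a display rule that keeps the
    patterns accounting for the top 75% of high-shift donor instances.
    """
    items = sorted(filtered_census.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(filtered_census.counts.values())
    if total == 0:
        return []
    target = coverage * total
    out, cum = [], 0
    for motif, count in items:
        out.append(motif)
        cum += count
        if cum >= target:
            break
    return out
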