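"""Hydrogen-bond detection criteria, water-bridged motif labels and census."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorphnmr.hbond_motifs import (
    HBondCriteria,
    MotifCensus,
    assign_motifs,
    assign_primary_motif,
    census,
    detect_hbonds,
    extend_through_water,
    filter_by_shift,
    select_top_patterns,
)
from amorphnmr.structure_io import UnitCell
from amorphnmr.synthetic_data import default_topology

from conftest import donor_acceptor_snapshot, make_snapshot, oracle_hbond_pairs, random_wide_cell


def donor_with_acceptor(distance: float, angle_deg: float, cell_edge: float = 20.0):
    """One N-H donor plus one O acceptor at a set H···O distance and N-H-O angle."""
    cell = UnitCell.cubic(cell_edge)
    n = np.array([5.0, 5.0, 5.0])
    h = n + np.array([1.0, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    acc = h + distance * np.array([math.cos(theta), math.sin(theta), 0.0])
    entries = [
        ("N", "N1", 0, "API", n),
        ("H", "H1", 0, "API", h),
        ("O", "OA", 1, "API", acc),
    ]
    return make_snapshot(cell, entries)


class TestDetectionCriteria:
    def test_contact_inside_both_cutoffs_is_detected(self, mini_topology):
        snap = donor_with_acceptor(2.4, 150.0)
        bonds = detect_hbonds(snap, mini_topology)
        assert len(bonds) == 1
        assert bonds[0].distance_hx == pytest.approx(2.4, abs=1e-6)
        assert bonds[0].angle_nhx == pytest.approx(150.0, abs=1e-6)

    def test_crystal_like_128_8_degree_bond_is_excluded(self, mini_topology):
        # the known intramolecular contact at 128.8 deg falls below the
        # 130 deg cutoff and must not be identified
        snap = donor_with_acceptor(2.4, 128.8)
        assert detect_hbonds(snap, mini_topology) == []

    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (2.5, 150.0, 0),   # boundary distance excluded (strict <)
            (2.499, 150.0, 1),
            (2.0, 130.0, 0),   # boundary angle excluded (strict >)
            (2.0, 130.1, 1),
            (2.6, 170.0, 0),
        ],
    )
    def test_strict_inequalities_at_both_boundaries(
        self, mini_topology, distance, angle, expected
    ):
        snap = donor_with_acceptor(distance, angle)
        assert len(detect_hbonds(snap, mini_topology)) == expected

    def test_detection_across_periodic_boundary(self, mini_topology):
        cell = UnitCell.cubic(12.0)
        entries = [
            ("N", "N1", 0, "API", (2.0, 6.0, 6.0)),
            ("H", "H1", 0, "API", (1.0, 6.0, 6.0)),
            ("O", "OA", 1, "API", (11.0, 6.0, 6.0)),  # 2.0 A through the wall
        ]
        snap = make_snapshot(cell, entries)
        bonds = detect_hbonds(snap, mini_topology)
        assert len(bonds) == 1
        assert bonds[0].distance_hx == pytest.approx(2.0, abs=1e-9)

    def test_cell_too_small_for_mic_is_an_error(self, mini_topology):
        snap = donor_with_acceptor(2.0, 160.0, cell_edge=4.0)
        with pytest.raises(ValueError, match="minimum-image"):
            detect_hbonds(snap, mini_topology)

    def test_matches_27_image_oracle_on_random_cells(self, mini_topology):
        rng = np.random.default_rng(77)
        criteria = HBondCriteria()
        for _ in range(25):
            cell = random_wide_cell(rng, min_width=2 * criteria.hx_max_ang + 0.5)
            snap = donor_acceptor_snapshot(cell, rng, n_donors=8, n_acceptors=10)
            got = {(b.donor_H, b.acceptor) for b in detect_hbonds(snap, mini_topology, criteria)}
            assert got == oracle_hbond_pairs(snap, mini_topology, criteria)


class TestMotifAssignment:
    def test_free_donor_gets_none_label(self, mini_topology):
        snap = donor_with_acceptor(3.5, 170.0)
        motif = assign_primary_motif((0, 1), [], mini_topology, snap)
        assert motif.canonical == "N1-H···(none)"
        assert not motif.is_bonded

    def test_shortest_acceptor_wins(self, mini_topology):
        cell = UnitCell.cubic(20.0)
        n = np.array([5.0, 5.0, 5.0])
        h = n + [1.0, 0.0, 0.0]
        entries = [
            ("N", "N1", 0, "API", n),
            ("H", "H1", 0, "API", h),
            ("O", "OA", 1, "API", h + [2.3, 0.0, 0.0]),
            ("O", "OA", 2, "API", h + [1.86, 0.4, 0.0]),  # 1.9 A, near-linear
        ]
        snap = make_snapshot(cell, entries)
        bonds = detect_hbonds(snap, mini_topology)
        motif = assign_primary_motif((0, 1), bonds, mini_topology, snap)
        asg = assign_motifs(snap, mini_topology)[0]
        assert asg.distance_hx == pytest.approx(np.sqrt(0.4**2 + 1.86**2), abs=1e-9)
        assert motif.primary_acceptor_site == "OA"
        assert asg.motif.primary_acceptor_site == "OA"

    def test_intramolecular_bond_is_detected_and_flagged(self):
        topo = default_topology()
        cell = UnitCell.cubic(20.0)
        # N21-H pointing at the same molecule's O29 with valid geometry
        n = np.array([5.0, 5.0, 5.0])
        h = n + [1.0, 0.0, 0.0]
        entries = [
            ("C", "C1", 0, "API", n + [0.0, 2.0, 0.0]),
            ("N", "N21", 0, "API", n),
            ("H", "H_N21", 0, "API", h),
            ("O", "O29", 0, "API", h + [2.0, 0.3, 0.0]),
        ]
        snap = make_snapshot(cell, entries)
        bonds = detect_hbonds(snap, topo)
        assert len(bonds) == 1
        assert bonds[0].intramolecular
        asg = next(a for a in assign_motifs(snap, topo) if a.donor_site == "N21")
        assert asg.motif.canonical == "N21-H···O29"
        assert asg.motif.intramolecular


def water_bridge_snapshot(secondary: str | None, same_molecule_pair: bool = False):
    """N6-H donating to a water; the water optionally donates onward."""
    topo = default_topology()
    cell = UnitCell.cubic(24.0)
    n = np.array([6.0, 6.0, 6.0])
    h = n + [1.0, 0.0, 0.0]
    ow = h + [2.0, 0.0, 0.0]
    half = math.radians(104.52 / 2)
    d1 = np.array([math.cos(half), math.sin(half), 0.0])
    d2 = np.array([math.cos(half), -math.sin(half), 0.0])
    entries = [
        ("C", "C1", 0, "API", n - [2.0, 0.0, 0.0]),
        ("N", "N6", 0, "API", n),
        ("H", "H_N6", 0, "API", h),
        ("O", "OW", 1, "water", ow),
        ("H", "HW1", 1, "water", ow + 0.9572 * d1),
        ("H", "HW2", 1, "water", ow + 0.9572 * d2),
    ]
    if secondary == "O20":
        entries.append(("C", "C1", 2, "API", ow + 4.2 * d1))
        entries.append(("O", "O20", 2, "API", ow + 2.8 * d1))
        if same_molecule_pair:
            entries.append(("O", "O29", 2, "API", ow + 2.8 * d2))
    elif secondary == "water":
        ow2 = ow + 2.9 * d1
        entries.append(("O", "OW", 2, "water", ow2))
        entries.append(("H", "HW1", 2, "water", ow2 + [0.9, 0.3, 0.0]))
        entries.append(("H", "HW2", 2, "water", ow2 + [0.9, -0.3, 0.0]))
        entries.append(("C", "C1", 3, "API", ow + 4.2 * d2))
        entries.append(("O", "O20", 3, "API", ow + 2.8 * d2))
    return make_snapshot(cell, entries), topo


class TestWaterBridges:
    def test_unbridged_water_motif(self):
        snap, topo = water_bridge_snapshot(secondary=None)
        asg = next(a for a in assign_motifs(snap, topo) if a.donor_site == "N6")
        assert asg.motif.canonical == "N6-H···OH2"

    def test_secondary_sites_sorted_lexicographically(self):
        # water donates to both another water and an O20: label O20/OH2
        snap, topo = water_bridge_snapshot(secondary="water")
        asg = next(a for a in assign_motifs(snap, topo) if a.donor_site == "N6")
        assert asg.motif.canonical == "N6-H···OH2···O20/OH2"

    def test_single_secondary_acceptor(self):
        snap, topo = water_bridge_snapshot(secondary="O20")
        asg = next(a for a in assign_motifs(snap, topo) if a.donor_site == "N6")
        assert asg.motif.canonical == "N6-H···OH2···O20"

    def test_same_molecule_secondary_pair_is_starred(self):
        snap, topo = water_bridge_snapshot(secondary="O20", same_molecule_pair=True)
        asg = next(a for a in assign_motifs(snap, topo) if a.donor_site == "N6")
        assert asg.motif.canonical == "N6-H···OH2···O20/O29*"
        assert asg.motif.same_molecule_secondary

    def test_extension_requires_water_acceptor(self, mini_topology):
        snap = donor_with_acceptor(2.0, 170.0)
        bonds = detect_hbonds(snap, mini_topology)
        with pytest.raises(ValueError, match="water"):
            extend_through_water(bonds[0], snap, mini_topology)


class TestCensus:
    def test_two_donor_arithmetic(self, mini_topology):
        cell = UnitCell.cubic(20.0)
        entries = [
            ("N", "N1", 0, "API", (5.0, 5.0, 5.0)),
            ("H", "H1", 0, "API", (6.0, 5.0, 5.0)),
            ("O", "OA", 1, "API", (8.0, 5.0, 5.0)),
            ("N", "N1", 2, "API", (14.0, 14.0, 14.0)),
            ("H", "H1", 2, "API", (15.0, 14.0, 14.0)),
        ]
        snap = make_snapshot(cell, entries)
        cen = census([snap], mini_topology)
        assert cen.total_donor_instances == 2
        assert cen.fractions == {
            "N1-H···OA": pytest.approx(0.5),
            "N1-H···(none)": pytest.approx(0.5),
        }

    def test_fractions_sum_to_one_and_are_scale_invariant(self, mini_topology):
        rng = np.random.default_rng(3)
        cell = random_wide_cell(rng, min_width=6.0)
        snap = donor_acceptor_snapshot(cell, rng, n_donors=6, n_acceptors=8)
        once = census([snap], mini_topology)
        twice = census([snap, snap], mini_topology)
        assert sum(once.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert once.fractions == twice.fractions

    def test_empty_snapshot_list_rejected(self, mini_topology):
        with pytest.raises(ValueError):
            census([], mini_topology)

    def test_motif_strings_invariant_under_atom_order_permutation(self):
        from amorphnmr.structure_io import read_snapshot, write_snapshot
        from amorphnmr.synthetic_data import EnsembleSpec, generate_cell

        spec = EnsembleSpec(
            n_api_per_cell=8, water_counts=[8], cells_per_content=[1],
            nominal_content_pct=[4.0], seed=21,
        )
        snap = generate_cell(spec, 0, 0)
        topo = default_topology()
        base = census([snap], topo)
        import numpy as np

        rng = np.random.default_rng(9)
        order = rng.permutation(snap.n_atoms)
        from conftest import make_snapshot as mk

        entries = [
            (
                snap.atoms[i].element,
                snap.atoms[i].site_label,
                snap.atoms[i].molecule_id,
                snap.atoms[i].molecule_kind,
                snap.atoms[i].position,
            )
            for i in order
        ]
        permuted = mk(snap.cell, entries)
        assert census([permuted], topo).counts == base.counts


class TestShiftFilter:
    def test_strict_threshold_boundary(self, mini_topology):
        snap = donor_with_acceptor(2.0, 170.0)
        asg = assign_motifs(snap, mini_topology)
        pairs = [(asg[0], 10.9), (asg[0], 11.0), (asg[0], 11.1)]
        kept = filter_by_shift(pairs, threshold=11.0)
        assert [s for _, s in kept] == [11.1]

    def test_empty_input_and_zero_threshold(self, mini_topology):
        snap = donor_with_acceptor(2.0, 170.0)
        asg = assign_motifs(snap, mini_topology)
        assert filter_by_shift([], threshold=11.0) == []
        assert len(filter_by_shift([(asg[0], 5.0)], threshold=0.0)) == 1

    def test_missing_shift_is_hard_error(self, mini_topology):
        snap = donor_with_acceptor(2.0, 170.0)
        asg = assign_motifs(snap, mini_topology)
        with pytest.raises(ValueError, match="missing shift"):
            filter_by_shift([(asg[0], float("nan"))])


class TestTopPatterns:
    @pytest.mark.parametrize(
        "counts,coverage,expected",
        [
            ({"A": 6, "B": 3, "C": 1}, 0.75, ["A", "B"]),
            ({"A": 8, "B": 1, "C": 1}, 0.75, ["A"]),
            ({"A": 6, "B": 3, "C": 1}, 1.0, ["A", "B", "C"]),
        ],
    )
    def test_smallest_covering_prefix(self, counts, coverage, expected):
        cen = MotifCensus(counts=counts, total_donor_instances=sum(counts.values()))
        assert select_top_patterns(cen, coverage=coverage) == expected

    def test_empty_census_gives_empty_list(self):
        cen = MotifCensus(counts={}, total_donor_instances=0)
        assert select_top_patterns(cen) == []

    @given(
        counts=st.dictionaries(
            st.text(alphabet="ABCDEFG", min_size=1, max_size=3),
            st.integers(min_value=1, max_value=50),
            min_size=1,
            max_size=8,
        ),
        coverage=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_selection_covers_requested_share(self, counts, coverage):
        cen = MotifCensus(counts=counts, total_donor_instances=sum(counts.values()))
        chosen = select_top_patterns(cen, coverage=coverage)
        total = sum(counts.values())
        covered = sum(counts[m] for m in chosen)
        assert covered >= coverage * total
        # minimality: dropping the last selected pattern breaks coverage
        if len(chosen) > 1:
            assert covered - counts[chosen[-1]] < coverage * total
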