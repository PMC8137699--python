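"""Referencing, spectrum aggregation, conditional decomposition and ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorphnmr.shift_spectra import (
    CandidateStructure,
    ShiftRecord,
    aggregate_spectrum,
    apply_referencing,
    fit_referencing,
    motif_conditional_spectra,
    population_above,
    rank_candidates,
    shift_rmse,
)


def shielding_records(values: dict[str, float]) -> list[ShiftRecord]:
    return [
        ShiftRecord(
            atom_id=i, snapshot_id=0, element="H", site_label=lab,
            value_ppm=v, kind="shielding",
        )
        for i, (lab, v) in enumerate(values.items())
    ]


def shift_records(values, element="H", snapshot_id=0, tag=""):
    return [
        ShiftRecord(
            atom_id=i, snapshot_id=snapshot_id, element=element,
            site_label=f"s{i}", value_ppm=v, kind="shift", source_tag=tag,
        )
        for i, v in enumerate(values)
    ]


class TestReferencing:
    def test_exact_linear_relation_recovered(self):
        exp = {"a": 2.0, "b": 7.5, "c": 11.0}
        recs = shielding_records({k: 30.0 - v for k, v in exp.items()})
        model = fit_referencing(recs, exp, "H")
        assert model.slope == pytest.approx(-1.0, abs=1e-12)
        assert model.intercept == pytest.approx(30.0, abs=1e-10)
        assert model.rmse_ppm == pytest.approx(0.0, abs=1e-10)

    def test_two_points_interpolate_with_zero_rmse(self):
        exp = {"a": 1.0, "b": 9.0}
        recs = shielding_records({"a": 25.0, "b": 19.5})
        model = fit_referencing(recs, exp, "H")
        assert model.rmse_ppm == pytest.approx(0.0, abs=1e-10)

    def test_noisy_ols_recovery(self):
        # sigma = 30 - delta + N(0, 0.1): slope near -1, rmse near 0.1
        rng = np.random.default_rng(12)
        delta = rng.uniform(0.0, 12.0, size=50)
        exp = {f"s{i}": float(d) for i, d in enumerate(delta)}
        sigma = {f"s{i}": float(30.0 - d + rng.normal(scale=0.1)) for i, d in enumerate(delta)}
        model = fit_referencing(shielding_records(sigma), exp, "H")
        assert -1.05 < model.slope < -0.95
        assert model.rmse_ppm == pytest.approx(0.1, abs=0.05)

    def test_too_few_matches_or_constant_shieldings_rejected(self):
        with pytest.raises(ValueError):
            fit_referencing(shielding_records({"a": 20.0}), {"a": 1.0}, "H")
        with pytest.raises(ValueError):
            fit_referencing(
                shielding_records({"a": 20.0, "b": 20.0}), {"a": 1.0, "b": 2.0}, "H"
            )

    def test_apply_then_refit_is_identity(self):
        exp = {"a": 2.0, "b": 7.5, "c": 11.0, "d": 4.2}
        recs = shielding_records({k: 28.7 - 0.97 * v for k, v in exp.items()})
        model = fit_referencing(recs, exp, "H")
        mapped = apply_referencing(model, recs)
        assert all(r.kind == "shift" for r in mapped)
        # refit treating the mapped shifts as "shieldings": identity map
        remapped = [
            ShiftRecord(r.atom_id, r.snapshot_id, r.element, r.site_label,
                        r.value_ppm, "shielding")
            for r in mapped
        ]
        ident = fit_referencing(remapped, exp, "H")
        assert ident.slope == pytest.approx(1.0, abs=1e-9)
        assert ident.intercept == pytest.approx(0.0, abs=1e-8)

    def test_element_mismatch_rejected(self):
        exp = {"a": 2.0, "b": 7.5}
        recs = shielding_records({"a": 28.0, "b": 22.5})
        model = fit_referencing(recs, exp, "H")
        bad = [
            ShiftRecord(0, 0, "C", "a", 100.0, "shielding"),
        ]
        with pytest.raises(ValueError):
            apply_referencing(model, bad)


class TestSpectra:
    def test_single_proton_unit_area_and_mode(self):
        spec = aggregate_spectrum(
            shift_records([10.0]), normalization="unit_area", ppm_range=(5, 15)
        )
        assert spec.integral() == pytest.approx(1.0, abs=1e-9)
        assert spec.bin_centers[np.argmax(spec.intensities)] == pytest.approx(10.0, abs=0.05)

    def test_per_proton_integral_counts_protons(self):
        spec = aggregate_spectrum(shift_records([9.0, 9.0]), ppm_range=(4, 14))
        assert spec.integral() == pytest.approx(2.0, abs=1e-6)

    def test_additivity_over_record_subsets(self):
        a = shift_records([8.0, 9.5, 11.2])
        b = shift_records([7.1, 10.0])
        rng = (2.0, 16.0)
        sa = aggregate_spectrum(a, ppm_range=rng)
        sb = aggregate_spectrum(b, ppm_range=rng)
        sab = aggregate_spectrum(a + b, ppm_range=rng)
        assert np.allclose(sa.intensities + sb.intensities, sab.intensities)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            aggregate_spectrum(shift_records([1.0]), bin_width=0.0)
        with pytest.raises(ValueError):
            aggregate_spectrum(shift_records([1.0]), broadening_ppm=-1.0)
        with pytest.raises(ValueError):
            aggregate_spectrum([])


class TestConditionalSpectra:
    def test_partition_sums_to_unconditional(self):
        rng = np.random.default_rng(4)
        recs = shift_records(list(rng.uniform(7, 13, size=40)))
        motifs = {(r.snapshot_id, r.atom_id): ("A" if r.atom_id % 3 else "B") for r in recs}
        cond = motif_conditional_spectra(recs, motifs, ppm_range=(2, 18))
        total = aggregate_spectrum(recs, ppm_range=(2, 18))
        stacked = np.sum([s.intensities for s in cond.values()], axis=0)
        assert np.allclose(stacked, total.intensities)

    def test_single_motif_equals_unconditional(self):
        recs = shift_records([8.0, 9.0, 10.0])
        motifs = {(r.snapshot_id, r.atom_id): "only" for r in recs}
        cond = motif_conditional_spectra(recs, motifs, ppm_range=(3, 15))
        total = aggregate_spectrum(recs, ppm_range=(3, 15))
        assert np.allclose(cond["only"].intensities, total.intensities)

    def test_missing_assignment_is_an_error(self):
        recs = shift_records([8.0, 9.0])
        with pytest.raises(ValueError, match="assignment"):
            motif_conditional_spectra(recs, {(0, 0): "A"})


class TestPopulationAbove:
    def test_half_above(self):
        recs = shift_records([10.0, 12.0], tag="g")
        assert population_above(recs, threshold=11.0) == {"g": pytest.approx(0.5)}

    def test_threshold_above_max_gives_zero(self):
        recs = shift_records([10.0, 10.5], tag="g")
        assert population_above(recs, threshold=11.0)["g"] == 0.0

    def test_boundary_value_not_counted(self):
        recs = shift_records([11.0], tag="g")
        assert population_above(recs, threshold=11.0)["g"] == 0.0


class TestRmseRanking:
    def test_identical_vectors_have_zero_rmse(self):
        cand = CandidateStructure("c", {"H": {"a": 1.0, "b": 2.0}})
        assert shift_rmse(cand, {"a": 1.0, "b": 2.0}, "H") == 0.0

    def test_known_arithmetic(self):
        cand = CandidateStructure("c", {"H": {"a": 1.0, "b": 2.0, "c": 3.0}})
        exp = {"a": 1.0, "b": 2.0, "c": 4.0}
        assert shift_rmse(cand, exp, "H") == pytest.approx(np.sqrt(1 / 3))

    def test_missing_site_is_an_error(self):
        cand = CandidateStructure("c", {"H": {"a": 1.0}})
        with pytest.raises(ValueError, match="missing"):
            shift_rmse(cand, {"a": 1.0, "b": 2.0}, "H")

    @given(
        shifts=st.lists(
            st.floats(min_value=-50, max_value=200, allow_nan=False),
            min_size=2, max_size=10,
        ),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_linear_scaling(self, shifts, scale):
        exp = {f"s{i}": 0.0 for i in range(len(shifts))}
        cand = CandidateStructure("c", {"H": {f"s{i}": v for i, v in enumerate(shifts)}})
        base = shift_rmse(cand, exp, "H")
        perm = CandidateStructure(
            "p", {"H": {f"s{i}": v for i, v in zip(reversed(range(len(shifts))), reversed(shifts))}}
        )
        assert shift_rmse(perm, exp, "H") == pytest.approx(base, rel=1e-9, abs=1e-12)
        scaled = CandidateStructure(
            "s", {"H": {f"s{i}": scale * v for i, v in enumerate(shifts)}}
        )
        assert shift_rmse(scaled, exp, "H") == pytest.approx(scale * base, rel=1e-9, abs=1e-9)

    def test_exact_candidate_ranks_first(self):
        exp = {"H": {"a": 1.0, "b": 5.0}}
        exact = CandidateStructure("exact", {"H": {"a": 1.0, "b": 5.0}})
        offset = CandidateStructure("off", {"H": {"a": 2.0, "b": 6.0}})
        table = rank_candidates([offset, exact], exp, ["H"])
        assert list(table["candidate_id"]) == ["exact", "off"]
        assert list(table["rank"]) == [1, 2]

    def test_single_candidate_ranks_first(self):
        exp = {"H": {"a": 1.0}, "C": {"x": 100.0}}
        cand = CandidateStructure("only", {"H": {"a": 1.3}, "C": {"x": 101.0}})
        table = rank_candidates([cand], exp, ["H", "C"])
        assert table.loc[0, "rank"] == 1

    def test_uniformly_better_tautomer_wins_every_element(self):
        # one tautomer's per-element RMSEs are all smaller: it ranks first
        # for each element alone and for the combined score
        exp = {
            "H": {"a": 1.0, "b": 2.0},
            "C": {"x": 100.0, "y": 120.0},
            "N": {"p": 200.0},
        }
        tautA = CandidateStructure(
            "A", {"H": {"a": 1.1, "b": 2.1}, "C": {"x": 101.0, "y": 121.0}, "N": {"p": 202.0}}
        )
        tautB = CandidateStructure(
            "B", {"H": {"a": 1.4, "b": 2.4}, "C": {"x": 103.0, "y": 123.0}, "N": {"p": 216.0}}
        )
        for el in ("H", "C", "N"):
            assert shift_rmse(tautA, exp[el], el) < shift_rmse(tautB, exp[el], el)
        table = rank_candidates([tautB, tautA], exp, ["H", "C", "N"])
        assert list(table["candidate_id"]) == ["A", "B"]
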