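"""Colocalization grouping, census arithmetic, damage scoring and baseline."""

import numpy as np
import pytest
from scipy import stats

from tightrope.coloc import (ComplexRecord, apply_density_filter,
                             baseline_random_probability, census_complexes,
                             colocalize_channels, compare_probabilities,
                             damage_colocalization_probability)
from tightrope.detection import Spot

TABLE1_COUNTS = {"A": 230, "B": 40, "C": 59, "AB": 25, "AC": 8, "BC": 6,
                 "ABC": 6}
TABLE1_FRACTIONS = {"A": 61.5, "B": 10.7, "C": 15.8, "AB": 6.7, "AC": 2.1,
                    "BC": 1.6, "ABC": 1.6}


def _spot(x, y, channel, intensity=100.0):
    return Spot(x=x, y=y, intensity=intensity, sigma_fit=1.3, channel=channel)


class TestColocalizeChannels:
    def test_pair_inside_inclusive_radius_is_one_complex(self):
        groups = colocalize_channels({"565": [_spot(10.0, 10.0, "565")],
                                      "655": [_spot(12.9, 10.0, "655")]})
        assert len(groups) == 1
        assert groups[0].composition == frozenset({"565", "655"})

    def test_pair_outside_radius_stays_separate(self):
        groups = colocalize_channels({"565": [_spot(10.0, 10.0, "565")],
                                      "655": [_spot(13.1, 10.0, "655")]})
        assert len(groups) == 2
        assert all(len(g.composition) == 1 for g in groups)

    def test_exact_boundary_is_inclusive(self):
        groups = colocalize_channels({"565": [_spot(10.0, 10.0, "565")],
                                      "655": [_spot(13.0, 10.0, "655")]})
        assert len(groups) == 1

    def test_chain_closure_builds_triple_complex(self):
        # A-B and B-C within radius, A-C beyond it: still one {A,B,C} complex
        groups = colocalize_channels(
            {"565": [_spot(10.0, 10.0, "565")],
             "605": [_spot(12.5, 10.0, "605")],
             "655": [_spot(15.0, 10.0, "655")]},
            protein_map={"565": "A", "605": "B", "655": "C"})
        assert len(groups) == 1
        assert groups[0].composition == frozenset("ABC")

    def test_same_channel_pair_flagged_ambiguous(self):
        groups = colocalize_channels({"565": [_spot(10.0, 10.0, "565"),
                                              _spot(11.0, 10.0, "565")],
                                      "655": [_spot(10.5, 10.0, "655")]})
        assert len(groups) == 1
        assert groups[0].ambiguous

    def test_symmetric_in_channel_order_and_translation(self):
        a = {"565": [_spot(10.0, 10.0, "565")], "655": [_spot(12.0, 11.0, "655")]}
        b = {"655": [_spot(12.0, 11.0, "655")], "565": [_spot(10.0, 10.0, "565")]}
        shifted = {ch: [_spot(s.x + 7.3, s.y - 2.1, ch) for s in spots]
                   for ch, spots in a.items()}
        ga, gb, gs = (colocalize_channels(d) for d in (a, b, shifted))
        assert [g.composition for g in ga] == [g.composition for g in gb]
        assert [g.composition for g in gs] == [g.composition for g in ga]
        assert gs[0].x - ga[0].x == pytest.approx(7.3)

    def test_position_is_intensity_weighted_mean(self):
        groups = colocalize_channels({"565": [_spot(10.0, 10.0, "565", 300.0)],
                                      "655": [_spot(12.0, 10.0, "655", 100.0)]})
        assert groups[0].x == pytest.approx(10.5)


class TestCensus:
    def test_published_triple_colour_census(self):
        census = census_complexes(TABLE1_COUNTS)
        assert census.total == 374
        for comp, frac in TABLE1_FRACTIONS.items():
            assert round(census.fraction_pct(comp), 1) == frac

    def test_published_dual_colour_census(self):
        census = census_complexes({"AB": 371, "C": 268, "ABC": 127})
        assert round(census.fraction_pct("AB"), 1) == 48.4
        assert round(census.fraction_pct("C"), 1) == 35.0
        assert round(census.fraction_pct("ABC"), 1) == 16.6

    def test_single_composition_is_100_percent(self):
        census = census_complexes({"A": 17})
        assert census.fraction_pct("A") == pytest.approx(100.0)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(10)
        counts = {c: int(n) for c, n in
                  zip(["A", "B", "C", "AB"], rng.integers(1, 500, 4))}
        census = census_complexes(counts)
        assert census.table["fraction_pct"].sum() == pytest.approx(100.0,
                                                                   abs=1e-9)

    def test_sem_over_flow_cells(self):
        records = []
        # 3 flow cells with A fractions 50%, 60%, 70%
        for fc, n_a in enumerate([5, 6, 7]):
            records += [ComplexRecord(composition=frozenset("A"), s_um=1.0,
                                      flow_cell_id=fc)] * n_a
            records += [ComplexRecord(composition=frozenset("B"), s_um=2.0,
                                      flow_cell_id=fc)] * (10 - n_a)
        census = census_complexes(records)
        assert census.n_flow_cells == 3
        row = census.table[census.table.composition == "A"].iloc[0]
        expected_sem = np.std([50.0, 60.0, 70.0], ddof=1) / np.sqrt(3)
        assert row["sem_pct"] == pytest.approx(expected_sem)

    def test_ambiguous_records_excluded(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=0.0),
                   ComplexRecord(composition=frozenset("AB"), s_um=0.0,
                                 ambiguous=True)]
        census = census_complexes(records)
        assert census.total == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            census_complexes([])


class TestDensityFilter:
    def _tightrope(self, tid, n):
        return [ComplexRecord(composition=frozenset("A"), s_um=float(i),
                              tightrope_id=tid) for i in range(n)]

    def test_overloaded_tightrope_dropped_entirely(self):
        records = self._tightrope(0, 7) + self._tightrope(1, 3)
        kept = apply_density_filter(records, max_per_tightrope=6)
        assert len(kept) == 3
        assert all(r.tightrope_id == 1 for r in kept)

    def test_boundary_six_retained(self):
        kept = apply_density_filter(self._tightrope(0, 6))
        assert len(kept) == 6

    def test_empty_input_passes_through(self):
        assert apply_density_filter([]) == []


class TestDamageColocalization:
    def test_all_on_marker_is_100_percent(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=8.0,
                                 tightrope_id=i) for i in range(10)]
        markers = {i: [8.0] for i in range(10)}
        res = damage_colocalization_probability(records, markers)
        assert res.probability_pct == pytest.approx(100.0)

    def test_none_within_radius_is_0_percent(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=2.0,
                                 tightrope_id=i) for i in range(10)]
        markers = {i: [8.0] for i in range(10)}
        res = damage_colocalization_probability(records, markers)
        assert res.probability_pct == pytest.approx(0.0)
        assert res.n_examined == 10

    def test_exclusion_rule_drops_other_complexes_on_hit(self):
        # complex on the marker plus two elsewhere: 1 examined, 1 colocalized
        records = [ComplexRecord(composition=frozenset("A"), s_um=8.0,
                                 tightrope_id=0),
                   ComplexRecord(composition=frozenset("A"), s_um=2.0,
                                 tightrope_id=0),
                   ComplexRecord(composition=frozenset("A"), s_um=14.0,
                                 tightrope_id=0)]
        res = damage_colocalization_probability(records, {0: [8.0]})
        assert (res.n_colocalized, res.n_examined) == (1, 1)

    def test_miss_counts_every_complex(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=2.0,
                                 tightrope_id=0),
                   ComplexRecord(composition=frozenset("A"), s_um=14.0,
                                 tightrope_id=0)]
        res = damage_colocalization_probability(records, {0: [8.0]})
        assert (res.n_colocalized, res.n_examined) == (0, 2)

    def test_markerless_tightropes_ignored(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=8.0,
                                 tightrope_id=0),
                   ComplexRecord(composition=frozenset("A"), s_um=8.0,
                                 tightrope_id=99)]
        res = damage_colocalization_probability(records, {0: [8.0]})
        assert res.n_examined == 1

    def test_sem_over_flow_cells(self):
        records, markers = [], {}
        # fc 0: both tightropes hit; fc 1: one of two
        for fc, hits in [(0, (True, True)), (1, (True, False))]:
            for t, hit in enumerate(hits):
                tid = 10 * fc + t
                records.append(ComplexRecord(
                    composition=frozenset("A"), s_um=8.0 if hit else 2.0,
                    tightrope_id=tid, flow_cell_id=fc))
                markers[(fc, tid)] = [8.0]
        res = damage_colocalization_probability(records, markers)
        assert res.per_flow_cell_pct == {0: 100.0, 1: 50.0}
        assert res.sem_pct == pytest.approx(np.std([100.0, 50.0], ddof=1)
                                            / np.sqrt(2))


class TestBaseline:
    def test_radius_covering_tightrope_gives_100_percent_expectation(self):
        records = [ComplexRecord(composition=frozenset("A"), s_um=1.0)]
        res = baseline_random_probability(records, length_um=16.0,
                                          radius_px=100.0)
        assert res.baseline_pct == pytest.approx(100.0)

    def test_uniform_binding_converges_to_2r_over_L(self):
        rng = np.random.default_rng(11)
        n = 10_000
        length_um, radius_px, px_nm = 16.0, 3.0, 100.0
        records = [ComplexRecord(composition=frozenset("A"),
                                 s_um=float(rng.uniform(0, length_um)),
                                 tightrope_id=i) for i in range(n)]
        res = baseline_random_probability(records, length_um=length_um,
                                          radius_px=radius_px,
                                          pixel_size_nm=px_nm)
        assert res.baseline_pct == pytest.approx(3.75)
        p = res.baseline_pct / 100.0
        se_pct = 100.0 * np.sqrt(p * (1 - p) / n)
        assert abs(res.probability_pct - res.baseline_pct) <= 3 * se_pct

    def test_zero_molecules_rejected(self):
        with pytest.raises(ValueError):
            baseline_random_probability([])


class TestCompareProbabilities:
    def test_identical_groups_give_t0_p1(self):
        t, p = compare_probabilities([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_equal_groups_give_t0(self):
        t, _p = compare_probabilities([10.0, 10.0, 10.0], [10.0, 10.0, 10.0])
        assert t == 0.0

    def test_separated_groups_significant(self):
        a, b = [30.0, 32.0, 28.0], [46.0, 50.0, 44.0]
        t, p = compare_probabilities(a, b)
        assert p < 0.01
        # independent oracle: closed-form pooled-variance t and t CDF
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
            / (na + nb - 2)
        t_ref = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=na + nb - 2)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_probabilities([1.0], [1.0, 2.0])
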