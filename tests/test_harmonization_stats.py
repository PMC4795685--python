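from itertools import product

import numpy as np
import pytest

from contourqa import (
    PairedSample,
    all_indices,
    compare_rounds,
    mann_whitney,
    summarize_round,
    wilcoxon_paired,
)
from contourqa.harmonization_stats import DegenerateSampleError, holm_adjust
from contourqa.indices import INDEX_NAMES

from conftest import make_cube


def paired(v1, v2, name="dsc") -> PairedSample:
    ids = tuple(f"o{i}" for i in range(len(v1)))
    return PairedSample(ids, tuple(v1), tuple(v2), index_name=name)


def signed_rank_enumeration_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = diffs[diffs != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    total = 0
    for signs in product((0, 1), repeat=len(d)):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        count += w <= w_obs
        total += 1
    return count / total


class TestWilcoxonPaired:
    def test_exact_p_for_five_positive_differences_is_one_sixteenth(self):
        v1 = [1.0, 2.0, 3.0, 4.0, 5.0]
        v2 = [1.5, 2.7, 3.1, 4.9, 5.4]
        res = wilcoxon_paired(paired(v1, v2))
        assert res.method_note.startswith("exact")
        assert res.p_value == pytest.approx(1 / 16)
        d = np.array(v2) - np.array(v1)
        assert res.p_value == pytest.approx(signed_rank_enumeration_p(d))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v1 = rng.normal(size=8)
        v2 = v1 + rng.normal(size=8)
        res = wilcoxon_paired(paired(v1, v2))
        assert res.p_value == pytest.approx(
            signed_rank_enumeration_p(v2 - v1), abs=1e-12)

    def test_uniform_positive_shift_n14_is_extreme_and_significant(self):
        v1 = np.linspace(0.4, 0.7, 14)
        # every observer improves, by slightly different amounts (no tied |d|)
        v2 = v1 + 0.05 + 0.001 * np.arange(14)
        res = wilcoxon_paired(paired(v1, v2))
        assert res.method_note.startswith("exact")
        assert res.statistic == 0.0  # all signs agree: min rank-sum is 0
        assert res.p_value == pytest.approx(2 / 2**14)
        assert res.significant

    def test_constant_shift_ties_all_differences_but_stays_significant(self):
        v1 = np.linspace(0.4, 0.7, 14)
        res = wilcoxon_paired(paired(v1, v1 + 0.05))
        assert "approximation" in res.method_note
        assert res.statistic == 0.0 and res.significant

    def test_invariant_under_common_constant(self):
        rng = np.random.default_rng(11)
        v1 = rng.normal(size=10)
        v2 = v1 + rng.normal(size=10)
        p0 = wilcoxon_paired(paired(v1, v2)).p_value
        p1 = wilcoxon_paired(paired(v1 + 5.0, v2 + 5.0)).p_value
        assert p0 == pytest.approx(p1)

    def test_all_zero_differences_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_paired(paired([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]))

    def test_tied_differences_fall_back_to_approximation(self):
        v1 = np.zeros(12)
        v2 = np.array([0.1] * 6 + [-0.1] * 6)
        res = wilcoxon_paired(paired(v1, v2))
        assert "approximation" in res.method_note
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_are_dropped_from_n_effective(self):
        v1 = [1.0, 2.0, 3.0, 4.0]
        v2 = [1.0, 2.5, 3.25, 4.75]
        res = wilcoxon_paired(paired(v1, v2))
        assert res.n_effective == (3,)


def brute_force_u(a, b) -> float:
    """U for group a by direct pairwise comparison, ties counted half."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


class TestMannWhitney:
    @pytest.mark.parametrize("seed", range(8))
    def test_u_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 12, size=rng.integers(3, 15)).astype(float)
        b = rng.integers(0, 12, size=rng.integers(3, 15)).astype(float)
        res = mann_whitney(a, b)
        assert res.statistic == pytest.approx(brute_force_u(a, b))

    def test_disjoint_supports_are_significant(self):
        res = mann_whitney([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert res.p_value < 0.05 and res.significant

    def test_identical_groups_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_tied_is_reported_degenerate_not_nan(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0 and "degenerate" in res.method_note

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 11)
        p0 = mann_whitney(a, b).p_value
        p1 = mann_whitney(np.exp(a), np.exp(b)).p_value
        assert p0 == pytest.approx(p1)

    def test_small_groups_without_ties_use_exact_null(self):
        res = mann_whitney([0.1, 0.5, 0.9], [0.2, 0.6, 1.4, 2.0])
        assert res.method_note.startswith("exact")

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateSampleError):
            mann_whitney([1.0], [1.0, 2.0])


class TestSummaries:
    def _indexsets(self, dsc_values):
        out = []
        for k, v in enumerate(dsc_values):
            # piggyback on real IndexSets by scaling one bar against another
            from contourqa import VoxelMask
            import numpy as np

            n = 1000
            i = int(round(v * n))  # identical-volume masks: dsc = i/n
            a = np.zeros((2 * n, 1, 1), bool)
            b = np.zeros((2 * n, 1, 1), bool)
            a[:n] = True
            b[n - i:2 * n - i] = True
            out.append(all_indices(VoxelMask(a), VoxelMask(b), test_id=f"o{k}"))
        return out

    def test_hand_computed_mean_and_sd(self):
        sets = self._indexsets([0.5, 0.7])
        mean, sd = summarize_round(sets)["dsc"]
        assert mean == pytest.approx(0.6)
        assert sd == pytest.approx(0.1414, abs=2e-4)

    def test_identical_records_have_zero_sd(self, cube):
        sets = [all_indices(cube, cube, test_id=f"o{i}") for i in range(4)]
        for name in INDEX_NAMES:
            mean, sd = summarize_round(sets)[name]
            assert sd == 0.0

    def test_single_record_rejected(self, cube):
        with pytest.raises(DegenerateSampleError):
            summarize_round([all_indices(cube, cube)])


class TestHolm:
    def test_step_down_adjustment(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])


class TestCompareRounds:
    def test_identical_rounds_flagged_degenerate_not_significant(self):
        from contourqa import preset_config, simulate_case, ObserverSet

        cfg = preset_config("lowrisk", n_observers=5, seed=2)
        one_round = simulate_case(cfg, case_id="1", rounds=("1",))
        s = ObserverSet(reference_observer=one_round.reference_observer)
        for (o, c, r), m in one_round:
            s.add(o, c, "1", m)
            s.add(o, c, "2", m)
        report = compare_rounds(s, "1", mode="reference")
        assert set(report.degenerate) == set(INDEX_NAMES)
        assert all(t is None for t in report.tests.values())
        assert "degenerate" in report.to_text_table()

    def test_observer_in_only_one_round_is_dropped_with_warning(self, caplog):
        import logging
        from contourqa import preset_config, simulate_case

        cfg = preset_config("lowrisk", n_observers=6, seed=4, round2_scale=0.5)
        s = simulate_case(cfg, case_id="1")
        del s.masks[("obs06", "1", "2")]
        with caplog.at_level(logging.WARNING):
            report = compare_rounds(s, "1", mode="reference")
        assert any("dropped" in r.message for r in caplog.records)
        # reference obs01 excluded, obs06 dropped -> 4 paired observers
        assert len(report.indexsets["1"]) == 4

    def test_reference_mode_excludes_the_reference_observer(self):
        from contourqa import preset_config, simulate_case

        cfg = preset_config("lowrisk", n_observers=6, seed=4)
        s = simulate_case(cfg, case_id="1")
        report = compare_rounds(s, "1", mode="reference")
        ids = {rec.test_id for rec in report.indexsets["1"]}
        assert s.reference_observer not in ids and len(ids) == 5

    def test_report_table_shape(self):
        from contourqa import preset_config, simulate_case

        cfg = preset_config("lowrisk", n_observers=5, seed=9, round2_scale=0.7)
        s = simulate_case(cfg, case_id="1")
        report = compare_rounds(s, "1", mode="consensus")
        frame = report.summary_frame()
        assert list(frame["round_id"]) == ["1", "2"]
        table = report.to_text_table()
        assert "VR (±SD)" in table and "p = " in table
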