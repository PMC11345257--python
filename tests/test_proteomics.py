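"""Detection, Venn overlap, imputation, s0 statistic, permutation volcano."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lamipul import (
    ConfigError,
    DeResult,
    LfqMatrix,
    LfqSimConfig,
    TwoSampleS0Test,
    call_direction,
    condition_overlap,
    detect_expressed,
    differential_expression,
    make_lfq,
    prepare,
    s0_t_test,
)
from oracles import pooled_t, venn_regions


def matrix_from(values: dict[str, list], conditions=("A", "B"), reps=3) -> LfqMatrix:
    cols = pd.MultiIndex.from_tuples(
        [(c, r) for c in conditions for r in range(1, reps + 1)],
        names=["condition", "replicate"])
    return LfqMatrix(pd.DataFrame.from_dict(values, orient="index",
                                            columns=cols).astype(float))


class TestDetectExpressed:
    def test_one_of_three_rule(self):
        m = matrix_from({
            "all_missing": [np.nan] * 3 + [1, 1, 1],
            "one_present": [8, np.nan, np.nan] + [1, 1, 1],
            "two_present": [8, 8, np.nan] + [1, 1, 1],
        })
        assert detect_expressed(m, "A", min_reps=1) == {"one_present", "two_present"}
        assert detect_expressed(m, "A", min_reps=3) == set()

    def test_min_reps_above_replicates(self):
        m = matrix_from({"p": [1] * 6})
        with pytest.raises(ConfigError):
            detect_expressed(m, "A", min_reps=4)

    def test_zero_counts_as_missing(self):
        m = matrix_from({"p": [0, 0, 0, 1, 1, 1]})
        assert detect_expressed(m, "A") == set()


class TestConditionOverlap:
    def test_disjoint_and_identical(self):
        disjoint = condition_overlap({"x": {1}, "y": {2}, "z": {3}})
        assert disjoint[("x",)] == disjoint[("y",)] == disjoint[("z",)] == 1
        assert disjoint[("x", "y", "z")] == 0
        same = condition_overlap({"x": {1, 2}, "y": {1, 2}, "z": {1, 2}})
        assert same[("x", "y", "z")] == 2
        assert sum(v for k, v in same.items() if len(k) < 3) == 0

    def test_matches_membership_enumeration(self, rng):
        for _ in range(50):
            sets = {name: set(rng.integers(0, 50, size=rng.integers(0, 40)))
                    for name in ("lam", "glc", "ctl")}
            regions = condition_overlap(sets)
            oracle = venn_regions(sets)
            for key, count in regions.items():
                assert count == oracle.get(key, 0)
            assert sum(regions.values()) == len(set().union(*sets.values()))


class TestPrepare:
    def test_log2_and_constant_zero_imputation(self):
        m = matrix_from({"p": [8, np.nan, 1, 4, 4, 4]})
        out = prepare(m)
        assert out.loc["p"].tolist() == [3.0, 0.0, 0.0, 2.0, 2.0, 2.0]

    def test_detection_uses_pre_imputation_matrix(self):
        # imputation never creates "expressed" proteins
        m = matrix_from({"p": [np.nan] * 3 + [4, 4, 4]})
        prepare(m)
        assert detect_expressed(m, "A") == set()


class TestS0TTest:
    def test_identical_groups(self):
        diff, t, p = s0_t_test([10, 11, 12], [10, 11, 12], s0=0)
        assert diff == 0 and t == 0 and p == 1

    def test_textbook_pooled_value(self):
        # sp = 1, t = -3 / sqrt(2/3)
        diff, t, p = s0_t_test([10, 11, 12], [13, 14, 15], s0=0)
        assert diff == -3
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))

    def test_s0_shrinks_the_statistic(self):
        _, t0, _ = s0_t_test([10, 11, 12], [13, 14, 15], s0=0)
        _, t, _ = s0_t_test([10, 11, 12], [13, 14, 15], s0=0.15)
        assert abs(t) < abs(t0)

    def test_s0_zero_equals_classical_pooled_t(self, rng):
        """1,000 random 3-vs-3 draws vs scipy's pooled t within 1e-10."""
        for _ in range(1000):
            a = rng.normal(size=3) * rng.uniform(0.5, 3)
            b = rng.normal(size=3) + rng.uniform(-2, 2)
            diff, t, p = s0_t_test(a, b, s0=0)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert t == pytest.approx(pooled_t(a, b), abs=1e-10)

    def test_zero_variance_s0_zero_warns(self):
        with pytest.warns(UserWarning, match="infinite"):
            diff, t, p = s0_t_test([5, 5, 5], [7, 7, 7], s0=0)
        assert np.isinf(t) and p == 0


@pytest.fixture
def small_matrix(rng):
    m, truth = make_lfq(LfqSimConfig(n_proteins=300, noise_sd=0.1), seed=42)
    return m, truth


class TestPermutationVolcano:
    def test_deterministic_given_seed(self, small_matrix):
        m, _ = small_matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = differential_expression(m, "laminarin", "control", seed=9)
            r2 = differential_expression(m, "laminarin", "control", seed=9)
        pd.testing.assert_frame_equal(r1.frame, r2.frame)
        assert r1.t_cut == r2.t_cut

    def test_monotone_in_fdr(self, small_matrix):
        m, _ = small_matrix
        prev: set = set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for fdr in (0.01, 0.05, 0.2):
                res = differential_expression(m, "laminarin", "control",
                                              fdr=fdr, seed=1)
                called = set(res.frame.index[res.frame["significant"]])
                assert prev <= called
                prev = called

    def test_fdr_zero_nothing_significant(self, small_matrix):
        m, _ = small_matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = differential_expression(m, "laminarin", "control", fdr=0.0, seed=1)
        assert res.n_significant == 0

    def test_planted_effects_recovered_with_direction(self, small_matrix):
        m, truth = small_matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = differential_expression(m, "laminarin", "control", seed=3)
        frame = res.frame
        hits = frame.loc[frame["significant"]]
        affected = set(truth["affected"])
        assert len(set(hits.index) & affected) / len(affected) >= 0.9
        for pid, row in hits.iterrows():
            if pid in affected:
                want = "up" if truth["true_difference"][pid] > 0 else "down"
                assert row["direction"] == want

    def test_difference_estimates_near_truth(self):
        """Planted-effect differences within +-0.2 log2 of truth on average."""
        cfg = LfqSimConfig(n_proteins=500, noise_sd=0.2, detection_limit=10.0)
        m, truth = make_lfq(cfg, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = differential_expression(m, "laminarin", "control", seed=5)
        errs = [res.frame.loc[pid, "difference"] - d
                for pid, d in truth["true_difference"].items()]
        assert abs(np.mean(errs)) < 0.2

    def test_exhaustive_permutation_warning(self, small_matrix):
        m, _ = small_matrix
        model = TwoSampleS0Test(prepare(m), "laminarin", "control")
        with pytest.warns(UserWarning, match="exhaustive"):
            res = model.fit(n_perm=250, seed=0)
        assert res.n_perm_used == 20  # C(6,3)

    def test_summary_mentions_parameters(self, small_matrix):
        m, _ = small_matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = differential_expression(m, "laminarin", "control", seed=2)
        text = res.summary()
        assert "0.15" in text and "0.05" in text and "laminarin" in text


class TestCallDirection:
    @pytest.mark.parametrize("sig,diff,want", [
        (True, 3.2, "up"), (True, -2.0, "down"),
        (False, 5.0, "ns"), (False, -5.0, "ns"), (True, 0.0, "ns"),
    ])
    def test_rule(self, sig, diff, want):
        r = DeResult("p", diff, 1.0, 0.01, sig, "ns")
        assert call_direction([r])[0].direction == want
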