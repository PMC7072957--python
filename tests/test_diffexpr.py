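from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from mirheat import (
    Contrast,
    CountMatrix,
    ExpressionMatrix,
    make_contrast,
    screen,
    test_replicated,
    test_unreplicated,
    unique_de_union,
)
from mirheat.io import DesignError


def hypergeom_enumeration_p(a, ta, b, tb):
    """Brute-force two-sided exact conditional p: enumerate every table with
    the observed margins and sum the probabilities of those no more likely
    than the observed one. Exact integer arithmetic throughout."""
    n = a + b
    lo, hi = max(0, n - tb), min(n, ta)
    weights = {k: comb(ta, k) * comb(tb, n - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / comb(ta + tb, n)


class TestUnreplicatedExactTest:
    @pytest.mark.parametrize(
        "a,ta,b,tb,expected",
        [
            (0, 1_000_000, 0, 1_000_000, 1.0),
            (10, 1000, 10, 1000, 1.0),
        ],
    )
    def test_balanced_tables_give_p_one(self, a, ta, b, tb, expected):
        assert test_unreplicated(a, ta, b, tb) == pytest.approx(expected)

    def test_extreme_imbalance_tiny_p(self):
        p = test_unreplicated(0, 100_000, 60, 100_000)
        assert p < 1e-10
        assert p == pytest.approx(hypergeom_enumeration_p(0, 100_000, 60, 100_000), rel=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31))
    def test_matches_enumeration_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        ta, tb = int(rng.integers(1, 61)), int(rng.integers(1, 61))
        a, b = int(rng.integers(0, ta + 1)), int(rng.integers(0, tb + 1))
        assert test_unreplicated(a, ta, b, tb) == pytest.approx(
            hypergeom_enumeration_p(a, ta, b, tb), rel=1e-12, abs=1e-15
        )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31))
    def test_matches_scipy_on_large_libraries(self, seed):
        """The float path agrees with an independent implementation."""
        rng = np.random.default_rng(seed)
        ta, tb = int(rng.integers(1e5, 5e6)), int(rng.integers(1e5, 5e6))
        a, b = int(rng.integers(0, 2000)), int(rng.integers(0, 2000))
        mine = test_unreplicated(a, ta, b, tb)
        ref = fisher_exact([[a, ta - a], [b, tb - b]]).pvalue
        assert mine == pytest.approx(ref, rel=1e-6, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31))
    def test_symmetric_in_sides(self, seed):
        rng = np.random.default_rng(seed)
        ta, tb = int(rng.integers(1, 10_000)), int(rng.integers(1, 10_000))
        a, b = int(rng.integers(0, min(ta, 500) + 1)), int(rng.integers(0, min(tb, 500) + 1))
        assert test_unreplicated(a, ta, b, tb) == pytest.approx(
            test_unreplicated(b, tb, a, ta), rel=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            test_unreplicated(1, 0, 0, 10)
        with pytest.raises(ValueError):
            test_unreplicated(11, 10, 0, 10)


class TestReplicatedTest:
    def test_identical_vectors_p_one(self):
        assert test_replicated([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0
        assert test_replicated([0.0, 0.0], [0.0, 0.0]) == 1.0

    def test_separated_groups_significant(self):
        p = test_replicated([1000, 1010, 990], [10, 11, 9])
        assert p < 0.01

    def test_matches_permutation_oracle(self):
        """Welch-t p agrees in rank with an exhaustive permutation test."""
        rng = np.random.default_rng(5)
        a = rng.normal(8, 0.5, size=4)
        b = rng.normal(6, 0.5, size=4)
        p_t = test_replicated(2**a - 1, 2**b - 1)  # undone by log2(x+1)
        # exhaustive label permutations of the pooled log values
        from itertools import combinations

        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= obs - 1e-12
            total += 1
        p_perm = count / total
        assert p_t < 0.05 and p_perm < 0.05

    def test_too_few_replicates_redirects(self):
        with pytest.raises(ValueError, match="unreplicated"):
            test_replicated([1.0], [2.0, 3.0])


def _screen_setup(tpm_num, tpm_den, count_num, count_den, total=1_000_000):
    ids = [f"m{i}" for i in range(len(tpm_num))]
    tpm = pd.DataFrame({"H1": tpm_num, "T1": tpm_den}, index=ids)
    counts = pd.DataFrame({"H1": count_num, "T1": count_den}, index=ids, dtype=np.int64)
    cm = CountMatrix(counts, pd.Series([total, total], index=["H1", "T1"]))
    contrast = Contrast("SCP", "HT", ("H1",), ("T1",))
    return ExpressionMatrix(tpm), cm, contrast


class TestScreen:
    def test_fold_change_and_calls(self):
        expr, cm, contrast = _screen_setup(
            [400.0, 100.0, 400.0], [100.0, 100.0, 390.0], [400, 100, 400], [100, 100, 390]
        )
        res = screen(expr, cm, contrast)
        r0 = res.iloc[0]
        assert r0["fold_change"] == pytest.approx(401 / 101)
        assert r0["p_value"] < 0.001 and r0["call"] == "up"
        assert res.iloc[1]["call"] == "not_de"  # FC = 1
        assert res.iloc[2]["call"] == "not_de"  # FC inside (0.5, 2)

    def test_pvalue_alone_insufficient(self):
        # large counts, significant p, but FC below 2 -> not called
        expr, cm, contrast = _screen_setup([150.0], [100.0], [150_000], [100_000])
        res = screen(expr, cm, contrast)
        assert res.iloc[0]["p_value"] < 1e-10
        assert res.iloc[0]["call"] == "not_de"

    def test_all_mirnas_returned(self):
        expr, cm, contrast = _screen_setup([400.0, 1.0], [100.0, 1.0], [400, 1], [100, 1])
        assert len(screen(expr, cm, contrast)) == 2

    def test_missing_library_is_design_error(self):
        expr, cm, _ = _screen_setup([1.0], [1.0], [1], [1])
        bad = Contrast("SCP", "HT", ("H9",), ("T1",))
        with pytest.raises(DesignError, match="H9"):
            screen(expr, cm, bad)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31))
    def test_direction_antisymmetry(self, seed):
        """Swapping sides flips calls and inverts fold changes; p unchanged."""
        rng = np.random.default_rng(seed)
        n = 12
        counts = rng.integers(0, 2000, size=(n, 2))
        ids = [f"m{i}" for i in range(n)]
        cdf = pd.DataFrame(counts, index=ids, columns=["H1", "T1"]).astype(np.int64)
        cm = CountMatrix(cdf, pd.Series([1_000_000, 900_000], index=["H1", "T1"]))
        tpm = cdf / cm.library_sizes * 1e6
        expr = ExpressionMatrix(tpm)
        fwd = screen(expr, cm, Contrast("SCP", "HT", ("H1",), ("T1",)))
        rev = screen(expr, cm, Contrast("SCP", "HT", ("T1",), ("H1",)))
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)
        np.testing.assert_allclose(
            fwd["fold_change"], 1 / rev["fold_change"], rtol=1e-9
        )
        flip = {"up": "down", "down": "up", "not_de": "not_de"}
        assert [flip[c] for c in fwd["call"]] == rev["call"].tolist()

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31))
    def test_calls_satisfy_thresholds(self, seed):
        """Every returned call obeys the p and fold-change rules exactly."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3000, size=(15, 2))
        ids = [f"m{i}" for i in range(15)]
        cdf = pd.DataFrame(counts, index=ids, columns=["H1", "T1"]).astype(np.int64)
        cm = CountMatrix(cdf, pd.Series([2_000_000, 2_000_000], index=["H1", "T1"]))
        expr = ExpressionMatrix(cdf / cm.library_sizes * 1e6)
        res = screen(expr, cm, Contrast("SCP", "HT", ("H1",), ("T1",)))
        for row in res.itertuples(index=False):
            if row.call == "up":
                assert row.fold_change >= 2.0 and row.p_value <= 0.05
            elif row.call == "down":
                assert row.fold_change <= 0.5 and row.p_value <= 0.05
            else:
                assert not (
                    row.p_value <= 0.05
                    and (row.fold_change >= 2.0 or row.fold_change <= 0.5)
                )

    def test_replicated_path_used_with_replicates(self):
        ids = ["m0"]
        tpm = pd.DataFrame(
            {"H1a": [1000.0], "H1b": [990.0], "T1a": [10.0], "T1b": [11.0]}, index=ids
        )
        counts = (tpm * 1).astype(np.int64)
        cm = CountMatrix(counts, pd.Series(1_000_000, index=tpm.columns))
        contrast = Contrast("SCP", "HT", ("H1a", "H1b"), ("T1a", "T1b"))
        res = screen(ExpressionMatrix(tpm), cm, contrast)
        assert res.attrs["test"] == "replicated_log_t"
        assert res.iloc[0]["call"] == "up"

    def test_bh_adjustment_reduces_calls(self):
        rng = np.random.default_rng(3)
        n = 50
        counts = rng.poisson(200, size=(n, 2))
        counts[0] = [600, 100]
        ids = [f"m{i}" for i in range(n)]
        cdf = pd.DataFrame(counts, index=ids, columns=["H1", "T1"]).astype(np.int64)
        cm = CountMatrix(cdf, pd.Series(1_000_000, index=["H1", "T1"]))
        expr = ExpressionMatrix(cdf / cm.library_sizes * 1e6)
        raw = screen(expr, cm, Contrast("SCP", "HT", ("H1",), ("T1",)))
        adj = screen(expr, cm, Contrast("SCP", "HT", ("H1",), ("T1",)), adjust="bh")
        assert (adj["call"] != "not_de").sum() <= (raw["call"] != "not_de").sum()
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-12).all()


class TestUniqueDeUnion:
    def _res(self, stage, calls):
        rows = [
            {
                "mirna_id": m,
                "stage": stage,
                "condition": "HT",
                "mean_tpm_num": 1.0,
                "mean_tpm_den": 1.0,
                "fold_change": 1.0,
                "log2fc": 0.0,
                "p_value": 0.01,
                "p_adjusted": 0.01,
                "call": c,
            }
            for m, c in calls.items()
        ]
        return pd.DataFrame(rows)

    def test_union_with_provenance(self):
        per_stage = {
            "SCP": self._res("SCP", {"a": "up", "b": "up"}),
            "MP": self._res("MP", {"b": "up", "c": "down"}),
        }
        out = unique_de_union(per_stage)
        assert out["mirna_id"].tolist() == ["a", "b", "c"]
        b = out[out["mirna_id"] == "b"].iloc[0]
        assert b["n_stage_calls"] == 2 and "SCP:up" in b["stage_directions"]

    def test_opposing_stage_directions_kept(self):
        per_stage = {
            "MP": self._res("MP", {"miR156g-5p": "up"}),
            "MRP": self._res("MRP", {"miR156g-5p": "down"}),
        }
        out = unique_de_union(per_stage)
        assert len(out) == 1
        assert bool(out.iloc[0]["opposing_across_stages"])

    def test_not_de_rows_ignored_and_empty_error(self):
        out = unique_de_union({"SCP": self._res("SCP", {"a": "not_de"})})
        assert len(out) == 0
        with pytest.raises(ValueError):
            unique_de_union({})
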