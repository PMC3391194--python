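"""Differential expression: contrasts, BH, calls, overlap, similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirtflow import diffexpr, simulate
from sirtflow.diffexpr import Contrast


def bh_bruteforce(p):
    """Independent step-up BH oracle: sort, scale by m/rank, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_single_value_unchanged(self):
        assert diffexpr.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_example(self):
        q = diffexpr.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(diffexpr.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.adjust_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(diffexpr.adjust_bh(p), bh_bruteforce(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    def test_order_preserving(self, p):
        q = diffexpr.adjust_bh(p)
        i, j = np.argsort(p)[:2][0], np.argsort(p)[-1]
        assert q[i] <= q[j] + 1e-12


class TestFoldChange:
    def test_signed_convention(self):
        fc = diffexpr.signed_fold_change(np.array([1.0, 0.0, -1.0, 0.585]))
        assert fc[0] == pytest.approx(2.0)
        assert fc[1] == pytest.approx(1.0)
        assert fc[2] == pytest.approx(-2.0)
        assert abs(fc[3]) == pytest.approx(2 ** 0.585)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-20, max_value=20))
    def test_magnitude_at_least_one_and_sign_matches(self, lfc):
        fc = float(diffexpr.signed_fold_change(np.array([lfc]))[0])
        assert abs(fc) >= 1.0
        if lfc > 0:
            assert fc > 0
        elif lfc < 0:
            assert fc < 0


class TestContrast:
    def test_noiseless_planted_effect(self):
        truth = simulate.ExpressionTruth(n_probes=20, replicate_sd=0.0,
                                         effects={"h": {0: 1.0}}, seed=0)
        m = simulate.gen_expression_experiment(truth)
        table = diffexpr.fit_contrast(m, Contrast("h", "g"))
        row = table.loc[simulate.probe_id(0)]
        assert row["log2fc"] == pytest.approx(1.0)
        assert row["fold_change"] == pytest.approx(2.0)

    def test_null_pvalues_uniform(self):
        truth = simulate.ExpressionTruth(n_probes=10000, replicate_sd=0.25, seed=5)
        m = simulate.gen_expression_experiment(truth)
        table = diffexpr.fit_contrast(m, Contrast("h", "g"))
        from scipy import stats

        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_calls_invariant_to_row_and_column_order(self):
        truth = simulate.tnfa_truth(n_probes=300, n_up=10, n_down=5, seed=2)
        m = simulate.gen_expression_experiment(truth)
        t1 = diffexpr.fit_contrast(m, Contrast("h", "g"))
        rng = np.random.default_rng(0)
        shuffled = m.iloc[rng.permutation(len(m))]
        shuffled = shuffled[["h_3", "h_1", "h_2", "g_2", "g_1", "g_3"]
                            + [c for c in m.columns if c[0] not in "gh"]]
        t2 = diffexpr.fit_contrast(shuffled, Contrast("h", "g"))
        assert diffexpr.de_counts(t1) == diffexpr.de_counts(t2)
        assert set(t1.index[t1["call"] == "up"]) == set(t2.index[t2["call"] == "up"])

    def test_zero_variance_probe_handled(self):
        # exactly representable values so the residual variance is exactly 0
        m = pd.DataFrame(
            {"h_1": [3.0, 2.0], "h_2": [3.0, 2.0], "h_3": [3.0, 2.0],
             "g_1": [1.0, 2.0], "g_2": [1.0, 2.0], "g_3": [1.0, 2.0]},
            index=["shifted", "flat"])
        table = diffexpr.fit_contrast(m, Contrast("h", "g"))
        assert table.loc["shifted", "p"] == np.finfo(float).tiny
        assert table.loc["flat", "p"] == 1.0

    def test_not_log2_matrix_rejected(self):
        truth = simulate.ExpressionTruth(n_probes=10, seed=0, baseline_mean=100.0)
        m = simulate.gen_expression_experiment(truth)
        with pytest.raises(ValueError):
            diffexpr.fit_contrast(m, Contrast("h", "g"))


class TestCalls:
    def _table(self, fc, q):
        lfc = np.log2(np.abs(fc)) * np.sign(fc)
        return pd.DataFrame({"log2fc": lfc, "fold_change": fc, "p": q, "q": q})

    def test_boundary_fc_is_ns(self):
        t = diffexpr.call_de(self._table(np.array([1.5]), np.array([0.001])))
        assert t["call"].iloc[0] == "ns"

    def test_clear_up_call(self):
        t = diffexpr.call_de(self._table(np.array([2.0]), np.array([0.04])))
        assert t["call"].iloc[0] == "up"

    def test_raw_p_mode(self):
        tab = self._table(np.array([2.0]), np.array([0.2]))
        tab["p"] = 0.01
        assert diffexpr.call_de(tab)["call"].iloc[0] == "ns"
        assert diffexpr.call_de(tab, use_q=False)["call"].iloc[0] == "up"

    def test_planted_recovery_rate(self):
        """With strong log2 effects (|lfc| = 3) at sd 0.25, >=99% of planted
        probes are called in the right direction and empirical FDR stays
        <= 0.05.  Triplicates give only 4 degrees of freedom, so moderate
        effects sit near the BH cutoff; strong effects do not."""
        recovered, planted_total, false_disc, calls = 0, 0, 0, 0
        for seed in range(20):
            truth = simulate.tnfa_truth(n_probes=1000, n_up=40, n_down=20,
                                        effect_up=3.0, effect_down=-3.0, seed=seed)
            m = simulate.gen_expression_experiment(truth)
            table = diffexpr.fit_contrast(m, Contrast("h", "g"))
            up_true = {simulate.probe_id(i) for i in truth.planted_up("h", "g")}
            dn_true = {simulate.probe_id(i) for i in truth.planted_down("h", "g")}
            up_called = set(table.index[table["call"] == "up"])
            dn_called = set(table.index[table["call"] == "down"])
            recovered += len(up_called & up_true) + len(dn_called & dn_true)
            planted_total += len(up_true) + len(dn_true)
            false_disc += len(up_called - up_true) + len(dn_called - dn_true)
            calls += len(up_called) + len(dn_called)
        assert recovered / planted_total >= 0.99
        assert false_disc / max(calls, 1) <= 0.05


class TestOverlapAndSimilarity:
    def _calls(self, probes, up=(), down=()):
        df = pd.DataFrame(index=list(probes))
        df["call"] = "ns"
        df.loc[list(up), "call"] = "up"
        df.loc[list(down), "call"] = "down"
        return df

    def test_set_semantics(self):
        probes = [f"p{i}" for i in range(6)]
        a = self._calls(probes, up=["p1", "p2", "p3"], down=["p5"])
        b = self._calls(probes, up=["p2", "p3", "p4"], down=["p5"])
        ov = diffexpr.overlap_profiles(a, b)
        assert ov.up == {"p2", "p3"} and ov.down == {"p5"}

    def test_disjoint_empty(self):
        probes = [f"p{i}" for i in range(4)]
        ov = diffexpr.overlap_profiles(self._calls(probes, up=["p0"]),
                                       self._calls(probes, up=["p1"]))
        assert ov.n_up == 0 and ov.n_down == 0

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.overlap_profiles(self._calls(["a"]), self._calls(["b"]))

    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        (set("abcdefghij"), set("abcde"), 0.5),
        ({"x"}, {"y"}, 0.0),
    ])
    def test_containment_similarity(self, a, b, expected):
        assert diffexpr.profile_similarity(a, b) == pytest.approx(expected)

    def test_jaccard_mode_and_empty_rejected(self):
        assert diffexpr.profile_similarity({"a", "b"}, {"b", "c"},
                                           method="jaccard") == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            diffexpr.profile_similarity(set(), {"a"})
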