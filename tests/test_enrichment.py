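"""Enrichment: hypergeometric over-connectivity and PAGE scoring."""

import math

import numpy as np
import pytest
from scipy import stats

from sirtflow import enrichment, simulate
from sirtflow.enrichment import page_score, tf_connectivity
from sirtflow.simulate import RegulonDB, RegulonTruth


def hypergeom_tail_enumerated(k, big_n, r, n, upper=True):
    """Exhaustive-enumeration oracle for small universes: sum the pmf
    C(r,x)*C(N-r,n-x)/C(N,n) over the tail."""
    denom = math.comb(big_n, n)
    xs = range(k, min(r, n) + 1) if upper else range(0, k + 1)
    return sum(math.comb(r, x) * math.comb(big_n - r, n - x) for x in xs
               if n - x <= big_n - r) / denom


def db_with(big_n, specs, query_size, seed=0):
    truth = RegulonTruth(universe_n=big_n, tf_specs=tuple(specs), query_size=query_size,
                         seed=seed)
    return simulate.gen_regulon_db(truth)


class TestConnectivity:
    def test_small_universe_hand_enumeration(self):
        # N=10, R=4, n=5, k=3: expected 2.0, upper tail 66/252
        db, query = db_with(10, [("TF", 4, 3)], 5)
        (row,) = tf_connectivity(query, db)
        assert row.expected == pytest.approx(2.0)
        assert row.p == pytest.approx(66 / 252, abs=1e-12)

    def test_tail_probability_matches_enumeration_many_cases(self):
        for big_n in (10, 20, 30):
            for r in (2, big_n // 3, big_n // 2):
                for n in (3, big_n // 2):
                    for k in range(0, min(r, n) + 1):
                        if r - k > big_n - n:
                            continue
                        db, query = db_with(big_n, [("TF", r, k)], n)
                        (row,) = tf_connectivity(query, db)
                        upper = row.z >= 0
                        oracle = hypergeom_tail_enumerated(k, big_n, r, n, upper=upper)
                        assert row.p == pytest.approx(oracle, abs=1e-12), (big_n, r, n, k)

    def test_overlap_at_expectation_gives_zero_z(self):
        # N=100, n=50, R=10 -> expected exactly 5
        db, query = db_with(100, [("TF", 10, 5)], 50)
        (row,) = tf_connectivity(query, db)
        assert row.z == pytest.approx(0.0, abs=1e-12)
        assert row.ratio == pytest.approx(1.0)

    def test_z_antisymmetric_about_expectation(self):
        # expected = 5; k = 8 and k = 2 are mirror images
        db_hi, q_hi = db_with(100, [("TF", 10, 8)], 50)
        db_lo, q_lo = db_with(100, [("TF", 10, 2)], 50)
        z_hi = tf_connectivity(q_hi, db_hi)[0].z
        z_lo = tf_connectivity(q_lo, db_lo)[0].z
        assert z_hi == pytest.approx(-z_lo, rel=1e-12)
        assert z_hi > 0 > z_lo

    def test_negative_z_uses_lower_tail(self):
        db, query = db_with(30, [("TF", 15, 2)], 15)
        (row,) = tf_connectivity(query, db)
        assert row.z < 0
        assert row.p == pytest.approx(
            hypergeom_tail_enumerated(2, 30, 15, 15, upper=False), abs=1e-12)

    def test_zero_variance_flagged(self):
        db = RegulonDB(universe_n=10, regulons={"ALL": frozenset(
            simulate.gene_id(i) for i in range(10))})
        query = frozenset(simulate.gene_id(i) for i in range(4))
        (row,) = tf_connectivity(query, db)
        assert not row.z_defined and math.isnan(row.z)

    def test_empty_query_rejected(self):
        db, _ = db_with(20, [("TF", 5, 2)], 10)
        with pytest.raises(ValueError):
            tf_connectivity(frozenset(), db)


@pytest.fixture(scope="module")
def table():
    db, query = simulate.gen_regulon_db(simulate.reference_regulon_truth(seed=0))
    return {r.tf: r for r in tf_connectivity(query, db)}


class TestWorkedExampleTable:
    """The NF-kB worked example: 12 regulators of a 200-gene profile in a
    22651-gene database; every statistic is checked at printed precision."""

    # (name, R, k, expected, ratio, p, z) as reported for the reference profile
    ROWS = [
        ("RelA", 451, 47, 3.982, 11.8, 1.011e-36, 21.87),
        ("c-Rel", 330, 37, 2.914, 12.7, 5.056e-30, 20.2),
        ("NF-kB1", 200, 29, 1.766, 16.42, 6.663e-27, 20.68),
        ("SP1", 2410, 57, 21.28, 2.679, 1.873e-12, 8.228),
        ("RelB", 41, 10, 0.362, 27.62, 2.030e-12, 16.1),
        ("c-Jun", 475, 22, 4.194, 5.245, 2.641e-10, 8.826),
        ("CREB1", 1024, 32, 9.042, 3.539, 4.662e-10, 7.848),
        ("EGR1", 587, 24, 5.183, 4.631, 4.826e-10, 8.412),
        ("ETS1", 462, 19, 4.079, 4.658, 3.155e-08, 7.497),
        ("STAT3", 373, 17, 3.293, 5.162, 3.969e-08, 7.649),
        ("NF-kB p65/p65", 24, 6, 0.2119, 28.31, 5.183e-08, 12.64),
        ("NF-kB2", 44, 7, 0.3885, 18.02, 1.095e-07, 10.66),
    ]

    @pytest.mark.parametrize("name,r,k,expected,ratio,p,z",
                             ROWS, ids=[r[0] for r in ROWS])
    def test_row_statistics_at_printed_precision(self, table, name, r, k,
                                                 expected, ratio, p, z):
        row = table[name]
        assert row.actual == k and row.r == r
        assert row.expected == pytest.approx(expected, rel=5e-4)
        assert row.ratio == pytest.approx(ratio, rel=5e-3)
        assert row.z == pytest.approx(z, rel=5e-3)
        assert row.p == pytest.approx(p, rel=5e-3)

    def test_rows_sorted_by_p(self, table):
        ps = [r.p for r in table.values()]
        db, query = simulate.gen_regulon_db(simulate.reference_regulon_truth(seed=0))
        rows = tf_connectivity(query, db)
        assert [r.p for r in rows] == sorted(ps)


class TestPage:
    def test_member_mean_equal_background_zero_z(self):
        allv = np.arange(10, dtype=float)
        row = page_score([4.5, 4.5], allv)
        assert row.z == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_direct_formula(self):
        rng = np.random.default_rng(1)
        allv = rng.normal(0, 1, 100000)
        mu, sigma = allv.mean(), allv.std()
        row = page_score([mu + 0.5 * sigma] * 4, allv)
        assert row.z == pytest.approx(0.5 * 2.0, rel=1e-9)  # (0.5 sigma)*sqrt(4)/sigma

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        allv = rng.normal(0, 1, 2000)
        member = allv[:25]
        z1 = page_score(member, allv).z
        z2 = page_score(3.0 * member + 7.0, 3.0 * allv + 7.0).z
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_null_sets_standard_normal(self):
        rng = np.random.default_rng(3)
        allv = rng.normal(0, 1, 5000)
        zs = [page_score(rng.choice(allv, 20, replace=False), allv).z
              for _ in range(2000)]
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            page_score([1.0], [1.0] * 10)

    def test_page_table_bookkeeping(self):
        import pandas as pd

        fc = pd.Series({"g1": 2.0, "g2": 2.0, "g3": 0.0, "g4": -1.0, "g5": 1.0})
        table = enrichment.page_table(
            fc, {"up_set": ["g1", "g2", "g_absent"], "null_set": ["g3", "g4"]},
            significant=["g1", "g5"])
        up = table[table["pathway"] == "up_set"].iloc[0]
        assert up["m"] == 2  # g_absent is not on the chip
        assert up["n_significant_members"] == 1
        assert (table["q"] >= table["p"] - 1e-15).all()
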