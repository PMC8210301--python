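import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ribometh import (
    compare_delta_sets,
    ddcq_fold,
    delta_rms,
    deviation_from_average,
    differential_table,
    significance_class,
    site_test,
    spearman,
    summed_delta,
)


def scores_frame(rows):
    """rows: (sample, replicate, site_id, score)"""
    return pd.DataFrame(rows, columns=["sample", "replicate", "site_id", "score"])


class TestSiteTest:
    def test_identical_groups(self):
        t, p = site_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_worked_triples(self):
        t, p = site_test([0.90, 0.92, 0.94], [0.80, 0.82, 0.84])
        assert t == pytest.approx(6.1237, abs=1e-4)
        assert p == pytest.approx(0.00360, abs=1e-5)

    def test_pooled_variance_closed_form(self):
        rng = np.random.default_rng(71)
        a, b = rng.normal(size=5), rng.normal(1, 2, size=7)
        t, p = site_test(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = 2 * sps.t.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_equal_constant_groups_convention(self):
        assert site_test([5, 5, 5], [5, 5]) == (0.0, 1.0)

    def test_too_small_groups_flagged_nan(self):
        t, p = site_test([1.0], [1, 2, 3])
        assert math.isnan(t) and math.isnan(p)

    def test_welch_flag_differs_under_unequal_variance(self):
        a = [0.1, 0.2, 0.3, 0.4]
        b = [0.0, 2.0, 4.0, 9.0]
        assert site_test(a, b, welch=True)[1] != site_test(a, b)[1]


class TestSignificanceClass:
    @pytest.mark.parametrize(
        "p,cls",
        [
            (0.04, "*"),
            (0.009, "**"),
            (0.0005, "***"),
            (0.05, "ns"),  # strict inequality at the boundary
            (0.01, "*"),
            (0.001, "**"),
            (0.5, "ns"),
            (0.0, "***"),
            (1.0, "ns"),
        ],
    )
    def test_thresholds(self, p, cls):
        assert significance_class(p) == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_class(1.5)


class TestDeltaRMS:
    def test_sample_equals_control_gives_zero(self):
        rows = [(s, r, "X", 0.8) for s in ("c1", "c2", "t1") for r in (1, 2)]
        df = delta_rms(scores_frame(rows), ["c1", "c2"])
        assert (df["delta"] == 0).all()

    def test_worked_arithmetic(self):
        rows = [("c1", 1, "X", 0.82), ("t1", 1, "X", 0.62)]
        df = delta_rms(scores_frame(rows), ["c1"])
        assert df["delta"].iloc[0] == pytest.approx(-0.20)

    def test_no_shared_sites_errors(self):
        rows = [("c1", 1, "X", 0.8), ("t1", 1, "Y", 0.6)]
        with pytest.raises(ValueError):
            delta_rms(scores_frame(rows), ["c1"])

    def test_invalid_records_excluded(self):
        df = scores_frame([("c1", 1, "X", 0.8), ("t1", 1, "X", 0.0)])
        df["valid"] = [True, False]
        with pytest.raises(ValueError):
            delta_rms(df, ["c1"])


class TestDifferentialTable:
    def test_classes_and_direction(self):
        rows = []
        for r in (1, 2, 3):
            rows += [("c1", r, "X", 0.90 + 0.01 * r), ("c1", r, "Y", 0.5)]
            rows += [("t1", r, "X", 0.60 + 0.01 * r), ("t1", r, "Y", 0.5)]
        out = differential_table(scores_frame(rows), ["c1"])
        x = out[out["site_id"] == "X"].iloc[0]
        assert x["direction"] == "hypo"
        assert x["delta"] == pytest.approx(-0.30)
        assert x["significance"] in ("**", "***")
        y = out[out["site_id"] == "Y"].iloc[0]
        assert y["significance"] == "ns" and y["delta"] == 0


class TestDeviationFromAverage:
    def test_identical_panel_zero(self):
        rows = [(s, r, "X", 0.7) for s in "abc" for r in (1, 2)]
        out = deviation_from_average(scores_frame(rows))
        assert np.allclose(out["deviation"], 0.0, atol=1e-12)

    def test_two_sample_arithmetic(self):
        rows = [("a", 1, "X", 0.9), ("b", 1, "X", 0.7)]
        out = deviation_from_average(scores_frame(rows)).set_index("sample")
        assert out.loc["a", "deviation"] == pytest.approx(0.1)
        assert out.loc["b", "deviation"] == pytest.approx(-0.1)

    def test_deviations_center_to_zero(self):
        rng = np.random.default_rng(73)
        rows = [(f"s{i}", r, site, float(rng.uniform(0, 1)))
                for i in range(4) for r in (1, 2, 3) for site in ("X", "Y", "Z")]
        out = deviation_from_average(scores_frame(rows))
        sums = out.groupby("site_id")["deviation"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_incomplete_sites_dropped(self):
        rows = [("a", 1, "X", 0.9), ("b", 1, "X", 0.7), ("a", 1, "Y", 0.5)]
        out = deviation_from_average(scores_frame(rows))
        assert set(out["site_id"]) == {"X"}


class TestSummedDelta:
    def _deltas(self):
        return pd.DataFrame(
            dict(sample=["t1"] * 3 + ["t2"] * 3,
                 site_id=["U354", "C1440", "G4593"] * 2,
                 delta=[-0.1, -0.2, 0.05, 0.0, 0.0, 0.0])
        )

    def test_all_zero(self):
        assert summed_delta(self._deltas())["t2"] == 0.0

    def test_subset(self):
        s = summed_delta(self._deltas(), ["U354", "C1440"])
        assert s["t1"] == pytest.approx(-0.3)

    def test_all_equals_column_sum(self):
        d = self._deltas()
        s = summed_delta(d, "ALL")
        for sample, grp in d.groupby("sample"):
            assert s[sample] == pytest.approx(grp["delta"].sum())

    def test_missing_site_named_in_error(self):
        with pytest.raises(KeyError, match="NOPE"):
            summed_delta(self._deltas(), ["NOPE"])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3], [2, 4, 9]).rho == pytest.approx(1.0)

    def test_worked_example(self):
        r = spearman([1, 2, 3], [3, 1, 2])
        assert r.rho == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(74)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1 = spearman(x, y)
        r2 = spearman(np.exp(x), y**3)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_permutation_oracle(self, n):
        rng = np.random.default_rng(75 + n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_ref = np.corrcoef(rx, ry)[0, 1]
        rhos = [np.corrcoef(rx, np.array(ry)[list(p)])[0, 1]
                for p in itertools.permutations(range(n))]
        p_ref = float(np.mean(np.abs(rhos) >= abs(rho_ref) - 1e-12))
        assert res.rho == pytest.approx(rho_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(76)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_use_midranks(self):
        x = [1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
        y = [2, 1, 3, 3, 5, 6, 8, 7, 9, 10, 12, 11]
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_all_tied_vector_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan], [2, 4, 9, 1])
        assert res.n == 3 and res.rho == pytest.approx(1.0)


class TestCompareDeltaSets:
    def _tbl(self, sites, deltas):
        return pd.DataFrame(dict(site_id=sites, delta=deltas))

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError):
            compare_delta_sets(self._tbl(["A"], [0.1]), self._tbl(["B"], [0.2]))

    def test_subset_join_cardinality(self):
        a = self._tbl(["A", "B"], [0.1, 0.2])
        b = self._tbl(["A", "B", "C"], [0.3, 0.4, 0.5])
        joined, only_a, only_b = compare_delta_sets(a, b)
        assert len(joined) == 2 and only_a == [] and only_b == ["C"]

    def test_self_join_identity(self):
        a = self._tbl(["A", "B"], [0.1, -0.2])
        joined, *_ = compare_delta_sets(a, a)
        assert (joined["delta_a"] == joined["delta_b"]).all()


class TestDDCq:
    def test_zero_ddcq_gives_unit_fold(self):
        assert ddcq_fold(20, 15, 20, 15) == 1.0

    def test_worked_example(self):
        assert ddcq_fold(20, 15, 22, 15) == pytest.approx(4.0)

    def test_swap_inverts_fold(self):
        f = ddcq_fold(20.3, 15.1, 22.8, 15.6)
        g = ddcq_fold(22.8, 15.6, 20.3, 15.1)
        assert f * g == pytest.approx(1.0)

    def test_missing_cq_errors(self):
        with pytest.raises(ValueError):
            ddcq_fold(float("nan"), 15, 22, 15)
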