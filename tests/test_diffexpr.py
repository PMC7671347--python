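"""RPM, expressed filter, normalisation, BH, and the NB Wald test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyploid_diel.diffexpr import (
    bh_fdr,
    compute_rpm,
    expressed_filter,
    nb_wald_test,
    per_timepoint_de,
    rpm_matrix,
    size_factors,
    summarize_deg,
)
from tests.conftest import make_meta


def bh_bruteforce(p):
    """Independent step-up enumeration: adj_i = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestRpm:
    @pytest.mark.parametrize(
        "count,total,expected", [(50, 1e6, 50.0), (0, 123.0, 0.0), (10, 2e6, 5.0)]
    )
    def test_values(self, count, total, expected):
        assert compute_rpm(count, total) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            compute_rpm(5, 0)

    def test_matrix_uses_supplied_totals_not_column_sums(self):
        counts = pd.DataFrame({"s1": [10, 10], "s2": [10, 10]}, index=["g1", "g2"])
        totals = pd.Series({"s1": 1e6, "s2": 2e6})
        rpm = rpm_matrix(counts, totals)
        assert rpm.loc["g1", "s1"] == 10.0 and rpm.loc["g1", "s2"] == 5.0

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        totals = pd.Series(1e6, index=list("abcd"))
        shuffled = counts.sample(frac=1, random_state=1)
        pd.testing.assert_frame_equal(
            rpm_matrix(counts, totals).loc[shuffled.index],
            rpm_matrix(shuffled, totals),
        )


class TestExpressedFilter:
    def _rpm(self, rows):
        meta = make_meta("P1", hours=[2.0, 6.0], n_reps=3)
        return pd.DataFrame(rows, columns=meta["sample_id"],
                            index=[f"g{i}" for i in range(len(rows))]), meta

    def test_all_replicates_at_one_time_is_expressed(self):
        rpm, meta = self._rpm([[1.2, 1.5, 1.0, 0.0, 0.0, 0.0]])
        assert expressed_filter(rpm, meta).all()

    def test_one_failing_replicate_at_every_time_is_not_expressed(self):
        rpm, meta = self._rpm([[1.2, 0.9, 1.5, 1.2, 0.9, 1.5]])
        assert not expressed_filter(rpm, meta).any()

    def test_all_zero_not_expressed(self):
        rpm, meta = self._rpm([[0.0] * 6])
        assert not expressed_filter(rpm, meta).any()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_has_double_factor(self):
        # 5-gene toy: scaling one column by 2 scales its factor by 2
        base = np.array([10, 50, 100, 200, 400])
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = size_factors(counts)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, (30, 4)), columns=list("abcd"))
        shuffled = counts.sample(frac=1, random_state=3)
        pd.testing.assert_series_equal(size_factors(counts), size_factors(shuffled))

    def test_fallback_when_no_all_nonzero_gene(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        sf = size_factors(counts)
        assert (sf > 0).all()


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == 0.2

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_bruteforce_stepup(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_bruteforce(pvals))


class TestNbWaldTest:
    def _frames(self, a, b):
        genes = [f"g{i}" for i in range(a.shape[0])]
        return (pd.DataFrame(a, index=genes, columns=["a1", "a2", "a3"]),
                pd.DataFrame(b, index=genes, columns=["b1", "b2", "b3"]))

    def test_identical_groups_give_null_result(self):
        a, b = self._frames(np.full((3, 3), 100), np.full((3, 3), 100))
        res = nb_wald_test(a, b)
        assert np.allclose(res["lfc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_all_zero_gene_convention(self):
        a, b = self._frames(np.array([[0, 0, 0], [100, 90, 110]]),
                            np.array([[0, 0, 0], [100, 95, 105]]))
        res = nb_wald_test(a.iloc[:, :3], b.iloc[:, :3])
        assert res["lfc"].iloc[0] == 0.0 and res["pvalue"].iloc[0] == 1.0

    def test_fewer_than_two_replicates_raises(self):
        a, b = self._frames(np.full((2, 3), 10), np.full((2, 3), 10))
        with pytest.raises(ValueError):
            nb_wald_test(a[["a1"]], b)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        n = 4000
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), n))
        r = 1 / 0.1
        a, b = self._frames(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 3)),
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 3)),
        )
        res = nb_wald_test(a, b)
        assert (res["pvalue"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        assert (res["pvalue"] < 0.01).mean() == pytest.approx(0.01, abs=0.02)

    def test_power_on_planted_fourfold_changes(self):
        rng = np.random.default_rng(7)
        n_null, n_sig = 2000, 500
        mu = np.exp(rng.uniform(np.log(500), np.log(2000), n_null + n_sig))
        mu_b = mu.copy()
        mu_b[n_null:] *= 4.0
        r = 1 / 0.05
        a, b = self._frames(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(len(mu), 3)),
            rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(len(mu), 3)),
        )
        res = nb_wald_test(a, b)
        assert res["significant"].iloc[n_null:].mean() >= 0.9

    def test_agrees_with_deseq2_on_small_fixture(self):
        """Independent cross-check against the reference NB Wald engine."""
        rng = np.random.default_rng(0)
        n = 200
        mu = np.exp(rng.uniform(np.log(100), np.log(2000), n))
        lfc_true = np.zeros(n)
        lfc_true[:60] = rng.choice([-1, 1], 60) * rng.uniform(1, 2, 60)
        r = 1 / 0.05
        a, b = self._frames(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, 3)),
            rng.negative_binomial(
                r, r / (r + (mu * 2.0**lfc_true)[:, None]), size=(n, 3)
            ),
        )
        res = nb_wald_test(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            counts = pd.concat([a, b], axis=1).T
            meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                                index=counts.index)
            dds = DeseqDataSet(counts=counts, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            ds.summary()
        ref = ds.results_df.loc[res.index]
        assert np.corrcoef(res["lfc"], ref["log2FoldChange"])[0, 1] >= 0.99
        mine = set(res.index[res["fdr"] < 0.01])
        theirs = set(ref.index[ref["padj"] < 0.01])
        assert len(mine & theirs) / max(len(mine | theirs), 1) >= 0.9


class TestSummarizeDeg:
    def _results(self, spec):
        # spec: {hour: (sig_mask, lfc)} over genes g0..g2
        out = {}
        for t, (sig, lfc) in spec.items():
            out[t] = pd.DataFrame(
                {"lfc": lfc, "significant": sig},
                index=["g0", "g1", "g2"],
            )
        return out

    def test_directions_and_unclassified(self):
        res = self._results({
            10.0: ([True, True, False], [-1.0, 2.0, 0.1]),
            22.0: ([True, True, False], [-2.0, -1.0, 0.2]),
        })
        deg = summarize_deg(res)
        assert deg.loc["g0", "direction"] == "up_A"      # negative lfc = A higher
        assert deg.loc["g1", "direction"] == "unclassified"
        assert "g2" not in deg.index

    def test_partition_identity_on_synthetic_contrast(self, small_bundle):
        _, _, libs, counts, meta = small_bundle
        res = per_timepoint_de(counts["P1"], counts["P2"], meta)
        deg = summarize_deg(res)
        vc = deg["direction"].value_counts()
        assert vc.sum() == len(deg)
        assert set(vc.index) <= {"up_A", "up_B", "unclassified"}
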