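import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest, rankdata

from tcrtrack.diffexp import (
    adjust_bh,
    classify,
    cross_tabulate,
    differential_expansion,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    exact_test,
    nb_exact_pvalue,
    overlap_sets,
    quantile_adjust,
    tmm_factors,
)
from tcrtrack.simulate import SimConfig, simulate_experiment


def _nb_counts(rng, mu, phi, shape):
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + np.broadcast_to(mu, shape)))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_oracle_factor(y, n, yr, nr):
    """Independent brute-force trimmed weighted mean of M-values (one sample
    against the reference, before geometric-mean rescaling)."""
    M, A, w = [], [], []
    for yi, yri in zip(y, yr):
        if yi > 0 and yri > 0:
            M.append(np.log2((yi / n) / (yri / nr)))
            A.append(0.5 * np.log2((yi / n) * (yri / nr)))
            w.append(1.0 / ((n - yi) / (n * yi) + (nr - yri) / (nr * yri)))
    M, A, w = np.array(M), np.array(A), np.array(w)
    m = len(M)
    keep = np.ones(m, dtype=bool)
    lo_m, hi_m = np.floor(m * 0.3) + 1, m - np.floor(m * 0.3)
    lo_a, hi_a = np.floor(m * 0.05) + 1, m - np.floor(m * 0.05)
    rm, ra = rankdata(M), rankdata(A)
    keep &= (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        y = np.tile(np.array([[5], [9], [2], [40]]), (1, 3))
        np.testing.assert_allclose(tmm_factors(y), 1.0)

    def test_pure_depth_change_gives_equal_factors(self):
        y = np.column_stack([np.array([5, 9, 2, 40]), 2 * np.array([5, 9, 2, 40])])
        np.testing.assert_allclose(tmm_factors(y), 1.0, rtol=1e-12)

    def test_five_clone_toy_matches_handrolled_oracle(self):
        y = np.array([
            [10, 500],   # dominant in sample B
            [20, 22],
            [30, 28],
            [40, 45],
            [50, 52],
        ], dtype=float)
        lib = y.sum(axis=0)
        factors = tmm_factors(y, lib)
        raw = np.array([1.0, _tmm_oracle_factor(y[:, 1], lib[1], y[:, 0], lib[0])])
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(factors, expected, atol=1e-6)

    def test_matches_edger(self, tmp_path):
        rng = np.random.default_rng(42)
        y = rng.negative_binomial(2, 0.1, (60, 4)).astype(float)
        y[y.sum(axis=1) == 0] += 1
        np.savetxt(tmp_path / "counts.tsv", y, fmt="%d", delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.table("counts.tsv"))
            writeLines(sprintf("%.12f", calcNormFactors(y, method="TMM")), "tmm.txt")
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        f_edger = np.loadtxt(tmp_path / "tmm.txt")
        np.testing.assert_allclose(tmm_factors(y), f_edger, atol=1e-8)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    GROUPS = ["A"] * 3 + ["B"] * 3

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(2.5, 1.0, 2000)
        y = rng.poisson(np.broadcast_to(mu[:, None], (2000, 6)))
        assert estimate_common_dispersion(y, self.GROUPS) < 0.01

    def test_flat_likelihood_returns_lower_bound_with_warning(self):
        y = np.array([[5, 5, 5, 5]])
        with pytest.warns(UserWarning, match="lower bound"):
            phi = estimate_common_dispersion(y, ["A", "A", "B", "B"])
        assert phi == pytest.approx(1e-6, rel=0.2)

    def test_no_replication_is_an_error(self):
        with pytest.raises(ValueError, match="replication"):
            estimate_common_dispersion(np.array([[3, 9]]), ["A", "B"])

    def test_matches_edger_common_dispersion(self, tmp_path):
        rng = np.random.default_rng(7)
        mu = rng.lognormal(2.0, 1.0, 300)
        y = _nb_counts(rng, mu[:, None], 0.3, (300, 4))
        y[y.sum(axis=1) == 0] += 1
        np.savetxt(tmp_path / "counts.tsv", y, fmt="%d", delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.table("counts.tsv"))
            d <- estimateCommonDisp(DGEList(counts=y, group=c(1,1,2,2)))
            writeLines(sprintf("%.10f", d$common.dispersion), "disp.txt")
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        phi_edger = float((tmp_path / "disp.txt").read_text())
        phi = estimate_common_dispersion(y, ["A", "A", "B", "B"])
        assert phi == pytest.approx(phi_edger, rel=0.05)

    def test_tagwise_shrinkage_limits(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(2.5, 0.8, 200)
        y = _nb_counts(rng, mu[:, None], 0.2, (200, 6))
        y[y.sum(axis=1) == 0] += 1
        phi = estimate_common_dispersion(y, self.GROUPS)
        heavy = estimate_tagwise_dispersion(y, self.GROUPS, phi, prior_weight=1e9)
        np.testing.assert_allclose(heavy, phi, atol=1e-4)

        none = estimate_tagwise_dispersion(y, self.GROUPS, phi, prior_weight=0.0)
        # prior weight 0 equals the per-clone grid ML (oracle: per-clone argmax)
        from tcrtrack.diffexp import _conditional_loglik, dispersion_grid, group_columns

        pseudo, _ = quantile_adjust(y.astype(float), self.GROUPS, y.sum(axis=0).astype(float), phi)
        grid = dispersion_grid(phi)
        cl = np.column_stack([
            _conditional_loglik(pseudo, group_columns(self.GROUPS), p) for p in grid
        ])
        np.testing.assert_allclose(none, grid[np.argmax(cl, axis=1)])

    def test_outlier_clone_gets_larger_dispersion(self):
        rng = np.random.default_rng(2)
        mu = np.full(100, 50.0)
        y = rng.poisson(np.broadcast_to(mu[:, None], (100, 6))).astype(float)
        y[0] = [5, 200, 20, 10, 300, 2]  # far noisier than the rest
        phi = estimate_common_dispersion(y, self.GROUPS)
        phig = estimate_tagwise_dispersion(y, self.GROUPS, phi, prior_weight=10.0)
        assert phig[0] > phi
        assert np.median(phig[1:]) <= phig[0]


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


class TestExactTest:
    def test_symmetric_mode_gives_p_one(self):
        assert nb_exact_pvalue(12, 12, 3, 3, 0.1) == 1.0

    def test_binomial_oracle_small(self):
        for z in (5, 17, 40):
            for za in range(z + 1):
                assert nb_exact_pvalue(za, z - za, 3, 3, 0.0) == pytest.approx(
                    binomtest(za, z, 0.5).pvalue, abs=1e-12
                )

    def test_more_extreme_partition_has_smaller_p(self):
        # brute-force monotonicity over all partitions of z = 20
        for phi in (0.0, 0.05, 0.3):
            ps = [nb_exact_pvalue(a, 20 - a, 3, 3, phi) for a in range(21)]
            assert ps[0] < ps[8]
            for a in range(10):
                assert ps[a] <= ps[a + 1] + 1e-12
            np.testing.assert_allclose(ps, ps[::-1])  # symmetric groups

    def test_exchangeability(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(20, (50, 3))
        b = rng.poisson(35, (50, 3))
        p1 = exact_test(a, b, 0.1)
        p2 = exact_test(b, a, 0.1)
        np.testing.assert_allclose(p1, p2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_test(np.array([[-1, 2, 3]]), np.array([[1, 2, 3]]), 0.1)

    def test_matches_edger_small_p(self, tmp_path):
        rng = np.random.default_rng(8)
        y = rng.negative_binomial(2, 0.15, (40, 4)).astype(float)
        y[y.sum(axis=1) == 0] += 1
        np.savetxt(tmp_path / "counts.tsv", y, fmt="%d", delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.table("counts.tsv"))
            p <- edgeR:::exactTestBySmallP(y[,1:2], y[,3:4], dispersion=0.15)
            writeLines(sprintf("%.12f", p), "pvals.txt")
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        p_edger = np.loadtxt(tmp_path / "pvals.txt")
        p_mine = exact_test(y[:, :2], y[:, 2:], 0.15)
        np.testing.assert_allclose(p_mine, p_edger, atol=1e-6)


# ---------------------------------------------------------------------------
# BH and classification
# ---------------------------------------------------------------------------


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_bh(np.ones(5)), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases_and_capped(self, ps):
        p = np.array(ps)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        # independent step-up oracle
        n = len(p)
        order = np.argsort(p, kind="stable")
        stepped = p[order] * n / np.arange(1, n + 1)
        expected = np.minimum(1.0, np.minimum.accumulate(stepped[::-1])[::-1])
        oracle = np.empty(n)
        oracle[order] = expected
        np.testing.assert_allclose(adj, oracle, atol=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "fc,adj,expected",
        [
            (1.0, 0.01, "DOE"),
            (0.5, 0.001, "NDE"),    # below the log2 1.5 ~ 0.585 gate
            (-2.0, 0.2, "NDE"),     # significance gate
            (-1.0, 0.01, "DUE"),
            (np.log2(1.5), 0.01, "NDE"),  # strict inequality at the cut
            (1.0, 0.05, "NDE"),           # strict inequality on alpha
        ],
    )
    def test_cutoff_rules(self, fc, adj, expected):
        assert classify(np.array([fc]), np.array([adj]))[0] == expected

    def test_representation_labels(self):
        out = classify(np.array([2.0, -2.0, 0.0]), np.array([0.01, 0.01, 0.01]),
                       contrast_kind="representation")
        assert out.tolist() == ["DOR", "DUR", "NDR"]


# ---------------------------------------------------------------------------
# cross-tables and overlaps
# ---------------------------------------------------------------------------


def reference_crosstable_labels() -> tuple[pd.Series, pd.Series]:
    """Label fixture realizing the reference day-10 cross-table margins:
    548 DOE of which 48 DOR / 392 NDR / 108 DUR; 68 DOR of which 48 DOE,
    18 NDE, 2 not detected in the expansion contrast."""
    exp, rep = {}, {}
    doe = [f"doe{i}" for i in range(548)]
    nde = [f"nde{i}" for i in range(2000)]
    for c in doe:
        exp[c] = "DOE"
    for c in nde:
        exp[c] = "NDE"
    for c in doe[:48]:
        rep[c] = "DOR"
    for c in doe[48:440]:
        rep[c] = "NDR"
    for c in doe[440:548]:
        rep[c] = "DUR"
    for c in nde[:18]:
        rep[c] = "DOR"
    for c in nde[18:]:
        rep[c] = "NDR"
    rep["extra0"] = "DOR"
    rep["extra1"] = "DOR"
    return pd.Series(exp), pd.Series(rep)


class TestCrossTable:
    def test_identical_labels_diagonal(self):
        lab = pd.Series({"a": "DOE", "b": "NDE", "c": "DUE"})
        ct = cross_tabulate(lab, lab.map({"DOE": "DOR", "NDE": "NDR", "DUE": "DUR"}))
        off = ct.counts.to_numpy() - np.diag(np.diag(ct.counts.to_numpy()))
        assert off.sum() == 0

    def test_disjoint_universes_all_nd_margins(self):
        a = pd.Series({"a": "DOE"})
        b = pd.Series({"x": "DOR"})
        ct = cross_tabulate(a, b)
        assert ct.counts.loc["DOE", "ND"] == 1
        assert ct.counts.loc["ND", "DOR"] == 1
        assert ct.counts.to_numpy().sum() == 2

    def test_duplicate_ids_rejected(self):
        dup = pd.Series(["DOE", "NDE"], index=["a", "a"])
        with pytest.raises(ValueError):
            cross_tabulate(dup, pd.Series({"a": "DOR"}))

    def test_reference_margins_percentages(self):
        exp, rep = reference_crosstable_labels()
        dor_rows = cross_tabulate(rep, exp, kind_a="representation",
                                  kind_b="expansion")
        assert dor_rows.counts.loc["DOR"].tolist() == [48, 18, 0, 2]
        assert dor_rows.row_percent.loc["DOR", "DOE"] == 71
        doe_rows = cross_tabulate(exp, rep)
        assert doe_rows.counts.loc["DOE"].sum() == 548
        assert doe_rows.row_percent.loc["DOE", "DUR"] == 20


class TestOverlap:
    def test_two_sets_regions(self):
        df = overlap_sets({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        counts = {(bool(r.x), bool(r.y)): r["count"] for _, r in df.iterrows()}
        assert counts == {(True, False): 1, (True, True): 2, (False, True): 1}

    def test_identical_sets_concentrate(self):
        s = {"a", "b"}
        df = overlap_sets({"x": set(s), "y": set(s), "z": set(s)})
        assert len(df) == 1 and df.iloc[0]["count"] == 2

    def test_per_set_totals_match_cardinality(self):
        sets = {"p": set(range(10)), "q": set(range(5, 20)), "r": set(range(15, 40))}
        df = overlap_sets(sets)
        for name, s in sets.items():
            assert df.loc[df[name], "count"].sum() == len(s)


# ---------------------------------------------------------------------------
# end-to-end contrast
# ---------------------------------------------------------------------------


class TestDifferentialExpansion:
    def test_recovers_strong_expanders(self, small_experiment):
        truth, table = small_experiment
        ids_a = [s.sample_id for s in table.samples if s.timepoint == 0]
        ids_b = [s.sample_id for s in table.samples if s.timepoint == 10]
        res = differential_expansion(table, ids_a, ids_b)
        assert set(res.columns) >= {"clone_id", "log2_fc", "avg_log2_ucpm",
                                    "p", "adj_p", "label"}
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
        strong = {
            cid for cid, f in zip(truth.cdr3_aa, truth.fold_day_last) if f >= 8
        } & set(res["clone_id"])
        doe = set(res.loc[res["label"] == "DOE", "clone_id"])
        assert strong and len(doe & strong) / len(strong) >= 0.8

    def test_alpha_monotonicity(self, small_experiment):
        from tcrtrack.diffexp import DiffExpConfig

        _, table = small_experiment
        ids_a = [s.sample_id for s in table.samples if s.timepoint == 0]
        ids_b = [s.sample_id for s in table.samples if s.timepoint == 10]
        loose = differential_expansion(table, ids_a, ids_b)
        tight = differential_expansion(
            table, ids_a, ids_b, config=DiffExpConfig(alpha=1e-9)
        )
        assert (tight["label"] == "DOE").sum() <= (loose["label"] == "DOE").sum()
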