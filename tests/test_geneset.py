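"""FPKM, expressed filter, DEG calls, set algebra, G-test, count simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zebratrack.geneset import (
    CONTRASTS,
    ContrastResult,
    ExpressionMatrix,
    call_degs,
    compute_fpkm,
    derive_circadian_sets,
    enrichment_table,
    filter_expressed,
    g_test,
    simulate_counts,
    threshold_degs,
)


def _matrix(values, groups=None, lengths=None, units="counts"):
    values = pd.DataFrame(values)
    groups = groups or {
        c: g for c, g in zip(values.columns, ["WT_M", "WT_N", "MUT_M", "MUT_N"] * 4)
    }
    return ExpressionMatrix(
        values=values,
        groups=pd.Series(groups),
        gene_lengths=pd.Series(lengths, index=values.index) if lengths is not None else None,
        units=units,
    )


def brute_force_g(table):
    """Independent evaluation of 2 * sum O*ln(O/E) via explicit loops."""
    table = [list(map(float, row)) for row in table]
    n = sum(sum(r) for r in table)
    rows = [sum(r) for r in table]
    cols = [sum(table[i][j] for i in range(2)) for j in range(2)]
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = table[i][j]
            if o > 0:
                g += o * math.log(o / (rows[i] * cols[j] / n))
    return 2.0 * g


class TestFpkm:
    def test_round_number_case(self):
        # count 10, length 1 kb, 1 M fragments -> FPKM 10
        mat = ExpressionMatrix(
            values=pd.DataFrame({"s1": [10]}, index=["g1"]),
            groups=pd.Series({"s1": "WT_M"}),
            gene_lengths=pd.Series({"g1": 1000}),
            library_sizes=pd.Series({"s1": 1_000_000}),
        )
        assert compute_fpkm(mat).values.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        mat = ExpressionMatrix(
            values=pd.DataFrame({"s1": [0]}, index=["g1"]),
            groups=pd.Series({"s1": "WT_M"}),
            gene_lengths=pd.Series({"g1": 1000}),
            library_sizes=pd.Series({"s1": 1_000_000}),
        )
        assert compute_fpkm(mat).values.loc["g1", "s1"] == 0.0

    def test_direct_formula_evaluation(self):
        # count 250, 2.5 kb, 2 M fragments -> 50
        mat = ExpressionMatrix(
            values=pd.DataFrame({"s1": [250]}, index=["g1"]),
            groups=pd.Series({"s1": "WT_M"}),
            gene_lengths=pd.Series({"g1": 2500}),
            library_sizes=pd.Series({"s1": 2_000_000}),
        )
        assert compute_fpkm(mat).values.loc["g1", "s1"] == pytest.approx(50.0)

    def test_zero_length_rejected(self):
        mat = ExpressionMatrix(
            values=pd.DataFrame({"s1": [1]}, index=["g1"]),
            groups=pd.Series({"s1": "WT_M"}),
            gene_lengths=pd.Series({"g1": 0}),
        )
        with pytest.raises(ValueError):
            compute_fpkm(mat)


class TestFilterExpressed:
    def _fpkm(self, rows, n_reps=4):
        cols = [f"{g}_r{r}" for g in ["WT_M", "WT_N", "MUT_M", "MUT_N"] for r in range(n_reps)]
        groups = {c: c.rsplit("_r", 1)[0] for c in cols}
        return ExpressionMatrix(
            values=pd.DataFrame(rows, columns=cols),
            groups=pd.Series(groups),
            units="fpkm",
        )

    def test_one_group_fully_above_keeps_gene(self):
        row = [0.2] * 4 + [0.0] * 12
        assert filter_expressed(self._fpkm([row])) == {0}

    def test_boundary_value_excluded_by_strict_inequality(self):
        assert filter_expressed(self._fpkm([[0.1] * 16])) == set()

    def test_three_of_four_samples_insufficient(self):
        row = ([0.2, 0.2, 0.2, 0.05]) * 4  # 3/4 above in every group
        assert filter_expressed(self._fpkm([row])) == set()

    def test_matches_brute_force_loop_on_random_matrix(self):
        rng = np.random.default_rng(61)
        vals = rng.uniform(0, 0.3, size=(300, 16))
        mat = self._fpkm(vals)
        got = filter_expressed(mat)
        groups = ["WT_M", "WT_N", "MUT_M", "MUT_N"]
        expected = set()
        for gi in range(300):
            for g in groups:
                cols = [c for c in mat.values.columns if mat.groups[c] == g]
                if all(mat.values.loc[gi, c] > 0.1 for c in cols):
                    expected.add(gi)
                    break
        assert got == expected


class TestCallDegs:
    def _fpkm_matrix(self, n_genes=50, seed=0, shift_first=None):
        rng = np.random.default_rng(seed)
        cols = [f"{g}_r{r}" for g in ["WT_M", "WT_N", "MUT_M", "MUT_N"] for r in range(4)]
        vals = rng.lognormal(3, 0.3, size=(n_genes, 16))
        if shift_first is not None:
            night_mut = [i for i, c in enumerate(cols) if c.startswith("MUT_N")]
            vals[0, night_mut] *= shift_first
        return ExpressionMatrix(
            values=pd.DataFrame(vals, columns=cols),
            groups=pd.Series({c: c.rsplit("_r", 1)[0] for c in cols}),
            units="fpkm",
        )

    def test_planted_strong_up_gene_called(self):
        mat = self._fpkm_matrix(shift_first=8.0)
        res = call_degs(mat, "N_mut_vs_wt")
        assert 0 in res.up
        assert res.table.loc[0, "fold_change"] > 1.5

    def test_fc_below_cutoff_never_a_deg(self):
        table = pd.DataFrame(
            {"fold_change": [1.4, 2.0], "p_adj": [0.001, 0.01]}, index=["a", "b"]
        )
        res = threshold_degs(table, "N_mut_vs_wt")
        assert res.degs == {"b"}
        assert res.table.loc["a", "direction"] == "ns"

    def test_down_direction_by_reciprocal_fold(self):
        table = pd.DataFrame(
            {"fold_change": [0.5, 0.8], "p_adj": [0.01, 0.01]}, index=["a", "b"]
        )
        res = threshold_degs(table, "WT_N_vs_M")
        assert res.down == {"a"}

    def test_null_matrix_false_positive_rate(self):
        # identical group means: BH-adjusted discoveries should be rare
        mat = self._fpkm_matrix(n_genes=2000, seed=1)
        res = call_degs(mat, "N_mut_vs_wt")
        assert len(res.degs) <= 0.06 * 2000

    def test_too_few_replicates_rejected(self):
        cols = ["WT_M_r1", "WT_N_r1", "WT_N_r2", "MUT_M_r1", "MUT_M_r2", "MUT_N_r1", "MUT_N_r2"]
        mat = ExpressionMatrix(
            values=pd.DataFrame(np.ones((5, 7)), columns=cols),
            groups=pd.Series({c: c.rsplit("_r", 1)[0] for c in cols}),
            units="fpkm",
        )
        with pytest.raises(ValueError, match="replicates"):
            call_degs(mat, "M_mut_vs_wt")


class TestDeriveCircadianSets:
    def _result(self, contrast, up=(), down=(), universe=("a", "b", "c", "d")):
        table = pd.DataFrame(
            {
                "fold_change": [2.0 if g in up else 0.5 if g in down else 1.0 for g in universe],
                "p_adj": [0.01 if (g in up or g in down) else 0.9 for g in universe],
            },
            index=list(universe),
        )
        return threshold_degs(table, contrast)

    def test_attenuated_morning_gene_lands_in_gs2(self):
        contrasts = {
            "M_mut_vs_wt": self._result("M_mut_vs_wt"),
            "N_mut_vs_wt": self._result("N_mut_vs_wt", up=("a",)),
            "WT_N_vs_M": self._result("WT_N_vs_M", down=("a", "b")),
            "MUT_N_vs_M": self._result("MUT_N_vs_M"),
        }
        sets = derive_circadian_sets(contrasts)
        assert sets["GS2"] == {"a"}
        assert sets["GS1"] == set()

    def test_empty_contrasts_give_empty_sets(self):
        contrasts = {c: self._result(c) for c in CONTRASTS}
        sets = derive_circadian_sets(contrasts)
        assert all(not sets[k] for k in ("U1", "D1", "U2", "D2", "U3", "D3", "U4", "D4", "GS1", "GS2"))

    def test_subset_invariants_on_random_inputs(self):
        rng = np.random.default_rng(67)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            contrasts = {}
            for c in CONTRASTS:
                lab = rng.choice(["up", "down", "ns"], size=200, p=[0.2, 0.2, 0.6])
                contrasts[c] = self._result(
                    c,
                    up=tuple(np.array(universe)[lab == "up"]),
                    down=tuple(np.array(universe)[lab == "down"]),
                    universe=universe,
                )
            sets = derive_circadian_sets(contrasts)
            assert sets["GS1"] <= sets["U3"]
            assert sets["GS2"] <= sets["D3"]
            assert not (sets["GS1"] & sets["GS2"])

    def test_mismatched_universes_rejected(self):
        contrasts = {c: self._result(c) for c in CONTRASTS}
        contrasts["WT_N_vs_M"] = self._result("WT_N_vs_M", universe=("a", "b"))
        with pytest.raises(ValueError, match="universe"):
            derive_circadian_sets(contrasts)


class TestGTest:
    def test_balanced_table_independence(self):
        r = g_test([[10, 10], [10, 10]])
        assert r.g == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_independent_formula_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(1000):
            table = rng.integers(1, 500, size=(2, 2))
            assert g_test(table).g == pytest.approx(brute_force_g(table), abs=1e-9)

    def test_row_swap_invariance(self):
        a = g_test([[30, 70], [10, 90]])
        b = g_test([[10, 90], [30, 70]])
        assert a.g == pytest.approx(b.g, abs=1e-12)

    def test_transpose_invariance(self):
        t = np.array([[12, 34], [56, 78]])
        assert g_test(t).g == pytest.approx(g_test(t.T).g, abs=1e-12)

    def test_chi_square_agreement_for_large_expected(self):
        # G and Pearson's X^2 are asymptotically equivalent; sample tables
        # near independence (where the equivalence holds) with big margins
        rng = np.random.default_rng(73)
        checked = 0
        for _ in range(500):
            pr, pc = rng.uniform(0.3, 0.7, 2)
            probs = np.outer([pr, 1 - pr], [pc, 1 - pc])
            table = rng.multinomial(2000, probs.ravel()).reshape(2, 2)
            r = g_test(table)
            if r.expected.min() > 50 and r.g > 0.5:
                chi2 = stats.chi2_contingency(table, correction=False).statistic
                assert r.g == pytest.approx(chi2, rel=0.05)
                checked += 1
        assert checked > 100

    def test_zero_cell_contributes_zero(self):
        r = g_test([[0, 50], [50, 50]])
        assert np.isfinite(r.g) and r.g > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            g_test([[0, 0], [10, 10]])

    def test_williams_correction_shrinks_g(self):
        plain = g_test([[30, 70], [10, 90]])
        corr = g_test([[30, 70], [10, 90]], williams_correction=True)
        assert 0 < corr.g < plain.g

    def test_enrichment_table_counts(self):
        expressed = {f"g{i}" for i in range(100)}
        circadian = {f"g{i}" for i in range(20)}
        affected = {f"g{i}" for i in range(10, 30)}
        table = enrichment_table(expressed, circadian, affected)
        assert table.tolist() == [[10, 10], [10, 70]]


class TestSimulateCounts:
    def test_same_seed_identical_matrix(self):
        a, _ = simulate_counts(n_genes=200, seed=9)
        b, _ = simulate_counts(n_genes=200, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_planted_sets_have_requested_sizes(self):
        _, truth = simulate_counts(n_genes=500, n_planted_circadian=40, n_planted_affected=10, seed=1)
        assert len(truth.circadian_genes) == 40
        assert len(truth.affected_genes) == 10
        assert truth.affected_genes <= truth.circadian_genes

    def test_poisson_limit_variance_to_mean(self):
        mat, _ = simulate_counts(
            n_genes=300, n_planted_circadian=0, n_planted_affected=0,
            dispersion=0.0, seed=2, mean_log10_range=(3.0, 3.0),
        )
        wt_m = mat.values[mat.samples_of("WT_M")].to_numpy(float)
        ratio = wt_m.var(axis=1, ddof=1).mean() / wt_m.mean(axis=1).mean()
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_planted_circadian_effect_visible_in_means(self):
        mat, truth = simulate_counts(n_genes=400, n_planted_circadian=50, seed=3)
        fpkm = compute_fpkm(mat)
        circ = sorted(truth.circadian_genes)
        m = fpkm.values.loc[circ, mat.samples_of("WT_M")].mean(axis=1)
        n = fpkm.values.loc[circ, mat.samples_of("WT_N")].mean(axis=1)
        assert np.median(m / n) == pytest.approx(3.0, rel=0.3)

    def test_invalid_planting_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(n_genes=10, n_planted_circadian=20)

    def test_null_fold_yields_near_empty_gs2(self):
        mat, _ = simulate_counts(
            n_genes=1000, circadian_fold=1.0, attenuation_fold=1.0, seed=4
        )
        fpkm = compute_fpkm(mat)
        expressed = filter_expressed(fpkm)
        contrasts = {c: call_degs(fpkm, c, genes=expressed) for c in CONTRASTS}
        sets = derive_circadian_sets(contrasts)
        assert len(sets["GS2"]) <= 0.005 * 1000
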