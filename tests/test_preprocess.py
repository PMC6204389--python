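"""CPM/filter/TMM/RPKM/DE unit behaviour against hand-computed oracles."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import coexnet as cx
from conftest import make_count_matrix


class TestCpm:
    def test_definition_on_million_read_library(self):
        cm = make_count_matrix([[1], [5], [999_994]])
        values = cx.cpm(cm)
        assert values.iloc[0, 0] == pytest.approx(1.0)
        assert values.iloc[1, 0] == pytest.approx(5.0)

    def test_all_zero_gene_row_stays_zero(self):
        cm = make_count_matrix([[0, 0], [10, 20]])
        assert (cx.cpm(cm).iloc[0] == 0).all()

    def test_zero_library_names_the_sample(self):
        cm = make_count_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            cx.cpm(cm)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        cm = make_count_matrix(rng.integers(0, 500, size=(40, 5)) + 1)
        assert cx.cpm(cm).sum(axis=0).to_numpy() == pytest.approx([1e6] * 5)


class TestFilterLowExpression:
    def make(self, cpm_rows):
        # libraries of exactly 1e6 so CPM equals the count
        rows = np.asarray(cpm_rows, dtype=float)
        filler = 1e6 - rows.sum(axis=0)
        return make_count_matrix(np.vstack([rows, filler]))

    def test_boundary_is_inclusive(self):
        cm = self.make([[1, 1, 1, 0]])
        kept = cx.filter_low_expression(cm, min_cpm=1, min_samples=3)
        assert "g0" in kept.gene_ids

    @pytest.mark.parametrize("row", [[1, 1, 0, 0], [0.99, 0.99, 0.99, 0.99]])
    def test_below_rule_removed(self, row):
        kept = cx.filter_low_expression(self.make([row]), 1, 3)
        assert "g0" not in kept.gene_ids

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(1)
        cm = make_count_matrix(rng.integers(0, 40, size=(60, 6)))
        once = cx.filter_low_expression(cm)
        twice = cx.filter_low_expression(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_gene_order_preserved(self):
        rng = np.random.default_rng(2)
        cm = make_count_matrix(rng.integers(0, 100, size=(30, 4)))
        kept = cx.filter_low_expression(cm)
        original = [g for g in cm.gene_ids if g in set(kept.gene_ids)]
        assert kept.gene_ids == original


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[10], [20], [30], [40]], (1, 3)))
        assert cx.tmm_factors(cm).to_numpy() == pytest.approx([1, 1, 1])

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(3)
        a = rng.integers(10, 1000, size=50)
        cm = make_count_matrix(np.column_stack([a, 2 * a]))
        assert cx.tmm_factors(cm).to_numpy() == pytest.approx([1.0, 1.0])

    def test_dominating_gene_pulls_factor_below_one(self):
        rng = np.random.default_rng(4)
        base = rng.integers(50, 500, size=60)
        skewed = base.copy()
        skewed[0] = base.sum()  # one gene takes ~50% of the library
        cm = make_count_matrix(np.column_stack([base, skewed, base]))
        factors = cx.tmm_factors(cm, reference="s0")
        assert factors["s1"] < 1.0

    def test_matches_independent_trimmed_mean_evaluation(self):
        # brute-force re-evaluation of the doubly trimmed weighted mean
        rng = np.random.default_rng(5)
        obs = rng.integers(1, 2000, size=80).astype(float)
        ref = rng.integers(1, 2000, size=80).astype(float)
        lo, lr = obs.sum(), ref.sum()
        m = np.log2((obs / lo) / (ref / lr))
        a = 0.5 * (np.log2(obs / lo) + np.log2(ref / lr))
        w = (lo - obs) / (lo * obs) + (lr - ref) / (lr * ref)
        n = len(m)
        rm, ra = rankdata(m), rankdata(a)
        keep = ((rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
                & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05)))
        expected = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        cm = make_count_matrix(np.column_stack([ref, obs]).astype(int))
        factors = cx.tmm_factors(cm, reference="s0")
        # the geometric-mean rescaling cancels in the ratio
        assert factors["s1"] / factors["s0"] == pytest.approx(expected, rel=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(6)
        cm = make_count_matrix(rng.integers(0, 300, size=(100, 6)))
        factors = cx.tmm_factors(cm)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors on a random matrix."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(5, 0.01, size=(120, 4)) + 1
        cm = make_count_matrix(counts)
        ours = cx.tmm_factors(cm, reference="s0")
        tsv = tmp_path / "counts.tsv"
        cm.counts.to_csv(tsv, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{tsv}", row.names=1))
            f <- calcNormFactors(x, method="TMM", refColumn=1)
            cat(sprintf("%.12f\\n", f))
        """))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        theirs = np.array([float(v) for v in proc.stdout.split()])
        assert ours.to_numpy() == pytest.approx(theirs, rel=1e-6)


class TestRpkm:
    def test_definition(self):
        cm = make_count_matrix([[10], [999_990]], lengths=[1000, 1000])
        expr = cx.rpkm(cm, pd.Series([1.0], index=["s0"]))
        assert expr.values.iloc[0, 0] == pytest.approx(10.0)

    def test_length_halves_value(self):
        cm = make_count_matrix([[10], [999_990]], lengths=[2000, 1000])
        expr = cx.rpkm(cm, pd.Series([1.0], index=["s0"]))
        assert expr.values.iloc[0, 0] == pytest.approx(5.0)

    def test_factor_two_halves_value(self):
        cm = make_count_matrix([[10], [999_990]], lengths=[1000, 1000])
        expr = cx.rpkm(cm, pd.Series([2.0], index=["s0"]))
        assert expr.values.iloc[0, 0] == pytest.approx(5.0)

    def test_nonpositive_factor_rejected(self):
        cm = make_count_matrix([[10], [20]])
        with pytest.raises(ValueError):
            cx.rpkm(cm, pd.Series([-1.0], index=["s0"]))


class TestCallDe:
    def make_expr(self, control_mean, substrate_mean):
        values = pd.DataFrame({
            "c1": [control_mean], "c2": [control_mean],
            "b1": [substrate_mean], "b2": [substrate_mean],
        }, index=["g0"])
        meta = pd.DataFrame({
            "condition": ["fructose", "fructose", "bagasse", "bagasse"],
            "timepoint": [24, 24, 6, 6],
            "replicate": [1, 2, 1, 2],
        }, index=values.columns)
        expr = cx.ExprMatrix(values=values,
                             norm_factors=pd.Series(1.0, index=values.columns))
        return expr, meta

    @pytest.mark.parametrize("ctrl,sub,lfc,status", [
        (1.0, 4.0, 2.0, "up"),
        (4.0, 1.0, -2.0, "down"),
        (1.0, 1.9, np.log2(1.9), "none"),
    ])
    def test_fold_change_rule(self, ctrl, sub, lfc, status):
        expr, meta = self.make_expr(ctrl, sub)
        de = cx.call_de(expr, meta, control="fructose", pseudo=0.0)
        assert de.log2fc.loc["g0", "6h"] == pytest.approx(lfc)
        assert de.status.loc["g0", "6h"] == status
        assert de.overall_status["g0"] == status

    def test_unknown_control_rejected(self):
        expr, meta = self.make_expr(1.0, 2.0)
        with pytest.raises(ValueError, match="glucose"):
            cx.call_de(expr, meta, control="glucose")

    def test_mixed_direction_across_timepoints(self):
        values = pd.DataFrame(
            {"c1": [1.0], "b6": [4.0], "b12": [0.25]}, index=["g0"])
        meta = pd.DataFrame({
            "condition": ["fructose", "bagasse", "bagasse"],
            "timepoint": [24, 6, 12],
            "replicate": [1, 1, 1],
        }, index=values.columns)
        expr = cx.ExprMatrix(values=values,
                             norm_factors=pd.Series(1.0, index=values.columns))
        de = cx.call_de(expr, meta, control="fructose", pseudo=0.0)
        assert de.overall_status["g0"] == "mixed"
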