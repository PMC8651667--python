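"""Size factors, dispersion, Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from genescout import de
from genescout import io as gio
from conftest import two_group_counts


def make_cm(counts, gene_ids=None, sample_ids=None):
    counts = np.asarray(counts)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    return gio.CountMatrix(gene_ids, sample_ids, counts)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm([[10, 10], [3, 3], [7, 7]])
        assert np.allclose(de.size_factors(cm), [1.0, 1.0])

    def test_pure_depth_doubling(self):
        cm = make_cm([[100, 200], [10, 20], [40, 80]])
        s = de.size_factors(cm)
        # hand oracle: every ratio to the geometric mean doubles in column 2
        assert np.isclose(s[1] / s[0], 2.0)
        assert np.isclose(np.exp(np.log(s).mean()), 1.0)

    def test_requires_an_all_positive_gene(self):
        cm = make_cm([[0, 5], [5, 0]])
        with pytest.raises(gio.ValidationError, match="filter"):
            de.size_factors(cm)


class TestDispersion:
    def make_meta(self, n, condition="embryonic"):
        return gio.SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "batch": ["B1"] * n,
            "timepoint": ["E11" if condition == "embryonic" else "P0"] * n,
            "condition": [condition] * n,
            "replicate": list(range(1, n + 1)),
        }))

    def test_method_of_moments_formula(self):
        """Oracle: alpha = (var - mean)/mean^2 on the normalized counts,
        applied by hand to the same numbers."""
        vals = np.array([38, 62, 45, 55, 70, 30])
        cm = make_cm(vals[None, :])
        alpha = de.estimate_dispersion(cm, np.ones(6), self.make_meta(6))
        m, v = vals.mean(), vals.var(ddof=1)
        assert np.isclose(alpha[0], max((v - m) / m**2, de.ALPHA_MIN))

    def test_constant_gene_hits_floor(self):
        cm = make_cm([[20, 20, 20, 20]])
        alpha = de.estimate_dispersion(cm, np.ones(4), self.make_meta(4))
        assert alpha[0] == de.ALPHA_MIN

    def test_poisson_gene_near_floor(self):
        rng = np.random.Generator(np.random.PCG64(0))
        cm = make_cm(rng.poisson(100, size=(200, 20)))
        alpha = de.estimate_dispersion(cm, np.ones(20), self.make_meta(20))
        assert np.median(alpha) < 0.01


class TestBH:
    def test_single_p_identity(self):
        assert de.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        # min over i' >= i of p_(i') * m / i' gives 0.04 for every entry
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_never_below_input_and_capped(self):
        rng = np.random.Generator(np.random.PCG64(1))
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            adj = de.bh_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_matches_statsmodels(self):
        rng = np.random.Generator(np.random.PCG64(2))
        p = rng.random(500)
        ours = de.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestWald:
    def test_equal_means_give_null_result(self):
        counts = np.tile([[40], [7]], (1, 8))
        cm = make_cm(counts)
        meta = gio.SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(8)],
            "batch": ["B1"] * 8,
            "timepoint": ["E11"] * 4 + ["P0"] * 4,
            "condition": ["embryonic"] * 4 + ["postnatal"] * 4,
            "replicate": [1, 2, 3, 4] * 2,
        }))
        tab = de.wald_de(cm, meta)
        assert np.allclose(tab["log2FoldChange"], 0.0)
        assert np.allclose(tab["pvalue"], 1.0)

    def test_label_swap_negates_lfc_preserves_p(self):
        cm, meta = two_group_counts(300, de_idx=np.arange(30), seed=5)
        fwd = de.wald_de(cm, meta)
        rev = de.wald_de(cm, meta, reference="postnatal", treatment="embryonic")
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_scale_invariance_of_one_column(self):
        cm, meta = two_group_counts(300, seed=6)
        scaled = cm.counts.copy()
        scaled[:, 0] *= 4
        cm2 = make_cm(scaled, gene_ids=cm.gene_ids, sample_ids=cm.sample_ids)
        s1 = de.size_factors(cm)
        s2 = de.size_factors(cm2)
        # the scaled sample's factor grows 4x relative to the others
        assert np.isclose((s2[0] / s2[1]) / (s1[0] / s1[1]), 4.0, rtol=1e-6)
        t1 = de.wald_de(cm, meta)
        t2 = de.wald_de(cm2, meta)
        # invariance is exact only in the epsilon->0 limit: rescaling one
        # column shifts every normalized count by 4^(1/n_samples) while the
        # pseudo-count stays fixed, so allow that small epsilon-driven drift
        assert np.allclose(t1["log2FoldChange"], t2["log2FoldChange"], atol=0.01)
        assert np.allclose(t1["pvalue"], t2["pvalue"], atol=0.02)
        assert np.allclose(t1["baseMean"] * 4 ** (1 / 12), t2["baseMean"], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_null_calibration(self, seed):
        cm, meta = two_group_counts(2000, seed=seed)
        tab = de.wald_de(cm, meta)
        frac = (tab["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_fold_change_recovered(self, seed):
        de_idx = np.arange(200)
        cm, meta = two_group_counts(2000, de_idx=de_idx, fold=4.0, seed=100 + seed)
        tab = de.wald_de(cm, meta)
        called = tab["padj"] < 0.05
        truth = np.zeros(2000, bool)
        truth[de_idx] = True
        sens = (called & truth).sum() / truth.sum()
        fdr = (called & ~truth).sum() / max(called.sum(), 1)
        assert sens >= 0.8
        assert fdr <= 0.1


class TestTopDegs:
    def make_table(self, p, lfc, genes=None):
        n = len(p)
        genes = genes or [f"g{i}" for i in range(n)]
        return pd.DataFrame({
            "gene_id": genes, "baseMean": 1.0, "log2FoldChange": lfc,
            "lfcSE": 1.0, "pvalue": p, "padj": de.bh_adjust(p),
            "rank": np.arange(1, n + 1),
        })

    def test_truncates_to_n_significant(self):
        tab = self.make_table([0.001] * 10 + [0.5] * 5, [1.0] * 15)
        assert len(de.top_degs(tab, n=3000, alpha=0.05)) == 10
        assert len(de.top_degs(tab, n=4, alpha=0.05)) == 4

    def test_tie_broken_by_abs_lfc_then_gene(self):
        tab = self.make_table([0.001, 0.001, 0.001], [1.0, -3.0, 1.0],
                              genes=["b", "c", "a"])
        assert de.top_degs(tab, n=3, alpha=0.05) == ["c", "a", "b"]

    def test_defaults_match_study(self):
        import inspect
        sig = inspect.signature(de.top_degs)
        assert sig.parameters["n"].default == 3000
        assert sig.parameters["alpha"].default == 0.05
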