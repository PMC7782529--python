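"""Per-dataset differential expression, Fisher combination, batch merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metallonet.core_io import ExpressionStudy
from metallonet.expression_meta import (
    fisher_combine,
    merge_with_batch_adjust,
    normalize_dataset,
    per_gene_pvalues,
    run_meta,
)
from metallonet.synthetic_data import SynthesisConfig, gen_expression


def make_study(matrix: np.ndarray, genes, n_ctrl, n_case, batch="B1"):
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"p{i}" for i in range(n_case)]
    groups = pd.Series({c: "control" if c.startswith("c") else "PD" for c in cols})
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=genes, columns=cols),
        groups=groups, batch=pd.Series({c: batch for c in cols}))


class TestNormalize:
    def test_low_values_pass_through(self):
        s = make_study(np.full((2, 4), 8.0), ["G1", "G2"], 2, 2)
        out = normalize_dataset(s)
        assert out.matrix.equals(s.matrix) and out.normalized

    def test_raw_1024_becomes_10(self):
        s = make_study(np.full((1, 4), 1024.0), ["G1"], 2, 2)
        assert (normalize_dataset(s).matrix.to_numpy() == 10.0).all()

    def test_force_overrides_heuristic(self):
        s = make_study(np.full((1, 4), 16.0), ["G1"], 2, 2)
        assert (normalize_dataset(s, force=True).matrix.to_numpy() == 4.0).all()

    def test_nonpositive_raw_intensity_rejected(self):
        m = np.full((1, 4), 1024.0)
        m[0, 0] = 0.0
        s = make_study(m, ["G1"], 2, 2)
        with pytest.raises(ValueError, match="nonpositive"):
            normalize_dataset(s)


class TestPerGenePvalues:
    def test_null_type_i_error_calibrated(self):
        # permutation-free null: both groups from one distribution
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(2000)]
        s = make_study(rng.standard_normal((2000, 20)), genes, 10, 10)
        p = per_gene_pvalues(s)["p"]
        rate = (p <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_three_sd_shift_is_highly_significant(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((1, 20))
        m[0, 10:] += 3.0
        s = make_study(m, ["G1"], 10, 10)
        out = per_gene_pvalues(s)
        assert out.loc["G1", "p"] < 1e-3
        assert out.loc["G1", "sign"] == 1.0

    def test_constant_gene_p_is_one(self):
        s = make_study(np.full((1, 6), 5.0), ["G1"], 3, 3)
        assert per_gene_pvalues(s).loc["G1", "p"] == 1.0

    def test_matches_scipy_per_gene(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((5, 12))
        s = make_study(m, [f"G{i}" for i in range(5)], 6, 6)
        out = per_gene_pvalues(s)
        for i in range(5):
            ref = stats.ttest_ind(m[i, 6:], m[i, :6])
            assert out.iloc[i]["p"] == pytest.approx(ref.pvalue)


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.05, 0.5, 1e-8):
            _, df, combined = fisher_combine([p])
            assert df == 2
            assert combined == pytest.approx(p, rel=1e-12)

    def test_worked_pair(self):
        X, df, combined = fisher_combine([0.05, 0.05])
        assert X == pytest.approx(-4 * np.log(0.05), abs=1e-9)
        assert X == pytest.approx(11.983, abs=1e-3)
        assert df == 4
        assert combined == pytest.approx(stats.chi2.sf(X, 4))
        assert combined == pytest.approx(0.0175, abs=2e-4)

    def test_p_of_one_contributes_nothing(self):
        X1, _, _ = fisher_combine([0.05])
        X2, _, _ = fisher_combine([0.05, 1.0])
        assert X1 == pytest.approx(X2)

    def test_zero_p_rejected_with_instruction(self):
        with pytest.raises(ValueError, match="floor"):
            fisher_combine([0.0, 0.5])


class TestRunMeta:
    def test_planted_genes_recovered_up(self):
        cfg = SynthesisConfig(seed=6)
        genes = [f"G{i}" for i in range(100)]
        de = {f"G{i}" for i in range(10)}
        studies = gen_expression(cfg, genes, de)
        results = {r.gene: r for r in run_meta(studies)}
        for g in de:
            assert results[g].significant
            assert results[g].direction in ("up", "down")

    def test_null_false_positive_rate_near_alpha(self):
        cfg = SynthesisConfig(seed=7, n_datasets=3)
        genes = [f"G{i}" for i in range(800)]
        studies = gen_expression(cfg, genes, set())
        results = run_meta(studies)
        fpr = np.mean([r.significant for r in results])
        assert 0.02 <= fpr <= 0.09

    def test_invariant_to_study_order(self):
        cfg = SynthesisConfig(seed=8, n_datasets=3)
        genes = [f"G{i}" for i in range(30)]
        studies = gen_expression(cfg, genes, {"G0"})
        a = run_meta(studies)
        b = run_meta(studies[::-1])
        assert [(r.gene, r.fisher_x, r.combined_p) for r in a] == \
               [(r.gene, r.fisher_x, r.combined_p) for r in b]

    def test_gene_in_single_study_keeps_its_p(self):
        rng = np.random.default_rng(3)
        s1 = make_study(rng.standard_normal((2, 8)), ["G1", "G2"], 4, 4, "B1")
        s2 = make_study(rng.standard_normal((1, 8)), ["G1"], 4, 4, "B2")
        results = {r.gene: r for r in run_meta([s1, s2])}
        only = per_gene_pvalues(s1).loc["G2", "p"]
        assert results["G2"].combined_p == pytest.approx(only, rel=1e-9)

    def test_significant_only_mode_ignores_weak_datasets(self):
        rng = np.random.default_rng(4)
        s1 = make_study(rng.standard_normal((1, 8)), ["G1"], 4, 4, "B1")
        s2 = make_study(rng.standard_normal((1, 8)), ["G1"], 4, 4, "B2")
        full = run_meta([s1, s2])[0]
        literal = run_meta([s1, s2], significant_only=True)[0]
        ps = full.per_study_p
        weak = [p for p in ps if p > 0.05]
        if weak:  # literal mode combines fewer p-values
            assert literal.df < full.df


class TestMergeBatchAdjust:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((4, 8))
        s1 = make_study(base, [f"G{i}" for i in range(4)], 4, 4, "B1")
        s2 = make_study(base + 7.0, [f"G{i}" for i in range(4)], 4, 4, "B2")
        merged = merge_with_batch_adjust([s1, s2])
        for g in merged.genes:
            means = {}
            for b in ("B1", "B2"):
                cols = [c for c in merged.samples if merged.batch[c] == b]
                means[b] = merged.matrix.loc[g, cols].mean()
            assert abs(means["B1"] - means["B2"]) < 1e-9

    def test_merge_restricted_to_shared_genes(self):
        rng = np.random.default_rng(6)
        s1 = make_study(rng.standard_normal((3, 6)), ["G1", "G2", "G3"], 3, 3, "B1")
        s2 = make_study(rng.standard_normal((2, 6)), ["G2", "G3"], 3, 3, "B2")
        merged = merge_with_batch_adjust([s1, s2])
        assert set(merged.genes) == {"G2", "G3"}
        assert len(merged.samples) == 12

    def test_single_sample_batch_rejected(self):
        s1 = make_study(np.zeros((1, 4)), ["G1"], 2, 2, "B1")
        bad = ExpressionStudy(
            matrix=pd.DataFrame([[1.0]], index=["G1"], columns=["x"]),
            groups=pd.Series({"x": "PD"}), batch=pd.Series({"x": "B2"}))
        with pytest.raises(ValueError, match="single sample"):
            merge_with_batch_adjust([s1, bad])

    def test_batch_free_data_preserved_up_to_affine_rescale(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((3, 10))
        s1 = make_study(base[:, :5] + 5, ["G1", "G2", "G3"], 3, 2, "B1")
        s2 = make_study(base[:, 5:] + 5, ["G1", "G2", "G3"], 3, 2, "B2")
        merged = merge_with_batch_adjust([s1, s2])
        # per gene, within-batch sample ordering and z-scores preserved
        for g in merged.genes:
            cols1 = [c for c in merged.samples if merged.batch[c] == "B1"]
            orig = s1.matrix.loc[g].to_numpy()
            adj = merged.matrix.loc[g, cols1].to_numpy()
            z1 = (orig - orig.mean()) / orig.std(ddof=1)
            z2 = (adj - adj.mean()) / adj.std(ddof=1)
            assert np.allclose(z1, z2, atol=1e-9)

    def test_batch_offsets_do_not_break_planted_classification(self):
        # end-to-end: classifier accuracy on planted signal within a few
        # points of the batch-free run
        from metallonet.hub_classification import crossval_classify
        genes = [f"G{i}" for i in range(30)]
        de = {f"G{i}" for i in range(6)}
        accs = {}
        for label, batch_sd in (("batchy", 2.0), ("clean", 1e-12)):
            cfg = SynthesisConfig(seed=9, n_datasets=3, batch_sd=batch_sd)
            studies = gen_expression(cfg, genes, de)
            merged = merge_with_batch_adjust(studies)
            X = merged.matrix.loc[sorted(de)].T.to_numpy()
            y = np.array([1 if merged.groups[s] == "PD" else 0
                          for s in merged.samples])
            rep = crossval_classify(X, y, algorithm="lda", folds=5, repeats=2,
                                    seed=0)
            accs[label] = rep.accuracy
        assert abs(accs["batchy"] - accs["clean"]) <= 0.05
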