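import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from istmescore.containers import ExpressionMatrix, GeneSet
from istmescore.refine import SignaturePair
from istmescore.scoring import (
    ANGIOPOIETIN_RATIO,
    EXHAUSTION_RATIO,
    SSGSEAScorer,
    ScoreTable,
    TMESubtypeClassifier,
    assign_subtypes,
    compute_istme,
    marker_ratio,
    normalize_scores,
    ssgsea_score,
)


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def brute_force_ssgsea(expr_col, gene_ids, set_genes, alpha):
    """Independent double-loop running-sum implementation."""
    stat = rankdata(expr_col, method="average")
    order = np.argsort(-stat, kind="stable")
    hits = {g for g in set_genes if g in set(gene_ids)}
    n = len(gene_ids)
    n_hit = len(hits)
    w_total = sum(abs(stat[i]) ** alpha for i in order if gene_ids[i] in hits)
    es, cum_hit, cum_miss = 0.0, 0.0, 0.0
    for pos in order:
        if gene_ids[pos] in hits:
            cum_hit += abs(stat[pos]) ** alpha / w_total
        else:
            cum_miss += 1.0 / (n - n_hit)
        es += cum_hit - cum_miss
    return es


class TestSSGSEA:
    def test_top_gene_singleton_set_alpha_zero(self):
        m = _em([[4.0], [3.0], [2.0], [1.0]])
        score = ssgsea_score(m, GeneSet("S", "", ["g0"]), alpha=0.0)
        assert score.iloc[0] == pytest.approx(2.0)  # 1 + 2/3 + 1/3 + 0

    def test_bottom_gene_singleton_set_alpha_zero(self):
        m = _em([[4.0], [3.0], [2.0], [1.0]])
        score = ssgsea_score(m, GeneSet("S", "", ["g3"]), alpha=0.0)
        assert score.iloc[0] == pytest.approx(-2.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        m = _em(rng.normal(size=(30, 5)))
        gset = GeneSet("S", "", [f"g{i}" for i in range(0, 30, 4)])
        before = ssgsea_score(m, gset, alpha=0.25)
        m2 = ExpressionMatrix(np.exp(m.data))
        after = ssgsea_score(m2, gset, alpha=0.25)
        np.testing.assert_allclose(before.values, after.values, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(8, 40))
        n_samples = int(rng.integers(1, 6))
        alpha = float(rng.choice([0.0, 0.25, 0.5, 1.0]))
        m = _em(rng.normal(size=(n_genes, n_samples)))
        size = int(rng.integers(1, n_genes - 1))
        genes = list(rng.choice(m.gene_ids, size=size, replace=False))
        scores = ssgsea_score(m, GeneSet("S", "", genes), alpha=alpha)
        for j, sid in enumerate(m.sample_ids):
            ref = brute_force_ssgsea(m.values[:, j], m.gene_ids, genes, alpha)
            assert scores[sid] == pytest.approx(ref, abs=1e-10)

    def test_reordering_rows_and_columns_invariant(self):
        rng = np.random.default_rng(2)
        m = _em(rng.normal(size=(20, 6)))
        gset = GeneSet("S", "", ["g1", "g5", "g9"])
        base = ssgsea_score(m, gset)
        gp = rng.permutation(20)
        sp = rng.permutation(6)
        m2 = ExpressionMatrix(m.data.iloc[gp, sp])
        out = ssgsea_score(m2, gset)
        np.testing.assert_allclose(out[base.index].values, base.values, atol=1e-12)

    def test_absent_set_genes_dropped_all_absent_raises(self):
        m = _em(np.random.default_rng(0).normal(size=(5, 2)))
        score = ssgsea_score(m, GeneSet("S", "", ["g0", "nope"]))
        assert len(score) == 2
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(m, GeneSet("S", "", ["nope"]))

    def test_negative_alpha_rejected(self):
        m = _em(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ssgsea_score(m, GeneSet("S", "", ["g0"]), alpha=-0.1)


class TestNormalizeAndSubtypes:
    def test_minmax_values(self):
        out = normalize_scores(pd.Series([2.0, 4.0, 6.0], index=list("abc")))
        np.testing.assert_allclose(out.values, [0, 0.5, 1])

    def test_order_preserved(self):
        raw = pd.Series(np.random.default_rng(0).normal(size=10))
        out = normalize_scores(raw)
        assert spearmanr(raw, out)[0] == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            normalize_scores(pd.Series([1.0, 1.0]))

    def _scores(self, immune, stromal):
        idx = [f"s{i}" for i in range(len(immune))]
        t = pd.DataFrame({"immune_norm": immune, "stromal_norm": stromal}, index=idx)
        t["immune_raw"] = t["immune_norm"]
        t["stromal_raw"] = t["stromal_norm"]
        return ScoreTable(table=t, genes_used={})

    def test_forced_label_example(self):
        sub = assign_subtypes(self._scores([1, 2, 3, 4], [4, 3, 2, 1]))
        assert sub.labels.tolist() == ["LH", "LH", "HL", "HL"]

    def test_value_at_median_classed_low(self):
        sub = assign_subtypes(self._scores([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        # sample s2 sits exactly at both medians (3) -> low on both axes
        assert sub.labels["s2"] == "LL"

    def test_even_n_marginals_split_in_half(self):
        rng = np.random.default_rng(3)
        imm, stro = rng.permutation(10) + 0.0, rng.permutation(10) + 0.0
        sub = assign_subtypes(self._scores(imm, stro))
        assert sum(l[0] == "H" for l in sub.labels) == 5
        assert sum(l[1] == "H" for l in sub.labels) == 5

    def test_all_four_combinations_reachable(self):
        sub = assign_subtypes(self._scores([1, 2, 3, 4], [1, 4, 2, 3]))
        assert set(sub.labels) == {"LL", "LH", "HL", "HH"}

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            assign_subtypes(self._scores([1, 2], [2, 1]))


class TestComputeIstme:
    def _sig(self, immune, stromal):
        return SignaturePair(
            immune=GeneSet("ISTME_IMMUNE", "", immune),
            stromal=GeneSet("ISTME_STROMAL", "", stromal),
            provenance=pd.DataFrame(),
        )

    def test_deterministic_and_correlates_with_planted_activity(self, mini_cohort):
        expr, clin, gt, refs = mini_cohort
        sig = self._sig(gt.immune_genes, gt.stromal_genes)
        st1 = compute_istme(expr, sig)
        st2 = compute_istme(expr, sig)
        pd.testing.assert_frame_equal(st1.table, st2.table)
        rho_i, _ = spearmanr(st1.table["immune_norm"], gt.immune_activity)
        rho_s, _ = spearmanr(st1.table["stromal_norm"], gt.stromal_activity)
        assert rho_i >= 0.8 and rho_s >= 0.8

    def test_robust_to_removing_ten_percent_of_signature(self, mini_cohort):
        expr, clin, gt, refs = mini_cohort
        sig = self._sig(gt.immune_genes, gt.stromal_genes)
        full = compute_istme(expr, sig)
        rng = np.random.default_rng(0)
        drop = set(rng.choice(gt.immune_genes, 3, replace=False)) | set(
            rng.choice(gt.stromal_genes, 2, replace=False)
        )
        reduced = ExpressionMatrix(expr.data.drop(index=list(drop)))
        part = compute_istme(reduced, sig)
        for col in ("immune_norm", "stromal_norm"):
            assert (full.table[col] - part.table[col]).abs().max() < 0.1

    def test_coverage_floor_enforced(self, mini_cohort):
        expr, clin, gt, refs = mini_cohort
        sig = self._sig(gt.immune_genes[:5] + ["x1", "x2", "x3", "x4", "x5"],
                        gt.stromal_genes)
        with pytest.raises(ValueError, match="coverage"):
            compute_istme(expr, sig)


class TestMarkerRatio:
    def _marker_matrix(self, values_by_gene):
        genes = list(values_by_gene)
        vals = np.array([values_by_gene[g] for g in genes], dtype=float)
        return _em(vals, genes=genes)

    def test_exhaustion_ratio_all_ones(self):
        num, den = EXHAUSTION_RATIO
        m = self._marker_matrix({g: [1.0, 1.0] for g in num + den})
        out = marker_ratio(m, num, den)
        np.testing.assert_allclose(out.values, 2.0)  # 4 genes / 2 genes

    def test_zero_denominator_flagged_nan(self):
        num, den = ANGIOPOIETIN_RATIO
        m = self._marker_matrix({"ANGPT1": [1.0], "ANGPT2": [0.0]})
        with pytest.warns(UserWarning, match="undefined"):
            out = marker_ratio(m, num, den)
        assert np.isnan(out.iloc[0])

    def test_scale_invariance(self):
        num, den = EXHAUSTION_RATIO
        rng = np.random.default_rng(1)
        vals = {g: rng.uniform(0.5, 3, 4) for g in num + den}
        m1 = self._marker_matrix(vals)
        m2 = self._marker_matrix({g: 2 * v for g, v in vals.items()})
        np.testing.assert_allclose(
            marker_ratio(m1, num, den).values, marker_ratio(m2, num, den).values
        )

    def test_missing_gene_raises_with_symbol(self):
        m = self._marker_matrix({"CD28": [1.0]})
        with pytest.raises(KeyError, match="PDCD1"):
            marker_ratio(m, *EXHAUSTION_RATIO)


class TestEstimators:
    def test_scorer_frozen_range_transform(self, mini_cohort):
        expr, clin, gt, refs = mini_cohort
        sig = SignaturePair(
            immune=GeneSet("I", "", gt.immune_genes),
            stromal=GeneSet("S", "", gt.stromal_genes),
            provenance=pd.DataFrame(),
        )
        X = expr.data.T  # samples x genes, sklearn convention
        scorer = SSGSEAScorer(signatures=sig).fit(X)
        out = scorer.transform(X.iloc[:10])
        ref = scorer.train_scores_.iloc[:10]
        np.testing.assert_allclose(out["immune_norm"], ref["immune_norm"], atol=1e-10)

    def test_subtype_classifier_round_trip(self, mini_cohort):
        expr, clin, gt, refs = mini_cohort
        sig = SignaturePair(
            immune=GeneSet("I", "", gt.immune_genes),
            stromal=GeneSet("S", "", gt.stromal_genes),
            provenance=pd.DataFrame(),
        )
        st = compute_istme(expr, sig)
        clf = TMESubtypeClassifier().fit(st.table)
        labels = clf.predict(st.table)
        ref = assign_subtypes(st)
        assert (labels == ref.labels.values).all()
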