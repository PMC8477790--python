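"""Stability selection and nearest-centroid fitting against small oracles."""

import numpy as np
import pytest
from scipy import stats

from tmepre import (SimulationConfig, StabilityParams, build_tmepre,
                    fit_centroid, optimize_cutoff, signature_scores,
                    simulate_cohort, stability_select, welch_t)
from tmepre.core_io import ExpressionMatrix
from tmepre.group_definition import GroupLabels, define_infiltration_groups

from conftest import REDUCED_ROUNDS


class TestWelchT:
    def test_matches_scalar_reference_per_gene(self, rng):
        pos = rng.normal(5, 1, size=(20, 4))
        neg = rng.normal(1, 2, size=(20, 5))
        t, p = welch_t(pos, neg)
        for i in range(20):
            ref = stats.ttest_ind(pos[i], neg[i], equal_var=False)
            assert abs(t[i] - ref.statistic) < 1e-10
            assert abs(p[i] - ref.pvalue) < 1e-10

    def test_null_genes_reject_at_nominal_rate(self, rng):
        pos = rng.normal(size=(1000, 30))
        neg = rng.normal(size=(1000, 50))
        _t, p = welch_t(pos, neg)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_zero_variance_conventions(self):
        pos = np.array([[2.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        neg = np.array([[2.0, 2.0], [1.0, 1.0]])
        t, p = welch_t(pos, neg)
        assert t[0] == 0.0 and p[0] == 1.0          # flat and equal: no evidence
        assert np.isinf(t[1]) and p[1] == 0.0       # flat but shifted

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t(np.ones((3, 1)), np.ones((3, 5)))


def _planted_contrast(n_pos=60, n_neg=90, n_planted=20, n_null=1000,
                      effect=3.0, seed=0):
    """Direct two-group matrix with planted differential genes."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    genes = [f"DIFF{i:03d}" for i in range(n_planted)] + \
            [f"NULL{i:04d}" for i in range(n_null)]
    values = rng.normal(7, 1, size=(len(genes), n))
    values[:n_planted, :n_pos] += effect
    ids = [f"S{i}" for i in range(n)]
    expr = ExpressionMatrix(genes, ids, values)
    labels = np.array(["POS"] * n_pos + ["NEG"] * n_neg, dtype=object)
    return expr, GroupLabels(ids, labels), genes[:n_planted]


class TestStabilitySelect:
    def test_recovers_planted_genes_at_strong_effect(self):
        hits = 0
        for seed in range(5):
            expr, groups, planted = _planted_contrast(effect=3.0, seed=seed)
            rep = stability_select(expr, groups, StabilityParams(
                n_rounds=REDUCED_ROUNDS, seed=seed))
            hits += set(planted) <= set(rep.selected)
        assert hits >= 4

    def test_null_contrast_selects_nothing(self):
        expr, groups, _ = _planted_contrast(effect=0.0, seed=7)
        rep = stability_select(expr, groups, StabilityParams(
            n_rounds=REDUCED_ROUNDS, seed=7))
        assert rep.selected == []
        # frequencies concentrate near top_k / n_genes
        assert rep.frequencies.mean() == pytest.approx(60 / 1020, rel=0.05)

    def test_each_round_marks_exactly_top_k(self):
        expr, groups, _ = _planted_contrast(n_null=200, seed=1)
        params = StabilityParams(n_rounds=20, seed=1)
        rep = stability_select(expr, groups, params)
        total = rep.frequencies.sum() * params.n_rounds
        assert total == pytest.approx(params.top_k * params.n_rounds)

    def test_same_seed_same_report(self):
        expr, groups, _ = _planted_contrast(n_null=200, seed=2)
        a = stability_select(expr, groups, StabilityParams(n_rounds=15, seed=9))
        b = stability_select(expr, groups, StabilityParams(n_rounds=15, seed=9))
        assert a.selected == b.selected
        assert (a.frequencies == b.frequencies).all()
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)

    def test_excluded_genes_never_candidates(self):
        expr, groups, planted = _planted_contrast(n_null=200, seed=3)
        rep = stability_select(expr, groups, StabilityParams(
            n_rounds=15, seed=3, excluded_genes=(planted[0],)))
        assert planted[0] not in rep.frequencies.index
        assert planted[0] not in rep.selected

    def test_group_too_small_for_folds(self):
        expr, groups, _ = _planted_contrast(n_pos=12, n_neg=90, n_null=50)
        with pytest.raises(ValueError, match="at least 20"):
            stability_select(expr, groups, StabilityParams(n_rounds=5))

    def test_recovery_monotone_in_effect_size(self):
        fractions = []
        for effect in (0.5, 1.5, 3.0):
            expr, groups, planted = _planted_contrast(effect=effect, seed=17)
            rep = stability_select(expr, groups, StabilityParams(
                n_rounds=REDUCED_ROUNDS, seed=17))
            fractions.append(len(set(planted) & set(rep.selected)) / len(planted))
        assert fractions == sorted(fractions)
        assert fractions[-1] >= 0.8


class TestCentroid:
    def _toy(self):
        # 2 genes, 3 POS / 3 NEG samples with hand-friendly values
        genes = ["G1", "G2"]
        ids = list("ABCDEF")
        values = np.array([[4.0, 5.0, 6.0, 0.0, 1.0, 2.0],
                           [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]])
        labels = np.array(["POS"] * 3 + ["NEG"] * 3, dtype=object)
        return ExpressionMatrix(genes, ids, values), GroupLabels(ids, labels)

    def test_scores_match_hand_arithmetic(self):
        expr, groups = self._toy()
        sig = fit_centroid(expr, groups, ["G1", "G2"])
        # hand-computed pooled standardization and centroids
        mu = expr.values.mean(axis=1)
        sd = expr.values.std(axis=1, ddof=1)
        z = (expr.values - mu[:, None]) / sd[:, None]
        c_pos, c_neg = z[:, :3].mean(axis=1), z[:, 3:].mean(axis=1)
        test = np.array([3.0, 4.0])
        zt = (test - mu) / sd
        expected = (np.linalg.norm(zt - c_neg) - np.linalg.norm(zt - c_pos)) / 2
        single = ExpressionMatrix(["G1", "G2"], ["X"], test[:, None])
        got = signature_scores(sig, single)["X"]
        assert abs(got - expected) < 1e-12

    def test_centroid_samples_score_symmetric(self):
        expr, groups = self._toy()
        sig = fit_centroid(expr, groups, ["G1", "G2"])
        at_pos = ExpressionMatrix(
            ["G1", "G2"], ["P"], (sig.centroid_pos * sig.sigma + sig.mu)[:, None])
        at_neg = ExpressionMatrix(
            ["G1", "G2"], ["N"], (sig.centroid_neg * sig.sigma + sig.mu)[:, None])
        s_pos = signature_scores(sig, at_pos)["P"]
        s_neg = signature_scores(sig, at_neg)["N"]
        assert s_pos > 0 > s_neg
        assert abs(s_pos + s_neg) < 1e-12

    def test_label_swap_negates_scores(self):
        expr, groups = self._toy()
        swapped = GroupLabels(groups.sample_ids,
                              np.where(groups.labels == "POS", "NEG", "POS"))
        s1 = signature_scores(fit_centroid(expr, groups, ["G1", "G2"]), expr)
        s2 = signature_scores(fit_centroid(expr, swapped, ["G1", "G2"]), expr)
        np.testing.assert_allclose(s1.to_numpy(), -s2.to_numpy(), atol=1e-12)

    def test_gene_order_does_not_change_scores(self):
        expr, groups = self._toy()
        s1 = signature_scores(fit_centroid(expr, groups, ["G1", "G2"]), expr)
        s2 = signature_scores(fit_centroid(expr, groups, ["G2", "G1"]), expr)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        genes = ["G1", "FLAT"]
        ids = list("ABCD")
        values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        labels = np.array(["POS", "POS", "NEG", "NEG"], dtype=object)
        with pytest.raises(ValueError, match="FLAT"):
            fit_centroid(ExpressionMatrix(genes, ids, values),
                         GroupLabels(ids, labels), genes)


class TestOptimizeCutoff:
    def test_enumerated_thresholds_confirm_optimum(self):
        pos, neg = np.array([0.5, 0.8]), np.array([-0.7, -0.2])
        c = optimize_cutoff(pos, neg)
        assert c == 0.5
        # brute-force over candidate thresholds: among sensitivity-1 cutoffs
        # none has higher specificity
        for cand in np.concatenate([pos, neg, [c]]):
            sens = (pos >= cand).mean()
            spec = (neg < cand).mean()
            if sens == 1.0:
                assert spec <= (neg < c).mean()
        assert (neg < c).mean() == 1.0

    def test_overlapping_groups_keep_sensitivity_one(self):
        # positives span below every negative: sensitivity stays 1 at the
        # price of zero specificity
        pos, neg = np.array([-1.0, 2.0]), np.array([0.0, 3.0])
        c = optimize_cutoff(pos, neg)
        assert (pos >= c).all()
        assert (neg < c).mean() == 0.0

    def test_singleton_positive(self):
        assert optimize_cutoff([0.3], [-1.0]) == 0.3


class TestBuildTmepre:
    def test_model_structure_on_paper_scale_cohort(self, model):
        assert len(model.tme1.genes) > 0
        assert len(model.tme2.genes) > 0
        assert model.tme1.cutoff is not None and model.tme2.cutoff is not None
        assert model.marker_cd8a == "CD8A"

    def test_infiltration_marker_never_in_its_signature(self, model):
        assert "CD8A" not in model.tme1.genes

    def test_selected_genes_come_from_planted_programs(self, model, cohort):
        _expr, _ann, truth = cohort
        allowed1 = set(truth.infiltration_genes) | set(truth.exhaustion_genes) \
            | {"PDCD1", "HAVCR2"}
        assert set(model.tme1.genes) <= allowed1
        assert len(set(model.tme1.genes) & set(truth.infiltration_genes)) \
            >= 0.8 * len(truth.infiltration_genes)
        allowed2 = set(truth.exhaustion_genes) | {"PDCD1", "HAVCR2"}
        assert set(model.tme2.genes) <= allowed2

    def test_derivation_is_deterministic(self, cohort):
        expr, ann, _ = cohort
        kw = dict(n_rounds=10, seed=33)
        m1 = build_tmepre(expr, ann, StabilityParams(**kw), StabilityParams(**kw))
        m2 = build_tmepre(expr, ann, StabilityParams(**kw), StabilityParams(**kw))
        assert m1.to_dict() == m2.to_dict()

    def test_stage_errors_carry_stage_name(self, cohort):
        expr, ann, _ = cohort
        bad = ann.copy()
        bad["msi_status"] = "MSS"
        with pytest.raises(ValueError, match="infiltration groups"):
            build_tmepre(expr, bad, StabilityParams(n_rounds=5),
                         StabilityParams(n_rounds=5))
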