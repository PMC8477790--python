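"""Stability-based gene selection and nearest-centroid fitting.

Selection runs many rounds of stratified 10-fold cross-validation on a
two-group contrast.  One round draws one stratified partition, holds out one
fold, and ranks genes by Welch t-test p-value.  A gene is selected if it
lands in the top ``top_k`` of that ranking in at least ``min_frequency`` of
the rounds (defaults: top 60 in >=80% of 200 rounds).  Selected genes
parameterize a nearest-centroid score with a cutoff placed to keep training
sensitivity at 1.

By default each round's t-test runs on the held-out fold (``test_split =
"holdout"``), so consecutive rounds score nearly disjoint sample subsets and
the frequency filter measures genuine selection stability: under a null
contrast no gene stays in the top ranks across rounds.  The alternative
``test_split = "train"`` tests on the retained 90%; because rounds then share
almost all their data, any gene associated with the contrast in the full
cohort — including chance associations — is reproduced in every round, and
the frequency filter loses its bite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CentroidSignature, ExpressionMatrix, TmepreModel
from .group_definition import (GroupLabels, define_exhaustion_groups,
                               define_infiltration_groups)


@dataclass
class StabilityParams:
    """Knobs of the stability-selection procedure."""

    n_rounds: int = 200
    n_folds: int = 10
    top_k: int = 60
    min_frequency: float = 0.80
    excluded_genes: tuple[str, ...] = ()
    seed: int = 0
    test_split: str = "holdout"  # "holdout": t-test on the held-out fold;
    #                              "train": t-test on the retained folds

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.top_k < 1:
            raise ValueError("n_rounds and top_k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.min_frequency <= 1:
            raise ValueError("min_frequency must be in (0, 1]")
        if self.test_split not in ("holdout", "train"):
            raise ValueError("test_split must be 'holdout' or 'train'")
        self.excluded_genes = tuple(self.excluded_genes)


@dataclass
class SelectionReport:
    """Per-gene selection frequencies plus the per-round fold assignments
    (rounds x samples fold index, for audit)."""

    frequencies: pd.Series  # index: candidate gene, value in [0, 1]
    selected: list[str]
    sample_ids: list[str]
    fold_assignments: np.ndarray  # shape (n_rounds, n_samples)
    params: StabilityParams

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame({
            "gene": self.frequencies.index,
            "frequency": self.frequencies.to_numpy(),
            "selected": [g in sel for g in self.frequencies.index],
        })


def welch_t(values_pos: np.ndarray, values_neg: np.ndarray):
    """Vectorized two-sided Welch t-test over gene rows.

    Returns (t, p) arrays.  Genes with zero variance in both groups get
    t = 0, p = 1 when the group means agree (the statistic is undefined);
    with differing means they get t = +/-inf, p = 0.
    """
    values_pos = np.atleast_2d(np.asarray(values_pos, dtype=float))
    values_neg = np.atleast_2d(np.asarray(values_neg, dtype=float))
    if values_pos.shape[1] < 2 or values_neg.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(values_pos, values_neg, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    flat = (values_pos.var(axis=1) == 0) & (values_neg.var(axis=1) == 0)
    if flat.any():
        diff = values_pos[:, 0] - values_neg[:, 0]
        equal = flat & (diff == 0)
        t[equal], p[equal] = 0.0, 1.0
        unequal = flat & (diff != 0)
        t[unequal] = np.sign(diff[unequal]) * np.inf
        p[unequal] = 0.0
    return t, p


def _rank_genes(p: np.ndarray, t: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorted by ascending p, ties by larger |t|, then gene id."""
    return np.lexsort((gene_ids, -np.abs(t), p))


def _stratified_folds(rng: np.random.Generator, n_pos: int, n_neg: int,
                      n_folds: int) -> tuple[np.ndarray, np.ndarray]:
    """Random fold index per sample, separately within POS and NEG."""
    def assign(n: int) -> np.ndarray:
        fold = np.arange(n) % n_folds
        return fold[rng.permutation(n)]
    return assign(n_pos), assign(n_neg)


def stability_select(expr: ExpressionMatrix, groups: GroupLabels,
                     params: StabilityParams) -> SelectionReport:
    """Run the repeated cross-validation selection on a POS/NEG contrast."""
    pos_ids, neg_ids = groups.pos_ids, groups.neg_ids
    # every fold needs >=2 samples per class when tested on the holdout, and
    # the retained split needs >=2 per class when tested on the training side
    min_needed = 2 * params.n_folds if params.test_split == "holdout" else params.n_folds
    for name, ids in (("POS", pos_ids), ("NEG", neg_ids)):
        if len(ids) < min_needed:
            raise ValueError(
                f"{name} group has {len(ids)} samples; need at least "
                f"{min_needed} for {params.n_folds}-fold partitions with "
                f"test_split={params.test_split!r}"
            )
    excluded = set(params.excluded_genes)
    candidates = np.asarray([g for g in expr.gene_ids if g not in excluded])
    if candidates.size == 0:
        raise ValueError("no candidate genes after exclusions")
    pos_idx = expr.sample_indices(pos_ids)
    neg_idx = expr.sample_indices(neg_ids)
    sub = expr.subset_genes(list(candidates))
    pos_vals, neg_vals = sub[:, pos_idx], sub[:, neg_idx]

    rng = np.random.default_rng(params.seed)
    counts = np.zeros(candidates.size, dtype=int)
    assignments = np.empty((params.n_rounds, len(pos_ids) + len(neg_ids)), dtype=int)
    for r in range(params.n_rounds):
        fold_pos, fold_neg = _stratified_folds(
            rng, len(pos_ids), len(neg_ids), params.n_folds)
        assignments[r] = np.concatenate([fold_pos, fold_neg])
        held = r % params.n_folds
        if params.test_split == "holdout":
            t, p = welch_t(pos_vals[:, fold_pos == held], neg_vals[:, fold_neg == held])
        else:
            t, p = welch_t(pos_vals[:, fold_pos != held], neg_vals[:, fold_neg != held])
        order = _rank_genes(p, t, candidates)
        counts[order[:params.top_k]] += 1

    freq = pd.Series(counts / params.n_rounds, index=candidates, name="frequency")
    hits = freq[freq >= params.min_frequency]
    # descending frequency, ties by gene id (stable secondary sort)
    selected = list(hits.sort_index(kind="stable")
                        .sort_values(ascending=False, kind="stable").index)
    return SelectionReport(freq, selected, pos_ids + neg_ids, assignments, params)


def fit_centroid(expr: ExpressionMatrix, groups: GroupLabels,
                 genes: list[str], positive_label: str = "POS") -> CentroidSignature:
    """Fit standardization and class centroids on the POS/NEG training samples.

    mu/sigma are pooled over POS+NEG samples (sd with ddof=1); centroids are
    the standardized group means.  The cutoff is left unset.
    """
    if not genes:
        raise ValueError("selected gene list is empty")
    pos_idx = expr.sample_indices(groups.pos_ids)
    neg_idx = expr.sample_indices(groups.neg_ids)
    sub = expr.subset_genes(list(genes))
    train = sub[:, np.concatenate([pos_idx, neg_idx])]
    mu = train.mean(axis=1)
    sigma = train.std(axis=1, ddof=1)
    if (sigma == 0).any():
        bad = [g for g, s in zip(genes, sigma) if s == 0]
        raise ValueError(
            f"zero training variance for gene(s) {bad}; drop them before fitting"
        )
    z = (sub - mu[:, None]) / sigma[:, None]
    return CentroidSignature(
        list(genes), mu, sigma,
        centroid_pos=z[:, pos_idx].mean(axis=1),
        centroid_neg=z[:, neg_idx].mean(axis=1),
        positive_label=positive_label,
    )


def signature_scores(sig: CentroidSignature, expr: ExpressionMatrix) -> pd.Series:
    """Nearest-centroid score per sample.

    score = (dist to negative centroid - dist to positive centroid) / n_genes,
    Euclidean distance on standardized values; higher = more positive-like.
    """
    sub = expr.subset_genes(sig.genes)
    z = (sub - sig.mu[:, None]) / sig.sigma[:, None]
    d_pos = np.linalg.norm(z - sig.centroid_pos[:, None], axis=0)
    d_neg = np.linalg.norm(z - sig.centroid_neg[:, None], axis=0)
    return pd.Series((d_neg - d_pos) / len(sig.genes), index=expr.sample_ids)


def optimize_cutoff(pos_scores, neg_scores) -> float:
    """Largest threshold keeping every training positive at or above it.

    Maximizing sensitivity (no false negatives on training positives) pins the
    cutoff at min(POS scores); among thresholds with sensitivity 1 this is the
    most specific one.  Classification rule downstream: score >= cutoff => POS.
    """
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    return float(pos_scores.min())


def build_tmepre(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    params_tme1: StabilityParams | None = None,
    params_tme2: StabilityParams | None = None,
    model_params: TmepreModel | None = None,
    *,
    marker_cd8a: str = "CD8A",
    marker_pd1: str = "PDCD1",
    marker_tim3: str = "HAVCR2",
    infiltration_percentile: float = 0.40,
    validation_low_quantile: float = 0.25,
    validation_high_quantile: float = 0.75,
    cd8_restricted_genes: list[str] | None = None,
    return_reports: bool = False,
):
    """Derive the full two-component model from a training cohort.

    Pipeline per component: define groups -> stability-select genes (the
    infiltration marker itself is excluded from the infiltration component)
    -> fit centroids -> optimize cutoff.  Errors from a stage are re-raised
    with the stage name attached.
    """
    from .core_io import DEFAULT_CD8_RESTRICTED_GENES

    if model_params is not None:
        marker_cd8a = model_params.marker_cd8a
        marker_pd1 = model_params.marker_pd1
        marker_tim3 = model_params.marker_tim3
        infiltration_percentile = model_params.infiltration_percentile
        validation_low_quantile = model_params.validation_low_quantile
        validation_high_quantile = model_params.validation_high_quantile
        cd8_restricted_genes = list(model_params.cd8_restricted_genes)
    if cd8_restricted_genes is None:
        cd8_restricted_genes = list(DEFAULT_CD8_RESTRICTED_GENES)
    params_tme1 = params_tme1 or StabilityParams()
    params_tme2 = params_tme2 or StabilityParams(seed=params_tme1.seed + 1)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    groups1, _cutoff = stage(
        "infiltration groups", define_infiltration_groups, expr, ann,
        marker=marker_cd8a, percentile=infiltration_percentile)
    p1 = dataclasses.replace(
        params_tme1,
        excluded_genes=tuple(sorted(set(params_tme1.excluded_genes) | {marker_cd8a})))
    report1 = stage("infiltration selection", stability_select, expr, groups1, p1)
    if not report1.selected:
        raise ValueError("[infiltration selection] no gene passed the frequency threshold")
    sig1 = stage("infiltration centroid", fit_centroid, expr, groups1,
                 report1.selected, "high_infiltration")
    s1 = signature_scores(sig1, expr)
    sig1.cutoff = optimize_cutoff(s1[groups1.pos_ids], s1[groups1.neg_ids])

    groups2 = stage("exhaustion groups", define_exhaustion_groups, expr,
                    groups1.pos_ids, marker_pd1=marker_pd1, marker_tim3=marker_tim3)
    report2 = stage("exhaustion selection", stability_select, expr, groups2, params_tme2)
    if not report2.selected:
        raise ValueError("[exhaustion selection] no gene passed the frequency threshold")
    sig2 = stage("exhaustion centroid", fit_centroid, expr, groups2,
                 report2.selected, "responsive")
    s2 = signature_scores(sig2, expr)
    sig2.cutoff = optimize_cutoff(s2[groups2.pos_ids], s2[groups2.neg_ids])

    model = TmepreModel(
        tme1=sig1, tme2=sig2,
        marker_cd8a=marker_cd8a, marker_pd1=marker_pd1, marker_tim3=marker_tim3,
        infiltration_percentile=infiltration_percentile,
        validation_low_quantile=validation_low_quantile,
        validation_high_quantile=validation_high_quantile,
        cd8_restricted_genes=cd8_restricted_genes,
    )
    if return_reports:
        return model, report1, report2
    return model
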