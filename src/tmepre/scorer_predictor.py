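"""Apply a fitted model: scores, classification rules, read-outs.

Two classification rules exist.  The training-cohort rule uses the cutoffs
optimized during derivation (same platform).  The validation rule is
rank-based and platform-free: a sample is a nonresponder when its
infiltration score falls in the cohort's lowest quartile, or in the highest
quartile while its exhaustion-state score is below the cohort median
(infiltrated but terminally exhausted).  Mechanism labels record which of the
two escape routes applies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, TmepreModel
from .group_definition import percentile_cutoff
from .signature_builder import signature_scores

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
MECH_NONE = "none"
MECH_INSUFFICIENT = "insufficient_infiltration"
MECH_EXHAUSTION = "terminal_exhaustion"


def score_samples(model: TmepreModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Continuous TME1 (infiltration) and TME2 (responsive-state) scores.

    Raises if any signature gene is missing from the matrix (listing them).
    """
    return pd.DataFrame({
        "sample_id": expr.sample_ids,
        "tme1_score": signature_scores(model.tme1, expr).to_numpy(),
        "tme2_score": signature_scores(model.tme2, expr).to_numpy(),
    })


def _finish(scores: pd.DataFrame, responder_mask: np.ndarray,
            insufficient_mask: np.ndarray) -> pd.DataFrame:
    out = scores.copy()
    out["predicted"] = np.where(responder_mask, RESPONDER, NONRESPONDER)
    mech = np.where(responder_mask, MECH_NONE,
                    np.where(insufficient_mask, MECH_INSUFFICIENT, MECH_EXHAUSTION))
    out["mechanism"] = mech
    return out


def classify_training_cohort(model: TmepreModel, scores: pd.DataFrame,
                             ann: pd.DataFrame):
    """Cutoff-based rule: responder iff both scores reach their trained cutoffs.

    Nonresponder mechanism is insufficient_infiltration when the infiltration
    score is below its cutoff, else terminal_exhaustion.  Returns the
    prediction table and a per-MSI-stratum summary.
    """
    from .evaluation import summarize_cohort

    if model.tme1.cutoff is None or model.tme2.cutoff is None:
        raise ValueError("model cutoffs are unset; derive or load a full model")
    t1 = scores["tme1_score"].to_numpy()
    t2 = scores["tme2_score"].to_numpy()
    infiltrated = t1 >= model.tme1.cutoff
    responder = infiltrated & (t2 >= model.tme2.cutoff)
    result = _finish(scores, responder, ~infiltrated)
    return result, summarize_cohort(result, ann)


def classify_validation_cohort(model: TmepreModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Rank-based rule for cohorts on a different platform.

    Within-cohort quantiles of the infiltration score mark the extreme
    quartiles; the cohort median of the exhaustion-state score splits low from
    high.  Nonresponder iff infiltration in the lowest quartile, or in the
    highest quartile with a below-median exhaustion-state score.
    """
    if len(scores) < 4:
        raise ValueError("validation rule needs a cohort of at least 4 samples")
    t1 = scores["tme1_score"].to_numpy(dtype=float)
    t2 = scores["tme2_score"].to_numpy(dtype=float)
    low_cut = percentile_cutoff(t1, model.validation_low_quantile)
    high_cut = percentile_cutoff(t1, model.validation_high_quantile)
    med_t2 = float(np.median(t2))
    lowest = t1 <= low_cut
    highest = t1 > high_cut
    nonresponder = lowest | (highest & (t2 < med_t2))
    return _finish(scores, ~nonresponder, lowest)


def cd8_restricted_readout(model: TmepreModel, expr: ExpressionMatrix,
                           gene_subset: list[str] | None = None) -> pd.Series:
    """Exhaustion-state score restricted to CD8-expressed signature genes.

    For purified CD8+ T-cell data the bulk-derived signature is narrowed to
    the genes primarily expressed by CD8+ T cells (default: the configured
    nine-gene subset).  Centroids and standardization are restricted to those
    genes; higher score = progenitor-exhausted-like (anti-PD1 responsive).
    """
    subset = model.cd8_restricted_genes if gene_subset is None else gene_subset
    restricted = model.tme2.restrict(list(subset))
    return signature_scores(restricted, expr)


def omega_range_coverage(scores_subset, scores_all) -> float:
    """Relative range coverage: subgroup score range over full-cohort range.

    omega = (max(subset) - min(subset)) / (max(all) - min(all)); lies in [0, 1]
    for a subgroup of the cohort and measures how much of the score's dynamic
    range the subgroup uses.
    """
    scores_subset = np.asarray(scores_subset, dtype=float)
    scores_all = np.asarray(scores_all, dtype=float)
    if scores_subset.size == 0 or scores_all.size == 0:
        raise ValueError("score vectors must be nonempty")
    denom = scores_all.max() - scores_all.min()
    if denom == 0:
        raise ValueError("full-cohort scores have zero range")
    return float((scores_subset.max() - scores_subset.min()) / denom)
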