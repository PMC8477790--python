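"""Training-contrast construction from marker-gene cutoffs.

The infiltration contrast compares MSI tumors with high CD8A (above the 40th
percentile of CD8A within MSI tumors) against MSS tumors with low CD8A.  The
exhaustion contrast, within the infiltration-positive samples, compares tumors
with both PD1 (PDCD1) and TIM3 (HAVCR2) below their medians (still responsive,
POS) against tumors with both above (terminally exhausted, NEG).  All
comparisons are strict; ties fall into neither group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, TmepreModel

POS = "POS"
NEG = "NEG"
EXCLUDED = "EXCLUDED"


@dataclass
class GroupLabels:
    """POS/NEG/EXCLUDED label per sample; POS and NEG are disjoint by construction."""

    sample_ids: list[str]
    labels: np.ndarray  # array of {POS, NEG, EXCLUDED}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length must match sample_ids")
        bad = set(self.labels) - {POS, NEG, EXCLUDED}
        if bad:
            raise ValueError(f"invalid group labels {sorted(bad)}")

    @property
    def pos_ids(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == POS]

    @property
    def neg_ids(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == NEG]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels})


def percentile_cutoff(values, p: float) -> float:
    """Empirical p-th percentile as the ceil(p*n)-th smallest value.

    Under this convention the strictly-above count of n distinct values is
    n - ceil(p*n); e.g. 131 distinct values at p=0.40 leave 78 above.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty vector")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in percentile input")
    if not 0 < p < 1:
        raise ValueError("percentile p must be in (0, 1)")
    k = math.ceil(p * values.size)
    return float(np.sort(values)[k - 1])


def _marker_by_sample(expr: ExpressionMatrix, gene: str) -> pd.Series:
    return pd.Series(expr.gene_values(gene), index=expr.sample_ids)


def define_infiltration_groups(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    model_params: TmepreModel | None = None,
    *,
    marker: str = "CD8A",
    percentile: float = 0.40,
) -> tuple[GroupLabels, float]:
    """Infiltration contrast: POS = MSI above the MSI-derived CD8A cutoff,
    NEG = MSS below it; everything else (MSI-L, Unknown, ties, MSI below,
    MSS above) is EXCLUDED.  Returns the labels and the cutoff."""
    if model_params is not None:
        marker = model_params.marker_cd8a
        percentile = model_params.infiltration_percentile
    status = ann.set_index("sample_id")["msi_status"].reindex(expr.sample_ids)
    if status.isna().any():
        missing = [s for s, v in status.items() if pd.isna(v)]
        raise ValueError(f"samples missing from annotations: {missing}")
    cd8a = _marker_by_sample(expr, marker)
    msi_values = cd8a[status == "MSI"]
    if msi_values.empty:
        raise ValueError("no MSI samples; cannot derive infiltration cutoff")
    cutoff = percentile_cutoff(msi_values.to_numpy(), percentile)
    labels = np.full(expr.n_samples, EXCLUDED, dtype=object)
    labels[((status == "MSI") & (cd8a > cutoff)).to_numpy()] = POS
    labels[((status == "MSS") & (cd8a < cutoff)).to_numpy()] = NEG
    groups = GroupLabels(list(expr.sample_ids), labels)
    for side, ids in (("POS (MSI, high marker)", groups.pos_ids),
                      ("NEG (MSS, low marker)", groups.neg_ids)):
        if not ids:
            raise ValueError(f"infiltration contrast group {side} is empty")
    return groups, cutoff


def define_exhaustion_groups(
    expr: ExpressionMatrix,
    infiltration_pos_ids: list[str],
    model_params: TmepreModel | None = None,
    *,
    marker_pd1: str = "PDCD1",
    marker_tim3: str = "HAVCR2",
) -> GroupLabels:
    """Exhaustion contrast within the infiltration-positive samples.

    Medians of PD1 and TIM3 are computed on those samples; both-strictly-below
    is POS (T cells can still respond), both-strictly-above is NEG (terminal
    exhaustion).  Higher downstream scores therefore mean a responsive
    microenvironment.  Samples outside the infiltration-positive set, or with
    a mixed / tied marker pattern, are EXCLUDED.
    """
    if model_params is not None:
        marker_pd1 = model_params.marker_pd1
        marker_tim3 = model_params.marker_tim3
    if not infiltration_pos_ids:
        raise ValueError("infiltration-positive set is empty")
    pd1 = _marker_by_sample(expr, marker_pd1)
    tim3 = _marker_by_sample(expr, marker_tim3)
    pos_set = set(infiltration_pos_ids)
    in_pos = np.asarray([s in pos_set for s in expr.sample_ids])
    med_pd1 = float(np.median(pd1[in_pos]))
    med_tim3 = float(np.median(tim3[in_pos]))
    labels = np.full(expr.n_samples, EXCLUDED, dtype=object)
    responsive = in_pos & (pd1 < med_pd1).to_numpy() & (tim3 < med_tim3).to_numpy()
    exhausted = in_pos & (pd1 > med_pd1).to_numpy() & (tim3 > med_tim3).to_numpy()
    labels[responsive] = POS
    labels[exhausted] = NEG
    groups = GroupLabels(list(expr.sample_ids), labels)
    for side, ids in (("POS (responsive, both markers low)", groups.pos_ids),
                      ("NEG (terminally exhausted, both markers high)", groups.neg_ids)):
        if not ids:
            raise ValueError(f"exhaustion contrast group {side} is empty")
    return groups
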