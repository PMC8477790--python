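"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the method assumes in a
normalized bulk-expression cohort: a latent CD8+ T-cell infiltration program
(CD8A plus a block of planted genes shifted up in infiltrated tumors), a
latent terminal-exhaustion program nested inside infiltration (PDCD1, HAVCR2
plus a second block), MSI/MSS labels with different infiltration prevalence,
and i.i.d. Gaussian background genes in log2 space.  A companion generator
produces purified-CD8 T-cell profiles in progenitor vs terminal exhaustion
states, and survival times can be attached to predicted labels with a
configurable true hazard ratio.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a fixed
seed reproduces cohorts bit-for-bit across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, validate_annotations

MARKER_GENES = ("CD8A", "PDCD1", "HAVCR2")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the cohort generator.

    Defaults mirror the training-cohort composition (131 MSI / 284 MSS) with
    an infiltration prevalence of 0.6 among MSI tumors (≈40% of MSI tumors
    lack high infiltration) and 0.1 among MSS, half of infiltrated tumors
    terminally exhausted, 3 log2-unit planted effects over unit-SD noise.
    """

    n_msi: int = 131
    n_mss: int = 284
    n_genes: int = 1000
    n_infiltration_genes: int = 20
    n_exhaustion_genes: int = 20
    effect_size_infiltration: float = 3.0
    effect_size_exhaustion: float = 3.0
    noise_sd: float = 1.0
    frac_msi_infiltrated: float = 0.6
    frac_mss_infiltrated: float = 0.1
    frac_infiltrated_exhausted: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_msi < 1 or self.n_mss < 0:
            raise ValueError("need at least one MSI sample and nonnegative n_mss")
        planted = self.n_infiltration_genes + self.n_exhaustion_genes + len(MARKER_GENES)
        if planted > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {planted} planted+marker genes"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("frac_msi_infiltrated", "frac_mss_infiltrated",
                     "frac_infiltrated_exhausted"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulationTruth:
    """Planted latent states and gene programs of a simulated cohort."""

    infiltrated: dict  # sample_id -> bool
    exhausted: dict    # sample_id -> bool (true only where infiltrated)
    infiltration_genes: list[str] = field(default_factory=list)
    exhaustion_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.exhausted.items():
            if e and not self.infiltrated.get(s, False):
                raise ValueError(f"sample {s} exhausted but not infiltrated")

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump({
                "infiltrated": self.infiltrated,
                "exhausted": self.exhausted,
                "infiltration_genes": self.infiltration_genes,
                "exhaustion_genes": self.exhaustion_genes,
            }, fh, indent=1)
            fh.write("\n")


def simulate_cohort(config: SimulationConfig):
    """Draw one cohort; returns (ExpressionMatrix, annotations, SimulationTruth).

    Gene layout: the three marker genes, then INF#### / EXH#### planted blocks,
    then BG#### background genes.  Baseline per-gene means are N(7, 2) in log2
    units; per-cell noise is N(0, noise_sd).  Infiltrated samples get CD8A and
    the infiltration block shifted up by ``effect_size_infiltration``;
    exhausted samples (a subset of infiltrated ones) additionally get PDCD1,
    HAVCR2 and the exhaustion block shifted by ``effect_size_exhaustion``.
    """
    rng = np.random.default_rng(config.seed)
    inf_genes = [f"INF{i:04d}" for i in range(config.n_infiltration_genes)]
    exh_genes = [f"EXH{i:04d}" for i in range(config.n_exhaustion_genes)]
    n_bg = config.n_genes - len(MARKER_GENES) - len(inf_genes) - len(exh_genes)
    bg_genes = [f"BG{i:04d}" for i in range(n_bg)]
    gene_ids = list(MARKER_GENES) + inf_genes + exh_genes + bg_genes

    n = config.n_msi + config.n_mss
    sample_ids = [f"S{i:04d}" for i in range(n)]
    msi_status = np.array(["MSI"] * config.n_msi + ["MSS"] * config.n_mss)

    p_inf = np.where(msi_status == "MSI", config.frac_msi_infiltrated,
                     config.frac_mss_infiltrated)
    infiltrated = rng.random(n) < p_inf
    exhausted = infiltrated & (rng.random(n) < config.frac_infiltrated_exhausted)

    baseline = rng.normal(7.0, 2.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                            size=(config.n_genes, n))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    inf_rows = [gene_index["CD8A"]] + [gene_index[g] for g in inf_genes]
    exh_rows = [gene_index["PDCD1"], gene_index["HAVCR2"]] + \
               [gene_index[g] for g in exh_genes]
    values[np.ix_(inf_rows, np.flatnonzero(infiltrated))] += \
        config.effect_size_infiltration
    values[np.ix_(exh_rows, np.flatnonzero(exhausted))] += \
        config.effect_size_exhaustion

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    ann = validate_annotations(pd.DataFrame({
        "sample_id": sample_ids,
        "msi_status": msi_status,
        "cohort": "simulated",
    }))
    truth = SimulationTruth(
        infiltrated=dict(zip(sample_ids, map(bool, infiltrated))),
        exhausted=dict(zip(sample_ids, map(bool, exhausted))),
        infiltration_genes=inf_genes,
        exhaustion_genes=exh_genes,
    )
    return expr, ann, truth


def simulate_purified_tcells(
    n_per_group: int,
    effect: float,
    seed: int,
    *,
    shifted_genes: tuple[str, ...] = ("PDCD1", "HAVCR2"),
    extra_genes: tuple[str, ...] = (),
    n_background: int = 200,
    noise_sd: float = 1.0,
):
    """Purified CD8+ T-cell profiles: progenitor vs terminally exhausted.

    The terminal group has the inhibitory receptors plus any configured
    CD8-restricted genes (``shifted_genes`` + ``extra_genes``) shifted up by
    ``effect`` log2 units.  Returns (ExpressionMatrix, labels) with labels in
    {'progenitor', 'terminal'}.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    shifted = list(dict.fromkeys(list(shifted_genes) + list(extra_genes)))
    bg = [f"TBG{i:04d}" for i in range(n_background)]
    gene_ids = shifted + bg
    n = 2 * n_per_group
    sample_ids = [f"T{i:04d}" for i in range(n)]
    labels = ["progenitor"] * n_per_group + ["terminal"] * n_per_group
    baseline = rng.normal(7.0, 2.0, size=len(gene_ids))
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(gene_ids), n))
    values[np.ix_(range(len(shifted)), range(n_per_group, n))] += effect
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


def simulate_survival(
    ann: pd.DataFrame,
    predicted: pd.Series | dict,
    hr_true: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    *,
    baseline_hazard: float = 1.0 / 365.0,
):
    """Attach exponential survival to predicted labels.

    Event times are exponential with hazard ``baseline_hazard`` for predicted
    responders and ``hr_true * baseline_hazard`` for predicted nonresponders.
    Each sample is independently censored with probability ``censor_rate``, in
    which case its time is drawn uniformly on (0, event time) and the event
    flag cleared.  Returns a copy of the annotations with surv_time/surv_event
    filled in (days).
    """
    if hr_true <= 0:
        raise ValueError("hr_true must be positive")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pred = pd.Series(predicted)
    labels = pred.reindex(ann["sample_id"])
    if labels.isna().any():
        missing = ann.loc[labels.isna().to_numpy(), "sample_id"].tolist()
        raise ValueError(f"samples without predicted label: {missing}")
    hazard = np.where(labels.to_numpy() == "nonresponder",
                      hr_true * baseline_hazard, baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(ann)) < censor_rate
    time = np.where(censored, rng.random(len(ann)) * t_event, t_event)
    out = ann.copy()
    out["surv_time"] = time
    out["surv_event"] = ~censored
    return validate_annotations(out)
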