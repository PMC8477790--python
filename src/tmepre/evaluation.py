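"""Survival statistics, p-value combination, and cohort summaries.

Hazard ratios come from a single-covariate Cox proportional-hazards fit
(Efron tie handling, via lifelines); group separation p-values from the
two-group log-rank test; independent validation p-values are pooled with the
unweighted Stouffer Z-transform.  Cohort summaries report counts and
one-decimal percentages of predicted responders and the two nonresponder
mechanism classes per MSI stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class SurvivalResult:
    hazard_ratio: float
    beta: float
    se: float
    logrank_stat: float
    logrank_p: float
    logrank_p_one_sided: float
    n_per_group: dict
    km_curves: dict  # group -> DataFrame(time, at_risk, survival)

    def to_dict(self) -> dict:
        return {
            "hazard_ratio": self.hazard_ratio,
            "beta": self.beta,
            "se": self.se,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "logrank_p_one_sided": self.logrank_p_one_sided,
            "n_per_group": self.n_per_group,
        }


def _two_groups(times, events, labels):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    if times.shape != events.shape or times.shape != labels.shape:
        raise ValueError("times, events and labels must have equal length")
    uniq = sorted(pd.unique(labels).tolist(), key=str)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if events.sum() == 0:
        raise ValueError("no observed events; survival tests are undefined")
    return times, events, labels, uniq


def _observed_minus_expected(times, events, mask) -> float:
    """Sum over event times of (observed - expected) deaths in the masked group."""
    oe = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & mask).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & mask).sum()
        oe += d1 - d * n1 / n
    return oe


def logrank_test(times, events, labels, worse_label=None):
    """Two-group log-rank test.

    Returns (chi-square statistic, two-sided p, one-sided p).  The one-sided p
    is oriented toward ``worse_label`` having worse survival (defaults to
    'nonresponder' when present, else the second group in sorted order), so a
    cohort where nonresponders die faster gives one-sided p < 0.5.
    """
    times, events, labels, uniq = _two_groups(times, events, labels)
    if worse_label is None:
        worse_label = "nonresponder" if "nonresponder" in uniq else uniq[1]
    if worse_label not in uniq:
        raise ValueError(f"worse_label {worse_label!r} not among groups {uniq}")
    mask = labels == worse_label
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    stat, p_two = float(res.test_statistic), float(res.p_value)
    direction_worse = _observed_minus_expected(times, events, mask) > 0
    p_one = p_two / 2 if direction_worse else 1 - p_two / 2
    return stat, p_two, p_one


def cox_hr(times, events, covariate):
    """Single-covariate Cox PH fit; HR = exp(beta) for covariate level 1 vs 0.

    Efron tie handling.  Monotone-likelihood / separation failures are
    reported as an infinite-HR result rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    covariate = np.asarray(covariate, dtype=float)
    if len(np.unique(covariate)) < 2:
        raise ValueError("covariate must take at least two values")
    if events.sum() == 0:
        raise ValueError("no observed events; Cox model is undefined")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "x": covariate})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
        beta = float(fitter.params_["x"])
        se = float(fitter.standard_errors_["x"])
    except ConvergenceError:
        sign = 1.0 if _observed_minus_expected(times, events, covariate > 0) > 0 else -1.0
        return sign * np.inf if sign > 0 else 0.0, sign * np.inf, np.inf
    return float(np.exp(beta)), beta, se


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier step function as a (time, at_risk, survival) table."""
    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    table = km.event_table
    return pd.DataFrame({
        "time": table.index.to_numpy(),
        "at_risk": table["at_risk"].to_numpy(),
        "survival": km.survival_function_["KM_estimate"].to_numpy(),
    })


def survival_analysis(times, events, labels, worse_label=None) -> SurvivalResult:
    """Log-rank + Cox + KM curves for a two-group comparison."""
    times, events, labels, uniq = _two_groups(times, events, labels)
    if worse_label is None:
        worse_label = "nonresponder" if "nonresponder" in uniq else uniq[1]
    stat, p_two, p_one = logrank_test(times, events, labels, worse_label)
    hr, beta, se = cox_hr(times, events, (labels == worse_label).astype(float))
    curves = {str(g): km_curve(times[labels == g], events[labels == g]) for g in uniq}
    return SurvivalResult(
        hazard_ratio=hr, beta=beta, se=se,
        logrank_stat=stat, logrank_p=p_two, logrank_p_one_sided=p_one,
        n_per_group={str(g): int((labels == g).sum()) for g in uniq},
        km_curves=curves,
    )


def stouffer_combine(pvalues) -> float:
    """Unweighted Stouffer Z-transform combination of independent p-values.

    z_i = Phi^-1(1 - p_i); combined p = 1 - Phi(sum z_i / sqrt(k)).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p-values must lie strictly inside (0, 1)")
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def correlate_scores(score_a, score_b, strata=None):
    """Pearson correlation overall and within each stratum.

    Returns (overall r, {stratum: r}).  Strata with fewer than 3 samples are
    skipped; zero-variance input raises.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples to correlate")

    def pearson(x, y):
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero variance in correlation input")
        return float(stats.pearsonr(x, y).statistic)

    overall = pearson(a, b)
    per_stratum: dict[str, float] = {}
    if strata is not None:
        strata = np.asarray(strata)
        for s in pd.unique(strata):
            m = strata == s
            if m.sum() >= 3:
                per_stratum[str(s)] = pearson(a[m], b[m])
    return overall, per_stratum


def round_percent(count: int, total: int, digits: int = 1) -> float:
    """Half-up percentage rounding, matching conventional report formatting."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-digits)
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(predictions: pd.DataFrame, ann: pd.DataFrame,
                     strata=("MSI", "MSS")) -> dict:
    """Counts and one-decimal percentages per MSI stratum.

    Percentages are of the stratum size (so the responder, insufficient-
    infiltration and terminal-exhaustion percentages add to 100 up to
    rounding).  Empty strata are omitted.
    """
    merged = predictions.merge(ann[["sample_id", "msi_status"]], on="sample_id",
                               how="left")
    if merged["msi_status"].isna().any():
        missing = merged.loc[merged["msi_status"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples missing msi_status annotation: {missing}")
    summary: dict[str, dict] = {}
    for stratum in strata:
        sub = merged[merged["msi_status"] == stratum]
        n = len(sub)
        if n == 0:
            continue
        counts = {
            "n": n,
            "responders": int((sub["predicted"] == "responder").sum()),
            "nonresponders": int((sub["predicted"] == "nonresponder").sum()),
            "insufficient_infiltration": int(
                (sub["mechanism"] == "insufficient_infiltration").sum()),
            "terminal_exhaustion": int(
                (sub["mechanism"] == "terminal_exhaustion").sum()),
        }
        counts["pct_responders"] = round_percent(counts["responders"], n)
        counts["pct_nonresponders"] = round_percent(counts["nonresponders"], n)
        counts["pct_insufficient_infiltration"] = round_percent(
            counts["insufficient_infiltration"], n)
        counts["pct_terminal_exhaustion"] = round_percent(
            counts["terminal_exhaustion"], n)
        summary[stratum] = counts
    return summary
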