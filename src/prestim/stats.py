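"""Shared statistical primitives: paired t-tests, FDR, behavioral tabulation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is a single number for t-tests and a (df1, df2) pair for F-tests.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None


def p_from_t(t, df):
    """Two-tailed p-value from a Student-t statistic.

    p = 2 * S(|t|) where S is the survival function of the t distribution
    with ``df`` degrees of freedom.
    """
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr < 1):
        raise ValueError("df must be >= 1")
    return 2.0 * sps.t.sf(np.abs(t), df)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired two-tailed t-test on per-subject values.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    md = d.mean()
    if sd == 0:
        if md == 0:
            # identical inputs: no effect, maximally non-significant
            return TestResult(statistic=0.0, df=n - 1, p=1.0)
        raise ValueError("zero-variance differences: t statistic undefined")
    t = md / (sd / np.sqrt(n))
    return TestResult(statistic=float(t), df=n - 1, p=float(p_from_t(t, n - 1)))


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject mask, adjusted p-values). Rejects the i* smallest p-values
    where i* is the largest i with p_(i) <= i*q/m; adjusted p-values follow the
    cumulative-minimum convention.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)


# --------------------------------------------------------------- behavior

_CATEGORIES = ("correct_aware", "correct_unaware", "incorrect_aware", "incorrect_unaware")


@dataclass
class BehaviorTable:
    """Per subject x ISI category percentages plus ideal-ISI selection.

    The ideal ISI for a subject is the one with the most similar numbers of
    correct-aware and correct-unaware trials, subject to both counts reaching
    a configurable minimum.
    """

    counts: pd.DataFrame        # index (subject, ISI_ms), columns categories
    percentages: pd.DataFrame   # same layout, rows sum to 100
    accuracy: pd.Series         # per subject x ISI
    ideal_isi: pd.Series        # per subject
    rt_means: pd.DataFrame      # per subject, columns CA / CU mean RT (ms)

    def rt_contrast(self) -> TestResult:
        """Paired test of mean reaction time, CA vs CU, across subjects."""
        ok = self.rt_means.dropna()
        return paired_t(ok["CA"].to_numpy(), ok["CU"].to_numpy())


def tabulate_behavior(log: pd.DataFrame, min_trials: int = 20) -> BehaviorTable:
    """Tabulate a trial log into the four accuracy x awareness categories.

    ``log`` needs columns truth, response, aware, RT_ms, ISI_ms and optionally
    subject. Raises LookupError when no ISI balances the correct-aware and
    correct-unaware counts at the required minimum for some subject.
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    log = log.copy()
    if "subject" not in log.columns:
        log["subject"] = "S00"
    correct = log["truth"].to_numpy() == log["response"].to_numpy()
    aware = log["aware"].to_numpy().astype(bool)
    cat = np.where(
        correct,
        np.where(aware, "correct_aware", "correct_unaware"),
        np.where(aware, "incorrect_aware", "incorrect_unaware"),
    )
    log["category"] = cat
    counts = (
        log.groupby(["subject", "ISI_ms", "category"], sort=True)
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=list(_CATEGORIES), fill_value=0)
    )
    totals = counts.sum(axis=1)
    percentages = counts.div(totals, axis=0) * 100.0
    accuracy = (counts["correct_aware"] + counts["correct_unaware"]) / totals * 100.0

    ideal = {}
    for subj, sub in counts.groupby(level="subject"):
        ca = sub["correct_aware"]
        cu = sub["correct_unaware"]
        feasible = (ca >= min_trials) & (cu >= min_trials)
        if not feasible.any():
            raise LookupError(
                f"subject {subj}: no ISI with >= {min_trials} trials in both "
                "the correct-aware and correct-unaware conditions"
            )
        diff = (ca - cu).abs()[feasible]
        ideal[subj] = diff.idxmin()[1]
    ideal_isi = pd.Series(ideal, name="ideal_ISI_ms")

    rt_rows = {}
    for subj, sub in log.groupby("subject"):
        at_ideal = sub[sub["ISI_ms"] == ideal_isi[subj]]
        rt_rows[subj] = {
            "CA": at_ideal.loc[at_ideal["category"] == "correct_aware", "RT_ms"].mean(),
            "CU": at_ideal.loc[at_ideal["category"] == "correct_unaware", "RT_ms"].mean(),
        }
    rt_means = pd.DataFrame.from_dict(rt_rows, orient="index")

    return BehaviorTable(
        counts=counts,
        percentages=percentages,
        accuracy=accuracy,
        ideal_isi=ideal_isi,
        rt_means=rt_means,
    )
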