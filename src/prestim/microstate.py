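"""Single-trial pre-stimulus microstate analysis.

The analysis follows the microstate tradition for spontaneous EEG: one
topographic map per trial (at the GFP peak closest to stimulus onset), a
polarity-invariant modified spatial k-means over the pooled maps, model
selection by the predictive-residual-variance cross-validation criterion,
back-fitting of the selected templates to every trial, and global explained
variance (GEV) accounting per subject and condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet
from . import stats as _stats


def gfp(x: np.ndarray) -> np.ndarray:
    """Global field power: spatial standard deviation of the potential field.

    Population (divide-by-N) convention over the channel axis; ``x`` may be a
    single map (channels,) or an array (..., channels, samples) in which case
    the channel axis is -2.
    """
    x = np.asarray(x, dtype=float)
    axis = -1 if x.ndim == 1 else -2
    if x.shape[axis] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return x.std(axis=axis, ddof=0)


def spatial_correlation(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True) -> float:
    """Strength-independent spatial correlation of two maps.

    Pearson-type correlation of the mean-removed channel vectors; with
    ``polarity_invariant`` the absolute value is returned (microstate maps
    are sign-free for spontaneous EEG).
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal channel counts")
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-15 or nv < 1e-15:
        raise ValueError("zero-norm map: correlation undefined")
    c = float(u @ v / (nu * nv))
    return abs(c) if polarity_invariant else c


@dataclass
class TopographicMap:
    """One average-referenced voltage map at a single latency."""

    values: np.ndarray
    time_offset_ms: float       # negative = pre-stimulus
    trial_id: int = 0
    subject_id: str = "S00"
    condition: str = "CA"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v - v.mean()   # enforce the reference-free convention


def find_prestim_peak_map(
    epochs: EpochSet, trial: int, window_ms: float = 50.0
) -> TopographicMap:
    """Map at the GFP local maximum closest to stimulus onset.

    Searches the half-open window [onset - w, onset) for strict local maxima
    of the GFP time series (window-interior samples only); the latest one
    wins. If the window holds no strict local maximum, falls back to the
    sample of maximal GFP, boundary allowed.
    """
    w = int(round(window_ms * epochs.fs / 1000.0))
    if w < 1 or w > epochs.onset_index:
        raise ValueError("window does not fit in the pre-stimulus data")
    sl = slice(epochs.onset_index - w, epochs.onset_index)
    g = gfp(epochs.data[trial][:, sl])
    interior = np.arange(1, w - 1)
    peaks = interior[(g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])]
    idx = int(peaks[-1]) if len(peaks) else int(np.argmax(g))
    abs_idx = epochs.onset_index - w + idx
    return TopographicMap(
        values=epochs.data[trial][:, abs_idx],
        time_offset_ms=(abs_idx - epochs.onset_index) / epochs.fs * 1000.0,
        trial_id=trial,
        subject_id=epochs.subject_id,
        condition=str(epochs.conditions[trial]),
    )


def collect_peak_maps(epochs: EpochSet, window_ms: float = 50.0) -> list[TopographicMap]:
    """Pre-stimulus peak map of every trial."""
    return [find_prestim_peak_map(epochs, t, window_ms) for t in range(epochs.n_trials)]


# ------------------------------------------------------------- clustering

@dataclass
class MicrostateModel:
    """A k-template clustering of the pooled single-trial maps."""

    k: int
    templates: np.ndarray       # (k, channels), unit norm, zero mean
    sigma2: float               # mean predictive residual variance
    cv: float                   # cross-validation criterion
    gev_total: float            # explained fraction of GFP^2-weighted variance
    assignments: np.ndarray     # (n_maps,) template index


def _maps_matrix(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        X = np.atleast_2d(np.asarray(maps, float))
    else:
        X = np.stack([np.asarray(m.values, float) for m in maps])
    X = X - X.mean(axis=1, keepdims=True)
    return X


def _dominant_direction(Xk: np.ndarray, start: np.ndarray, iters: int = 60) -> np.ndarray:
    """Dominant eigenvector of Xk^T Xk by power iteration (warm-started)."""
    t = start.copy()
    prev = np.inf
    for _ in range(iters):
        t_new = Xk.T @ (Xk @ t)
        nrm = np.linalg.norm(t_new)
        if nrm < 1e-30:
            return start
        t_new /= nrm
        delta = 1.0 - abs(t_new @ t)
        t = t_new
        if delta < 1e-12 and prev < 1e-12:
            break
        prev = delta
    return t


def _fit_once(X: np.ndarray, init_templates: np.ndarray, max_iter: int, tol: float) -> tuple:
    """One run of polarity-invariant spatial k-means from given templates."""
    N = X.shape[0]
    total_ss = float(np.sum(X * X))
    T = init_templates.copy()
    k = T.shape[0]
    ess_old = -np.inf
    assign = np.zeros(N, dtype=int)
    for _ in range(max_iter):
        corr2 = (X @ T.T) ** 2                      # (N, k)
        assign = np.argmax(corr2, axis=1)
        for j in range(k):
            members = assign == j
            if not members.any():
                # re-seed an empty cluster with the worst-explained map
                worst = int(np.argmin(corr2[np.arange(N), assign]))
                T[j] = X[worst] / np.linalg.norm(X[worst])
                assign[worst] = j
                members = assign == j
            T[j] = _dominant_direction(X[members], T[j])
        ess = float(np.sum((X @ T.T)[np.arange(N), assign] ** 2))
        if ess - ess_old < tol * total_ss:
            ess_old = ess
            break
        ess_old = ess
    corr2 = (X @ T.T) ** 2
    assign = np.argmax(corr2, axis=1)
    ess = float(np.sum(corr2[np.arange(N), assign]))
    return ess, T, assign, total_ss


def cluster_microstates(
    maps,
    k_range: Iterable[int] = range(1, 21),
    restarts: int = 100,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: Optional[int] = None,
) -> list[MicrostateModel]:
    """Modified (polarity-invariant) spatial k-means for each candidate k.

    Assignment maximizes the squared spatial correlation with the templates;
    the template update is the dominant eigenvector of the sum of outer
    products of the maps assigned to it, so sign flips of any input map are
    irrelevant. The best of ``restarts`` random data-point initializations is
    kept per k; when scanning an ascending k range, the previous k's solution
    (plus the worst-explained map) seeds one extra restart, which makes the
    explained variance non-decreasing in k.
    """
    X = _maps_matrix(maps)
    N, C = X.shape
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("k must be >= 1")
    if ks[-1] > N:
        raise ValueError("more clusters than maps requested")
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms < 1e-15):
        raise ValueError("zero-norm map in input")
    Xn = X / norms[:, None]

    def _random_init(k: int) -> np.ndarray:
        T = rng.normal(size=(k, C))
        T -= T.mean(axis=1, keepdims=True)
        return T / np.linalg.norm(T, axis=1, keepdims=True)

    models = []
    prev_T: Optional[np.ndarray] = None
    for k in ks:
        best = None
        # data-sampled initializations; on tiny inputs the number of distinct
        # k-subsets can be below `restarts`, so surplus restarts use random
        # directions to escape initialization-limited local optima
        n_data_inits = min(max(restarts, 1), comb(N, k))
        inits = [Xn[rng.choice(N, size=k, replace=False)] for _ in range(n_data_inits)]
        inits += [_random_init(k) for _ in range(max(restarts, 1) - n_data_inits)]
        if prev_T is not None and prev_T.shape[0] == k - 1:
            corr2 = (X @ prev_T.T) ** 2
            worst = int(np.argmin(np.max(corr2, axis=1) / (norms**2)))
            inits.append(np.vstack([prev_T, Xn[worst]]))
        for T0 in inits:
            res = _fit_once(X, T0, max_iter, tol)
            if best is None or res[0] > best[0]:
                best = res
        ess, T, assign, total_ss = best
        sigma2 = (total_ss - ess) / (N * (C - 1))
        cv = sigma2 * ((C - 1) / (C - 1 - k)) ** 2 if C - 1 - k > 0 else np.inf
        models.append(
            MicrostateModel(
                k=k, templates=T, sigma2=sigma2, cv=float(cv),
                gev_total=ess / total_ss, assignments=assign,
            )
        )
        prev_T = T
    return models


def cv_criterion(model: MicrostateModel, n_channels: int) -> float:
    """Predictive residual variance criterion CV = sigma2 ((N-1)/(N-1-k))^2."""
    if n_channels - 1 - model.k <= 0:
        raise ValueError("need n_channels > k + 1")
    return model.sigma2 * ((n_channels - 1) / (n_channels - 1 - model.k)) ** 2


def select_k(models: Sequence[MicrostateModel]) -> MicrostateModel:
    """Model at the minimum of the cross-validation criterion."""
    return min(models, key=lambda m: m.cv)


# -------------------------------------------------------------- labeling

@dataclass
class Labeling:
    """Per-trial back-fit of the selected templates."""

    table: pd.DataFrame   # trial, subject, condition, label, C, gfp, time_offset_ms
    templates: np.ndarray


def label_trials(maps: Sequence[TopographicMap], templates: np.ndarray) -> Labeling:
    """Assign each map to the template with maximal |spatial correlation|.

    Ties break toward the lowest template index. Stores the correlation, the
    map's GFP, and the (unnormalized) GEV contribution GFP^2 * C^2.
    """
    templates = np.atleast_2d(templates)
    if templates.shape[0] == 0:
        raise ValueError("templates must be nonempty")
    X = _maps_matrix(maps)
    norms = np.linalg.norm(X, axis=1)
    corr = np.zeros((X.shape[0], templates.shape[0]))
    nonzero = norms > 1e-15
    corr[nonzero] = (X[nonzero] / norms[nonzero, None]) @ (
        templates / np.linalg.norm(templates, axis=1, keepdims=True)
    ).T
    corr2 = corr**2
    labels = np.argmax(corr2, axis=1)
    C_abs = np.sqrt(corr2[np.arange(X.shape[0]), labels])
    g = norms / np.sqrt(X.shape[1])     # GFP of a zero-mean map
    rows = pd.DataFrame(
        {
            "trial": [m.trial_id for m in maps],
            "subject": [m.subject_id for m in maps],
            "condition": [m.condition for m in maps],
            "label": labels,
            "C": C_abs,
            "gfp": g,
            "time_offset_ms": [m.time_offset_ms for m in maps],
            "gev_num": g**2 * C_abs**2,
        }
    )
    return Labeling(table=rows, templates=templates)


def gev_by_map_condition(labeling: Labeling) -> pd.DataFrame:
    """GEV per subject x condition x template.

    GEV(k, cond) = sum over trials labeled k of GFP^2 C^2, normalized by the
    summed GFP^2 of all trials in that subject x condition cell, so values
    are comparable across subjects with different trial counts.
    """
    tab = labeling.table
    if len(tab) == 0:
        raise ValueError("empty labeling")
    k = labeling.templates.shape[0]
    denom = tab.assign(g2=tab["gfp"] ** 2).groupby(["subject", "condition"])["g2"].sum()
    if (denom <= 0).any():
        raise ValueError("condition with no topographic variance")
    num = (
        tab.groupby(["subject", "condition", "label"])["gev_num"]
        .sum()
        .unstack("label", fill_value=0.0)
        .reindex(columns=range(k), fill_value=0.0)
    )
    gev = num.div(denom, axis=0)
    gev.columns.name = "template"
    return gev


def compare_gev(gev_table: pd.DataFrame, template_index: int) -> _stats.TestResult:
    """Paired t-test across subjects of one template's GEV, CA vs CU."""
    col = gev_table[template_index].unstack("condition")
    col = col.dropna()
    if len(col) < 2 or "CA" not in col or "CU" not in col:
        raise ValueError("need >= 2 subjects with both conditions")
    return _stats.paired_t(col["CA"].to_numpy(), col["CU"].to_numpy())
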