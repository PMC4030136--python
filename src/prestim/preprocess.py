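"""Reference transforms, zero-phase filtering, spline interpolation, windowing.

All transforms are linear and act per sample (references) or per channel
(filtering), so they commute; the pipeline filters the full epochs first and
cuts the short pre-stimulus windows afterwards, which keeps filter edge
effects away from the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as spsig
from scipy.special import eval_legendre

from .containers import ElectrodeMontage, EpochSet, condition_counts


@dataclass(frozen=True)
class ReferenceScheme:
    """One of the reference transforms: average, mastoids, or a single electrode."""

    kind: str = "average"
    electrode_name: str | None = None
    mastoid_names: tuple[str, str] = ("M1", "M2")

    def __post_init__(self) -> None:
        if self.kind not in ("average", "mastoids", "electrode"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.kind == "electrode" and not self.electrode_name:
            raise ValueError("electrode reference needs electrode_name")

    @property
    def label(self) -> str:
        return self.electrode_name if self.kind == "electrode" else self.kind


def rereference(epochs: EpochSet, scheme: ReferenceScheme) -> EpochSet:
    """Re-express all channels relative to the requested reference, per sample."""
    data = epochs.data
    if scheme.kind == "average":
        ref = data.mean(axis=1, keepdims=True)
    elif scheme.kind == "electrode":
        idx = epochs.montage.index(scheme.electrode_name)
        ref = data[:, idx : idx + 1, :]
    else:
        i1 = epochs.montage.index(scheme.mastoid_names[0])
        i2 = epochs.montage.index(scheme.mastoid_names[1])
        ref = 0.5 * (data[:, i1 : i1 + 1, :] + data[:, i2 : i2 + 1, :])
    return epochs.with_data(data - ref)


@dataclass(frozen=True)
class FilterSpec:
    """Two-pass (zero-phase) Butterworth band-pass specification."""

    low_hz: float = 1.0
    high_hz: float = 30.0
    order: int = 2

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError("need 0 < low < high < Nyquist")


def bandpass_filter(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Zero-phase Butterworth band-pass, applied forward + backward per channel.

    Edges are handled by reflect-padding three filter lengths per pass.
    """
    spec.validate(epochs.fs)
    b, a = spsig.butter(spec.order, [spec.low_hz, spec.high_hz], btype="band", fs=epochs.fs)
    padlen = 3 * max(len(a), len(b))
    if epochs.n_samples <= padlen:
        raise ValueError("epoch too short for filter edge padding")
    out = spsig.filtfilt(b, a, epochs.data, axis=-1, padtype="even", padlen=padlen)
    return epochs.with_data(out)


def _spline_g(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin spherical-spline kernel g(x) = 1/4pi sum (2n+1)/(n(n+1))^m P_n(x)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def interpolate_channels(
    epochs: EpochSet,
    bad: Sequence[str],
    m: int = 4,
    n_terms: int = 50,
    lambda_reg: float = 1e-5,
) -> EpochSet:
    """Replace bad channels by spherical-spline estimates from the good ones.

    Uses the Perrin thin-plate spline on the sphere (order ``m``, ``n_terms``
    Legendre terms) with a small ridge term on the spline system for
    numerical stability. Good channels are untouched.
    """
    if not bad:
        return epochs.with_data(epochs.data.copy())
    bad_idx = np.array([epochs.montage.index(name) for name in bad])
    n_ch = epochs.n_channels
    if len(bad_idx) >= n_ch - 3:
        raise ValueError("too many bad channels to interpolate")
    good_idx = np.setdiff1d(np.arange(n_ch), bad_idx)
    pos = epochs.montage.positions
    G_gg = _spline_g(pos[good_idx] @ pos[good_idx].T, m, n_terms)
    G_bg = _spline_g(pos[bad_idx] @ pos[good_idx].T, m, n_terms)

    ng = len(good_idx)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G_gg + lambda_reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0

    data = epochs.data.copy()
    v = data[:, good_idx, :]                              # (T, ng, S)
    rhs = np.concatenate([v, np.zeros((v.shape[0], 1, v.shape[2]))], axis=1)
    sol = np.linalg.solve(A, rhs.transpose(1, 0, 2).reshape(ng + 1, -1))
    c, c0 = sol[:ng], sol[ng]
    est = G_bg @ c + c0                                   # (nbad, T*S)
    data[:, bad_idx, :] = est.reshape(len(bad_idx), v.shape[0], v.shape[2]).transpose(1, 0, 2)
    return epochs.with_data(data)


def extract_prestim(epochs: EpochSet, window_ms: float) -> EpochSet:
    """Restrict the data to the half-open pre-stimulus window [onset - w, onset)."""
    w = int(round(window_ms * epochs.fs / 1000.0))
    if w < 1 or w > epochs.onset_index:
        raise ValueError(
            f"window of {window_ms} ms does not fit before onset "
            f"({epochs.onset_index} pre-stimulus samples available)"
        )
    data = epochs.data[:, :, epochs.onset_index - w : epochs.onset_index]
    return epochs.with_data(data, onset_index=w)


def reject_artifacts(
    epochs: EpochSet, abs_threshold_uv: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose absolute voltage exceeds the threshold on any channel.

    Returns the cleaned EpochSet and the rejected trial indices; retained
    counts per condition are stored in ``epochs attrs`` terms via
    ``condition_counts`` on the result.
    """
    if not abs_threshold_uv > 0:
        raise ValueError("threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    rejected = np.flatnonzero(peak > abs_threshold_uv)
    if len(rejected) == epochs.n_trials:
        raise ValueError("all trials exceeded the artifact threshold")
    kept = epochs.trial_mask(peak <= abs_threshold_uv)
    return kept, rejected
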