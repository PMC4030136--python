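"""Synthetic EEG generator with planted microstate, alpha-phase and source structure.

Each simulated trial is the sum of four components, all in microvolts:

* a piecewise-constant sequence of quasi-stable topographic states (80-120 ms
  durations) scaled by a rectified-sinusoid strength envelope, so the global
  field power shows clear local maxima for peak-picking;
* a 10 Hz oscillation projected through a spatially localized profile, whose
  phase at stimulus onset is drawn per trial from a von Mises distribution
  with a condition-dependent mean direction;
* the forward field of a fixed "differential" occipital dipole, scaled
  per condition (the recoverable source-level effect);
* independent Gaussian sensor noise.

The returned GroundTruth records everything needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import ElectrodeMontage, EpochSet
from .inverse import HeadModel, LeadField, dipole_topography

# canonical directions used to name special channels in the synthetic montage
_SPECIAL_DIRECTIONS = {
    "Cz": (0.0, 0.0, 1.0),
    "FPz": (0.0, 0.951, 0.309),
    "Oz": (0.0, -0.951, 0.309),
    "M1": (-0.940, -0.210, -0.270),
    "M2": (0.940, -0.210, -0.270),
}


def make_montage(n_channels: int = 204, seed: int = 0) -> ElectrodeMontage:
    """Quasi-uniform electrode montage on the upper ~2/3 of the unit sphere.

    Points follow a Fibonacci spiral over the spherical cap z >= -1/3 (scalp
    coverage, no face/nape channels), rotated in azimuth by a seed-dependent
    angle. Channels nearest to the canonical Cz/FPz/Oz and mastoid directions
    are renamed accordingly so reference schemes can address them by label.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # uniform areal coverage of the cap z in [-1/3, 1]
    z = 1.0 - (i + 0.5) * (4.0 / 3.0) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = phi0 + i * golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)

    names = [f"E{k + 1:03d}" for k in range(n_channels)]
    taken: set[int] = set()
    for label, direction in _SPECIAL_DIRECTIONS.items():
        d = np.asarray(direction) / np.linalg.norm(direction)
        order = np.argsort(-(pos @ d))
        for idx in order:
            if idx not in taken:
                names[idx] = label
                taken.add(int(idx))
                break
    return ElectrodeMontage(names=tuple(names), positions=pos)


def make_templates(
    montage: ElectrodeMontage,
    k: int,
    leadfield: LeadField,
    seed: int = 0,
    max_corr: float = 0.7,
    max_retries: int = 500,
    occipital_first: int = 0,
) -> np.ndarray:
    """k planted template maps as forward fields of randomly placed dipoles.

    Each template is the scalp field of a random dipole (random solution
    point, random orientation), made zero-mean across channels and unit L2
    norm. Candidates too similar to an accepted template (pairwise |spatial
    correlation| > ``max_corr``) are resampled. The first ``occipital_first``
    templates draw their dipoles from the occipital solution points, so a
    condition-prevalence bias on them plants an occipital source difference.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if leadfield.gain.shape[0] != montage.n_channels:
        raise ValueError("leadfield channels do not match montage")
    rng = np.random.default_rng(seed)
    P = leadfield.sources.n_points
    # plant occipital templates in the deeper posterior core so their inverse
    # images stay inside the flagged occipital region despite point spread
    occ_idx = np.flatnonzero(leadfield.sources.points[:, 1] <= -0.6)
    if occipital_first > 0 and len(occ_idx) == 0:
        raise ValueError("source space has no occipital points")
    templates: list[np.ndarray] = []
    attempts = 0
    while len(templates) < k:
        if attempts > max_retries:
            raise RuntimeError(
                f"could not draw {k} templates with pairwise |C| <= {max_corr}"
            )
        attempts += 1
        if len(templates) < occipital_first:
            p_idx = occ_idx[rng.integers(len(occ_idx))]
        else:
            p_idx = rng.integers(P)
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        v = leadfield.gain[:, 3 * p_idx : 3 * p_idx + 3] @ moment
        v = v - v.mean()
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            continue
        v = v / nrm
        if any(abs(v @ t) > max_corr for t in templates):
            continue
        templates.append(v)
    return np.stack(templates)


@dataclass(frozen=True)
class AlphaParams:
    """Pre-stimulus alpha component: on-bin 10 Hz with condition-dependent phase."""

    freq: float = 10.0
    amplitude: float = 1.0                 # GFP of the alpha topography, microvolts
    phase_concentration: float = 2.0       # von Mises kappa of the onset phase
    condition_phase_offset: float = np.pi  # mean-direction offset CU - CA, radians
    mean_phase_ca: float = 0.0
    spatial_profile: Optional[np.ndarray] = None  # per-channel weights; None = occipital


@dataclass(frozen=True)
class DiffSourceParams:
    """Condition-dependent occipital dipole (the planted source effect)."""

    location: tuple[float, float, float] = (0.0, -0.75, 0.0)
    amplitude_ca: float = 0.4              # GFP of its scalp field, microvolts
    amplitude_cu: float = 1.2


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the synthetic experiment.

    Defaults emulate the recording setup the analyses assume: 1000 Hz
    sampling, 250 ms of pre-stimulus data, quasi-stable states of 80-120 ms,
    state field strength a few microvolts GFP with sensor noise at 0.3 of the
    state amplitude, and a weaker alpha component with an opposite-phase
    condition effect.
    """

    n_trials_per_condition: int = 150
    fs: float = 1000.0
    epoch_ms: float = 300.0
    onset_ms: float = 250.0
    duration_range: tuple[float, float] = (80.0, 120.0)
    state_amplitude: float = 3.0           # peak GFP of the state component, microvolts
    envelope_freq: float = 10.0            # rectified -> ~20 Hz GFP periodicity
    envelope_floor: float = 0.1            # fraction of peak strength the field never drops below
    alpha: AlphaParams = AlphaParams()
    diff_source: DiffSourceParams = DiffSourceParams()
    noise_sd: float = 0.9                  # per channel/sample, microvolts
    n_artifact_trials: int = 0
    artifact_amplitude_uv: float = 150.0
    # relative per-template occurrence weights per condition (None = uniform);
    # a template overrepresented in one condition dissociates the conditions
    # by GEV, the planted counterpart of the condition-specific maps
    state_weights_ca: Optional[tuple[float, ...]] = None
    state_weights_cu: Optional[tuple[float, ...]] = None


@dataclass
class GroundTruth:
    """Everything planted by the generator, for scoring downstream stages."""

    state_sequence: np.ndarray          # (n_trials, n_samples) template index
    planted_templates: np.ndarray       # (k, n_channels), unit norm, zero mean
    alpha_phase_at_onset: np.ndarray    # (n_trials,) radians
    source_amplitudes: dict             # condition -> scalp-field GFP
    diff_source_field: np.ndarray       # (n_channels,) unit-GFP field
    conditions: np.ndarray              # (n_trials,)
    artifact_trials: np.ndarray         # planted high-amplitude trials
    seed: int


def _occipital_profile(montage: ElectrodeMontage) -> np.ndarray:
    """Default localized alpha topography: Gaussian bump around Oz, unit GFP."""
    center = np.asarray(_SPECIAL_DIRECTIONS["Oz"])
    center = center / np.linalg.norm(center)
    d2 = np.sum((montage.positions - center) ** 2, axis=1)
    w = np.exp(-d2 / (2 * 0.5**2))
    w = w - w.mean()
    return w / w.std()


def _unit_gfp(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    s = v.std()
    if s < 1e-15:
        raise ValueError("degenerate (constant) topography")
    return v / s


def _state_sequence(
    rng: np.random.Generator, k: int, n_samples: int, fs: float,
    duration_range: tuple[float, float],
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Piecewise-constant template indices; the first run starts mid-state.

    ``weights`` are relative occurrence probabilities per template
    (self-transitions excluded). Also returns the (possibly epoch-clipped)
    runs as (start, duration, state) with starts that may be negative, so the
    strength envelope can be aligned with the full extent of each state.
    """
    lo = int(round(duration_range[0] * fs / 1000.0))
    hi = int(round(duration_range[1] * fs / 1000.0))
    if weights is None:
        weights = np.ones(k)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (k,) or np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("state weights must be k nonnegative values")
    seq = np.empty(n_samples, dtype=np.int16)
    runs: list[tuple[int, int, int]] = []
    state = int(rng.choice(k, p=weights / weights.sum()))
    # burn-in: the epoch opens partway through an ongoing state
    pos = -int(rng.integers(0, hi))
    while pos < n_samples:
        dur = int(rng.integers(lo, hi + 1))
        seq[max(pos, 0) : min(pos + dur, n_samples)] = state
        runs.append((pos, dur, state))
        pos += dur
        if k > 1:
            w = weights.copy()
            w[state] = 0.0
            state = int(rng.choice(k, p=w / w.sum()))
    return seq, runs


def _state_envelope(
    runs: list[tuple[int, int, int]], n_samples: int, fs: float,
    envelope_freq: float, floor: float,
) -> np.ndarray:
    """Rectified-sinusoid strength envelope phase-locked to the state runs.

    Each state run carries an integer number of half-period arches, so the
    field strength peaks mid-state and dips to ``floor`` exactly at the
    transitions — the microstate phenomenology the peak-picking step assumes
    (GFP troughs mark state boundaries).
    """
    env = np.empty(n_samples)
    for start, dur, _ in runs:
        n_arches = max(1, int(round(2.0 * envelope_freq * dur / fs)))
        a = max(start, 0)
        b = min(start + dur, n_samples)
        if b <= a:
            continue
        t = np.arange(a, b) - start
        env[a:b] = np.abs(np.sin(np.pi * n_arches * t / dur))
    return floor + (1.0 - floor) * env


def simulate_epochs(
    templates: np.ndarray,
    montage: ElectrodeMontage,
    params: SimParams = SimParams(),
    seed: int = 0,
    head: HeadModel = HeadModel(),
) -> tuple[EpochSet, GroundTruth]:
    """Simulate a subject's epoched EEG with known ground truth."""
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    if templates.shape[1] != montage.n_channels:
        raise ValueError("template/montage channel mismatch")
    if params.onset_ms < 200.0:
        raise ValueError("need at least 200 ms of pre-stimulus data")
    if params.n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    k = templates.shape[0]
    rng = np.random.default_rng(seed)
    fs = params.fs
    n_samples = int(round(params.epoch_ms * fs / 1000.0))
    onset = int(round(params.onset_ms * fs / 1000.0))
    n_trials = 2 * params.n_trials_per_condition
    C = montage.n_channels
    conditions = np.array(
        ["CA"] * params.n_trials_per_condition + ["CU"] * params.n_trials_per_condition,
        dtype="U2",
    )
    perm = rng.permutation(n_trials)
    conditions = conditions[perm]

    # unit-GFP state topographies so state_amplitude is the component's GFP
    state_maps = np.stack([_unit_gfp(t) for t in templates])
    if params.alpha.spatial_profile is not None:
        alpha_profile = _unit_gfp(np.asarray(params.alpha.spatial_profile, float))
    else:
        alpha_profile = _occipital_profile(montage)
    diff_field = _unit_gfp(
        dipole_topography(
            montage,
            params.diff_source.location,
            np.asarray(params.diff_source.location) / np.linalg.norm(params.diff_source.location),
            head=head,
        )
    )
    amp_by_cond = {"CA": params.diff_source.amplitude_ca, "CU": params.diff_source.amplitude_cu}

    t_rel = (np.arange(n_samples) - onset) / fs   # seconds relative to onset
    data = np.empty((n_trials, C, n_samples))
    state_seq = np.empty((n_trials, n_samples), dtype=np.int16)
    phases = np.empty(n_trials)
    kappa = params.alpha.phase_concentration
    weights_by_cond = {
        "CA": params.state_weights_ca,
        "CU": params.state_weights_cu,
    }
    for tr in range(n_trials):
        seq, runs = _state_sequence(
            rng, k, n_samples, fs, params.duration_range,
            weights=weights_by_cond[str(conditions[tr])],
        )
        state_seq[tr] = seq
        envelope = _state_envelope(
            runs, n_samples, fs, params.envelope_freq, params.envelope_floor
        )
        signal = state_maps[seq].T * (params.state_amplitude * envelope)   # (C, S)

        mu = params.alpha.mean_phase_ca
        if conditions[tr] == "CU":
            mu = mu + params.alpha.condition_phase_offset
        if np.isinf(kappa):
            theta = mu
        else:
            theta = rng.vonmises(mu, kappa)
        phases[tr] = np.angle(np.exp(1j * theta))
        if params.alpha.amplitude > 0:
            osc = np.cos(2 * np.pi * params.alpha.freq * t_rel + phases[tr])
            signal = signal + np.outer(alpha_profile, params.alpha.amplitude * osc)

        amp = amp_by_cond[conditions[tr]]
        if amp != 0:
            signal = signal + amp * diff_field[:, None]
        if params.noise_sd > 0:
            signal = signal + rng.normal(0.0, params.noise_sd, size=(C, n_samples))
        data[tr] = signal

    artifact_trials = np.sort(rng.choice(n_trials, size=params.n_artifact_trials, replace=False))
    for tr in artifact_trials:
        ch = int(rng.integers(C))
        start = int(rng.integers(0, max(n_samples - 20, 1)))
        data[tr, ch, start : start + 20] += params.artifact_amplitude_uv

    epochs = EpochSet(
        data=data, fs=fs, onset_index=onset, conditions=conditions,
        montage=montage, subject_id=f"sim-{seed}",
    )
    truth = GroundTruth(
        state_sequence=state_seq,
        planted_templates=templates.copy(),
        alpha_phase_at_onset=phases,
        source_amplitudes=amp_by_cond,
        diff_source_field=diff_field,
        conditions=conditions.copy(),
        artifact_trials=artifact_trials,
        seed=seed,
    )
    return epochs, truth


def simulate_cohort(
    templates: np.ndarray,
    montage: ElectrodeMontage,
    params: SimParams = SimParams(),
    n_subjects: int = 11,
    seed: int = 0,
    head: HeadModel = HeadModel(),
) -> list[tuple[EpochSet, GroundTruth]]:
    """Simulate ``n_subjects`` independent subjects sharing the same templates."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for s, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        ep, gt = simulate_epochs(templates, montage, params, seed=sub_seed, head=head)
        ep.subject_id = f"S{s:02d}"
        out.append((ep, gt))
    return out
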