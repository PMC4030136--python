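"""Core data containers: electrode montages and epoched EEG.

The epoch container is deliberately simple: a ``trials x channels x samples``
voltage array (microvolts) plus the metadata every downstream stage needs
(sampling rate, stimulus-onset sample, per-trial condition labels, montage).
On disk it is a directory with a raw little-endian float32 binary, a JSON
sidecar describing the shape and metadata, and an events TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("CA", "CU")


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels and unit-sphere positions (head radius normalized to 1).

    Coordinates follow the RAS convention: +x right, +y anterior, +z superior.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if pos.shape[0] < 4:
            raise ValueError("a montage needs at least 4 electrodes")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must be unit vectors")
        if len(self.names) != pos.shape[0]:
            raise ValueError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@dataclass
class EpochSet:
    """Epoched multichannel EEG with condition labels.

    ``onset_index`` is 0-based; the sample at ``onset_index`` is the first
    post-stimulus sample, so the pre-stimulus window of length ``w`` is the
    half-open slice ``[onset_index - w, onset_index)``.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    fs: float
    onset_index: int
    conditions: np.ndarray  # (n_trials,) of {"CA", "CU"}
    montage: ElectrodeMontage
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        self.conditions = np.asarray(self.conditions, dtype="U2")
        if self.conditions.shape != (self.data.shape[0],):
            raise ValueError("one condition label per trial required")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not (0 <= self.onset_index <= self.data.shape[2]):
            raise ValueError("onset_index outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **kwargs) -> "EpochSet":
        """Copy of this EpochSet with replaced data (and optional metadata)."""
        return EpochSet(
            data=data,
            fs=kwargs.get("fs", self.fs),
            onset_index=kwargs.get("onset_index", self.onset_index),
            conditions=kwargs.get("conditions", self.conditions.copy()),
            montage=kwargs.get("montage", self.montage),
            subject_id=kwargs.get("subject_id", self.subject_id),
        )

    def trial_mask(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return self.with_data(self.data[mask], conditions=self.conditions[mask])

    # ------------------------------------------------------------------ I/O

    def save(self, out_dir: str | Path) -> Path:
        """Write the container: data.bin (float32 LE) + meta.json + events.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(out / "data.bin")
        meta = {
            "shape": list(self.data.shape),
            "dtype": "<f4",
            "fs": self.fs,
            "onset_index": int(self.onset_index),
            "subject_id": self.subject_id,
            "channel_names": list(self.montage.names),
            "channel_positions": self.montage.positions.tolist(),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1))
        events = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "condition": self.conditions,
                "onset_sample": np.full(self.n_trials, self.onset_index),
            }
        )
        events.to_csv(out / "events.tsv", sep="\t", index=False)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "EpochSet":
        src = Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        shape = tuple(meta["shape"])
        data = np.fromfile(src / "data.bin", dtype=meta["dtype"]).reshape(shape)
        events = pd.read_csv(src / "events.tsv", sep="\t")
        montage = ElectrodeMontage(
            names=tuple(meta["channel_names"]),
            positions=np.asarray(meta["channel_positions"], dtype=float),
        )
        return cls(
            data=data.astype(float),
            fs=float(meta["fs"]),
            onset_index=int(meta["onset_index"]),
            conditions=events["condition"].to_numpy(dtype="U2"),
            montage=montage,
            subject_id=meta.get("subject_id", "S00"),
        )


def condition_counts(conditions: Sequence[str]) -> dict[str, int]:
    arr = np.asarray(conditions, dtype="U2")
    return {c: int(np.sum(arr == c)) for c in CONDITIONS}
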