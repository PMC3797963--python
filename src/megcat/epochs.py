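"""Epoch container shared by the simulator and every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np


@dataclass
class EpochSet:
    """Trials x channels x time tensor with per-trial metadata.

    ``labels`` holds the stimulus category ('A'/'B') of each trial and
    ``trial_index`` the position of the trial in the presentation order —
    the quantity that drives learning effects.  ``time_ms`` is the sample
    grid relative to stimulus onset.  ``kind`` distinguishes whole-head
    sensor ensembles from region-bounded dipole ensembles.
    """

    data: np.ndarray
    labels: np.ndarray
    trial_index: np.ndarray
    time_ms: np.ndarray
    channel_names: list[str]
    kind: str = "sensor"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_names = [str(c) for c in self.channel_names]
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        n, c, t = self.data.shape
        if self.labels.shape != (n,) or self.trial_index.shape != (n,):
            raise ValueError("labels/trial_index must have one entry per trial")
        if self.time_ms.shape != (t,):
            raise ValueError("time_ms length must match the data time axis")
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must match the channel axis")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if self.kind not in ("sensor", "region"):
            raise ValueError("kind must be 'sensor' or 'region'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select_trials(self, rows: np.ndarray) -> "EpochSet":
        """Subset of trials (rows into the trial axis), metadata carried along."""
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            data=self.data[rows],
            labels=self.labels[rows],
            trial_index=self.trial_index[rows],
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            # track_times=False keeps files byte-identical across reruns
            f.create_dataset("data", data=self.data, track_times=False)
            f.create_dataset("labels", data=np.char.encode(self.labels.astype(str)),
                             track_times=False)
            f.create_dataset("trial_index", data=self.trial_index, track_times=False)
            f.create_dataset("time_ms", data=self.time_ms, track_times=False)
            f.create_dataset(
                "channel_names", data=np.char.encode(np.array(self.channel_names)),
                track_times=False,
            )
            f.attrs["kind"] = self.kind

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                labels=np.char.decode(f["labels"][()]),
                trial_index=f["trial_index"][()],
                time_ms=f["time_ms"][()],
                channel_names=list(np.char.decode(f["channel_names"][()])),
                kind=str(f.attrs["kind"]),
            )
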