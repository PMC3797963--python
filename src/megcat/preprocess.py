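"""Epoch conditioning: baseline removal, moving-window binning, phase split.

Conventions used throughout: time bins are half-open intervals [a, b) in
ms, trial indices are 0-based, and the pre-stimulus baseline is the mean
over [-120, 0) ms per trial and channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import EpochSet

BASELINE_MS = (-120.0, 0.0)
ANALYSIS_MS = (0.0, 400.0)
DEFAULT_WINDOW_MS = 20.0
DEFAULT_STEP_MS = 10.0
DEFAULT_PHASE_SIZE = 100


@dataclass
class BinnedEpochs:
    """Trials x channels x time-bin tensor after moving-window averaging."""

    data: np.ndarray
    bin_centers_ms: np.ndarray
    labels: np.ndarray
    trial_index: np.ndarray
    channel_names: list[str]
    window_ms: float = DEFAULT_WINDOW_MS
    step_ms: float = DEFAULT_STEP_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bin_centers_ms = np.asarray(self.bin_centers_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, bins)")
        if self.bin_centers_ms.shape != (self.data.shape[2],):
            raise ValueError("bin_centers_ms must match the bin axis")
        if np.any(np.diff(self.bin_centers_ms) <= 0):
            raise ValueError("bins must be ordered")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def select_trials(self, rows: np.ndarray) -> "BinnedEpochs":
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            data=self.data[rows],
            labels=self.labels[rows],
            trial_index=self.trial_index[rows],
        )


def remove_baseline(epochs: EpochSet) -> EpochSet:
    """Subtract the per-trial, per-channel mean over [-120, 0) ms.

    Returns the post-onset samples on [0, 400) ms only.
    """
    t = epochs.time_ms
    base = (t >= BASELINE_MS[0]) & (t < BASELINE_MS[1])
    if not np.any(base):
        raise ValueError("epochs lack pre-stimulus samples in [-120, 0) ms")
    post = (t >= ANALYSIS_MS[0]) & (t < ANALYSIS_MS[1])
    baseline = epochs.data[:, :, base].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data[:, :, post] - baseline, time_ms=t[post])


def sliding_average(
    epochs: EpochSet,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> BinnedEpochs:
    """Moving-window mean along time: bins [k*step, k*step + window) ms.

    With the 20/10 ms defaults over a [0, 400) ms epoch this yields 39
    bins with centres 10, 20, ..., 390 ms (centre = left edge + window/2).
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be > 0")
    t = epochs.time_ms
    start, stop = ANALYSIS_MS
    if t[0] > start or t[-1] < start:
        raise ValueError("epochs must cover the [0, 400) ms analysis window")
    edges = []
    left = start
    while left + window_ms <= stop:
        edges.append(left)
        left += step_ms
    bins = np.empty((epochs.n_trials, epochs.n_channels, len(edges)))
    centers = np.empty(len(edges))
    for k, a in enumerate(edges):
        mask = (t >= a) & (t < a + window_ms)
        if not np.any(mask):
            raise ValueError(f"no samples fall in bin [{a}, {a + window_ms}) ms")
        bins[:, :, k] = epochs.data[:, :, mask].mean(axis=2)
        centers[k] = a + window_ms / 2.0
    return BinnedEpochs(
        data=bins,
        bin_centers_ms=centers,
        labels=epochs.labels,
        trial_index=epochs.trial_index,
        channel_names=epochs.channel_names,
        window_ms=window_ms,
        step_ms=step_ms,
    )


def select_phase(
    epochs: EpochSet, phase: str, n: int = DEFAULT_PHASE_SIZE
) -> EpochSet:
    """The ``n`` earliest ('early') or latest ('late') trials by trial_index.

    Original row order is preserved.
    """
    if phase not in ("early", "late"):
        raise ValueError("phase must be 'early' or 'late'")
    if n > epochs.n_trials:
        raise ValueError(f"requested {n} trials but only {epochs.n_trials} available")
    order = np.argsort(epochs.trial_index, kind="stable")
    chosen = order[:n] if phase == "early" else order[-n:]
    return epochs.select_trials(np.sort(chosen))
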