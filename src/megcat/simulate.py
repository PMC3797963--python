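"""Synthetic MEG epoch generator.

Produces sensor-space (102-channel) and region-bounded dipole-ensemble
epochs with the statistical structure the downstream analyses assume:
temporally band-limited Gaussian noise, a slow per-trial baseline offset,
and category-signed evoked effects confined to configurable post-onset
latency windows.  Each effect's amplitude is modulated by a logistic
learning curve over the trial index, emulating the acquisition of
category information over a feedback-driven session.

The temporal profile of an effect is a raised-cosine bump spanning its
window, so effect energy is exactly confined to the window.  Category A
receives the effect with positive sign, category B with negative sign;
the between-category mean difference at the bump peak is therefore twice
the effect amplitude along its spatial pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .epochs import EpochSet
from .stimuli import StimulusSet

EPOCH_START_MS = -120.0
EPOCH_STOP_MS = 400.0
DEFAULT_DT_MS = 5.0
N_SENSORS = 102

#: default scenario targets (left-hemisphere ventral visual / prefrontal)
DEFAULT_VVP_TARGET = "fusiform-lh"
DEFAULT_PFC_TARGET = "parsorbitalis-lh"

_VVP_REGIONS = (
    "pericalcarine",
    "lingual",
    "lateraloccipital",
    "cuneus",
    "fusiform",
    "inferiortemporal",
)
_PFC_REGIONS = (
    "parsorbitalis",
    "parstriangularis",
    "parsopercularis",
    "rostralmiddlefrontal",
    "lateralorbitofrontal",
    "superiorfrontal",
)


@dataclass(frozen=True)
class LearningParams:
    """Logistic ramp of effect strength over the trial index.

    Value at trial t: floor + (ceiling - floor) / (1 + exp(-rate (t - midpoint))).
    ``ceiling < floor`` encodes an effect that decays with learning.
    """

    floor: float = 1.0
    ceiling: float = 1.0
    midpoint_trial: int = 300
    rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("floor", "ceiling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Band-limited noise model: white Gaussian noise smoothed by a moving
    average of length ``smooth_ms`` (variance-preserving), plus a constant
    per-trial, per-channel baseline offset with sd ``baseline_offset_sd``."""

    sd: float = 1.0
    smooth_ms: float = 20.0
    baseline_offset_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.sd < 0 or self.smooth_ms < 0 or self.baseline_offset_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class EffectSpec:
    """A category-dependent evoked effect confined to one latency window.

    ``target`` is ``"sensor"`` or a region name; ``spatial_pattern`` (unit
    norm over the target's channels) is drawn at simulation time when left
    unset.  ``amplitude`` is in noise-sd units at the bump peak.
    """

    target: str
    window_ms: tuple[float, float]
    amplitude: float
    learning: LearningParams = field(default_factory=LearningParams)
    spatial_pattern: np.ndarray | None = None

    def __post_init__(self) -> None:
        start, stop = self.window_ms
        if not (0.0 <= start < stop <= EPOCH_STOP_MS):
            raise ValueError(
                f"effect window {self.window_ms} must lie within [0, {EPOCH_STOP_MS})"
            )
        if self.spatial_pattern is not None:
            p = np.asarray(self.spatial_pattern, dtype=float)
            if not np.isclose(np.linalg.norm(p), 1.0):
                raise ValueError("spatial_pattern must have unit norm")
            self.spatial_pattern = p


@dataclass(frozen=True)
class Region:
    name: str
    pathway: str
    hemisphere: str
    dipole_count: int

    def __post_init__(self) -> None:
        if self.pathway not in ("VVP", "PFC"):
            raise ValueError("pathway must be 'VVP' or 'PFC'")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.dipole_count < 2:
            raise ValueError("dipole_count must be >= 2")


@dataclass
class RegionLayout:
    """Named cortical regions with pathway assignment and dipole counts."""

    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def pathway_of(self, name: str) -> str:
        for r in self.regions:
            if r.name == name:
                return r.pathway
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.regions)


def default_layout(dipole_count: int = 8) -> RegionLayout:
    """24-region layout: 12 ventral-visual and 12 prefrontal regions
    (6 anatomical names x 2 hemispheres each)."""
    regions = []
    for names, pathway in ((_VVP_REGIONS, "VVP"), (_PFC_REGIONS, "PFC")):
        for base in names:
            for hemi, suffix in (("L", "lh"), ("R", "rh")):
                regions.append(
                    Region(f"{base}-{suffix}", pathway, hemi, dipole_count)
                )
    return RegionLayout(regions=regions)


def tiny_layout(dipole_count: int = 4) -> RegionLayout:
    """Three-region desk-scale layout used by the miniature fixtures."""
    return RegionLayout(
        regions=[
            Region("fusiform-lh", "VVP", "L", dipole_count),
            Region("lateraloccipital-rh", "VVP", "R", dipole_count),
            Region("parsorbitalis-lh", "PFC", "L", dipole_count),
        ]
    )


def learning_curve(trial_index, learning: LearningParams):
    """Logistic learning modulation in [0, 1]; vectorised over trial_index."""
    t = np.asarray(trial_index, dtype=float)
    if np.any(t < 0):
        raise ValueError("trial_index must be >= 0")
    sig = 1.0 / (1.0 + np.exp(-learning.rate * (t - learning.midpoint_trial)))
    out = learning.floor + (learning.ceiling - learning.floor) * sig
    return float(out) if np.isscalar(trial_index) else out


def time_axis(dt_ms: float = DEFAULT_DT_MS) -> np.ndarray:
    """Sample grid from -120 ms to 400 ms (exclusive), including onset at 0."""
    if dt_ms <= 0 or (EPOCH_START_MS / dt_ms) % 1 != 0:
        raise ValueError("dt_ms must be positive and divide the epoch bounds")
    return np.arange(EPOCH_START_MS, EPOCH_STOP_MS, dt_ms)


def raised_cosine(time_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Raised-cosine bump on [start, stop): 0 at the edges, 1 at the centre."""
    start, stop = window_ms
    bump = np.zeros_like(time_ms, dtype=float)
    inside = (time_ms >= start) & (time_ms < stop)
    phase = (time_ms[inside] - start) / (stop - start)
    bump[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return bump


def _smoothed_noise(
    rng: np.random.Generator, shape: tuple[int, ...], noise: NoiseParams, dt_ms: float
) -> np.ndarray:
    x = rng.standard_normal(shape)
    k = max(1, int(round(noise.smooth_ms / dt_ms)))
    if k > 1:
        # moving average then rescale so the marginal variance stays sd^2
        x = uniform_filter1d(x, size=k, axis=-1, mode="reflect") * np.sqrt(k)
    return noise.sd * x


def _inject_effects(
    data: np.ndarray,
    effects: list[EffectSpec],
    labels: np.ndarray,
    trial_index: np.ndarray,
    time_ms: np.ndarray,
    rng: np.random.Generator,
) -> None:
    n_channels = data.shape[1]
    signs = np.where(labels == "A", 1.0, -1.0)
    for eff in effects:
        pattern = eff.spatial_pattern
        if pattern is None:
            pattern = rng.standard_normal(n_channels)
            pattern /= np.linalg.norm(pattern)
        elif pattern.shape != (n_channels,):
            raise ValueError(
                f"spatial_pattern length {pattern.shape[0]} != {n_channels} channels"
            )
        bump = raised_cosine(time_ms, eff.window_ms)
        gain = eff.amplitude * signs * learning_curve(trial_index, eff.learning)
        data += gain[:, None, None] * pattern[None, :, None] * bump[None, None, :]


def _simulate(
    stimulus_set: StimulusSet,
    effects: list[EffectSpec],
    noise: NoiseParams,
    rng: np.random.Generator,
    n_channels: int,
    channel_names: list[str],
    kind: str,
    dt_ms: float,
) -> EpochSet:
    t = time_axis(dt_ms)
    labels = stimulus_set.trial_labels
    n_trials = labels.size
    trial_index = np.arange(n_trials)
    data = _smoothed_noise(rng, (n_trials, n_channels, t.size), noise, dt_ms)
    if noise.baseline_offset_sd > 0:
        data += rng.normal(0.0, noise.baseline_offset_sd, size=(n_trials, n_channels, 1))
    _inject_effects(data, effects, labels, trial_index, t, rng)
    return EpochSet(
        data=data,
        labels=labels,
        trial_index=trial_index,
        time_ms=t,
        channel_names=channel_names,
        kind=kind,
    )


def simulate_sensor_epochs(
    stimulus_set: StimulusSet,
    effects: list[EffectSpec] | None = None,
    noise: NoiseParams = NoiseParams(),
    rng: np.random.Generator | None = None,
    n_channels: int = N_SENSORS,
    dt_ms: float = DEFAULT_DT_MS,
) -> EpochSet:
    """Whole-head magnetometer-ensemble epochs for every trial of the set."""
    if rng is None:
        rng = np.random.default_rng()
    effects = list(effects or [])
    for eff in effects:
        if eff.target != "sensor":
            raise ValueError(f"sensor simulation got effect targeting {eff.target!r}")
    names = [f"MAG{i:03d}" for i in range(n_channels)]
    return _simulate(stimulus_set, effects, noise, rng, n_channels, names, "sensor", dt_ms)


def simulate_region_ensembles(
    stimulus_set: StimulusSet,
    layout: RegionLayout,
    effects: list[EffectSpec] | None = None,
    noise: NoiseParams = NoiseParams(),
    rng: np.random.Generator | None = None,
    dt_ms: float = DEFAULT_DT_MS,
) -> dict[str, EpochSet]:
    """One dipole-ensemble EpochSet per region; effects only in their targets."""
    if rng is None:
        rng = np.random.default_rng()
    effects = list(effects or [])
    known = set(layout.names)
    for eff in effects:
        if eff.target not in known:
            raise ValueError(f"effect targets unknown region {eff.target!r}")
    out: dict[str, EpochSet] = {}
    streams = rng.spawn(len(layout))
    for region, stream in zip(layout.regions, streams):
        region_effects = [e for e in effects if e.target == region.name]
        names = [f"{region.name}-dip{i:02d}" for i in range(region.dipole_count)]
        out[region.name] = _simulate(
            stimulus_set, region_effects, noise, stream,
            region.dipole_count, names, "region", dt_ms,
        )
    return out


def default_scenario_effects(
    layout: RegionLayout,
    amplitude: float = 2.5,
    midpoint_trial: int = 300,
    rate: float = 0.02,
) -> list[EffectSpec]:
    """The canonical learning scenario.

    One left ventral-visual region (fusiform-lh) carries a 150-250 ms
    effect whose strength ramps up with learning (floor 0.05, ceiling 1.0);
    one left prefrontal region (parsorbitalis-lh) carries a 250-350 ms
    effect that decays with learning (floor 1.0, ceiling 0.2).  All other
    regions are pure noise.
    """
    for target in (DEFAULT_VVP_TARGET, DEFAULT_PFC_TARGET):
        if target not in layout.names:
            raise ValueError(f"layout lacks default scenario target {target!r}")
    return [
        EffectSpec(
            target=DEFAULT_VVP_TARGET,
            window_ms=(150.0, 250.0),
            amplitude=amplitude,
            learning=LearningParams(floor=0.05, ceiling=1.0,
                                    midpoint_trial=midpoint_trial, rate=rate),
        ),
        EffectSpec(
            target=DEFAULT_PFC_TARGET,
            window_ms=(250.0, 350.0),
            amplitude=amplitude,
            learning=LearningParams(floor=1.0, ceiling=0.2,
                                    midpoint_trial=midpoint_trial, rate=rate),
        ),
    ]


def default_sensor_effect(amplitude: float = 1.0,
                          midpoint_trial: int = 300,
                          rate: float = 0.02) -> EffectSpec:
    """Sensor-space analogue of the learning effect: 150-250 ms ramp-up."""
    return EffectSpec(
        target="sensor",
        window_ms=(150.0, 250.0),
        amplitude=amplitude,
        learning=LearningParams(floor=0.05, ceiling=1.0,
                                midpoint_trial=midpoint_trial, rate=rate),
    )
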