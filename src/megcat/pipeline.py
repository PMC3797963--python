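"""End-to-end orchestration: simulate -> preprocess -> discriminate ->
excursion -> decode, for a cohort of simulated subjects.

A single master seed is split with ``numpy.random.SeedSequence`` into
per-subject streams and, within each subject, per-stage streams
(stimuli, sensor simulation, region simulation, label permutations), so
every result file is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .decoding import CANONICAL_WINDOWS, compare_phases, decode_grid, pool_pathways
from .discriminability import discriminability_trace, shuffled_traces
from .excursion import excursion_pvalue, fisher_combine, find_excursions
from .preprocess import remove_baseline, select_phase, sliding_average
from .simulate import (
    NoiseParams,
    default_layout,
    default_scenario_effects,
    default_sensor_effect,
    simulate_region_ensembles,
    simulate_sensor_epochs,
    tiny_layout,
)
from .stimuli import generate_stimulus_set, make_prototype_pair

logger = logging.getLogger(__name__)

_STAGES = ("stimuli", "sensor", "region", "perm")


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the study's canonical defaults."""

    seed: int = 0
    n_subjects: int = 7
    # stimuli
    n_per_category: int = 300
    n_blocks: int = 5
    jitter_scale: float = 0.2
    min_mean_separation: float = 0.0
    # simulation
    scenario: str = "default"  # or "null" (no effects anywhere)
    layout_name: str = "default"  # or "tiny"
    dipole_count: int = 8
    n_sensors: int = 102
    dt_ms: float = 5.0
    noise_sd: float = 1.0
    noise_smooth_ms: float = 20.0
    baseline_offset_sd: float = 0.5
    effect_amplitude: float = 2.5
    sensor_amplitude: float = 1.0
    learning_midpoint_trial: int = 300
    learning_rate: float = 0.02
    # analysis
    variance_fraction: float = 0.99
    bin_window_ms: float = 20.0
    bin_step_ms: float = 10.0
    excursion_threshold: float = 20.0
    excursion_summary: str = "max_mass"
    n_perm: int = 100
    n_phase: int = 100
    save_epochs: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_per_category < 1 or self.n_per_category % self.n_blocks != 0:
            raise ValueError("n_per_category must be positive and divisible by n_blocks")
        if self.scenario not in ("default", "null"):
            raise ValueError("scenario must be 'default' or 'null'")
        if self.layout_name not in ("default", "tiny"):
            raise ValueError("layout_name must be 'default' or 'tiny'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError("variance_fraction must be in (0, 1]")
        if self.excursion_threshold <= 0:
            raise ValueError("excursion_threshold must be > 0")
        n_trials = 2 * self.n_per_category
        if self.n_phase < 6 or self.n_phase > n_trials:
            raise ValueError("n_phase must lie in [6, total trial count]")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    def layout(self):
        make = default_layout if self.layout_name == "default" else tiny_layout
        return make(dipole_count=self.dipole_count)

    def noise(self) -> NoiseParams:
        return NoiseParams(
            sd=self.noise_sd,
            smooth_ms=self.noise_smooth_ms,
            baseline_offset_sd=self.baseline_offset_sd,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def tiny_config(seed: int = 0) -> AnalysisConfig:
    """Desk-scale configuration used by the miniature fixtures and tests."""
    return AnalysisConfig(
        seed=seed,
        n_subjects=2,
        n_per_category=20,
        layout_name="tiny",
        dipole_count=4,
        n_sensors=12,
        n_perm=20,
        n_phase=10,
    )


def _subject_stage_seeds(master_seed: int, n_subjects: int) -> list[dict]:
    """Per-subject, per-stage seed sequences derived from the master seed."""
    subject_seqs = np.random.SeedSequence(master_seed).spawn(n_subjects)
    out = []
    for seq in subject_seqs:
        children = seq.spawn(len(_STAGES))
        out.append(dict(zip(_STAGES, children)))
    return out


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Execute every stage for every simulated subject; write the bundle.

    Output layout under ``out_dir``: stimuli/, epochs/ (optional),
    traces/, excursion/, decoding/, manifest.json.  Idempotent for a
    fixed config.
    """
    config.validate()
    out = Path(out_dir)
    for sub in ("stimuli", "epochs", "traces", "excursion", "decoding"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    layout = config.layout()
    noise = config.noise()
    subject_p = []
    written: list[str] = []

    def save_frame(df, rel: str) -> None:
        df.to_csv(out / rel, index=False)
        written.append(rel)

    for s, stage_seqs in enumerate(_subject_stage_seeds(config.seed, config.n_subjects)):
        tag = f"subject{s:02d}"
        logger.info("pipeline: %s starting", tag)

        # -- stimuli ----------------------------------------------------
        stim_rng = np.random.default_rng(stage_seqs["stimuli"])
        pair = make_prototype_pair(
            seed=int(stage_seqs["stimuli"].generate_state(1)[0]),
            min_mean_separation=config.min_mean_separation,
            jitter_scale=config.jitter_scale,
        )
        stimuli = generate_stimulus_set(
            pair, config.n_per_category, stim_rng, config.n_blocks
        )
        stimuli.to_csv(out / "stimuli" / f"{tag}_exemplars.csv",
                       out / "stimuli" / f"{tag}_order.csv")
        written += [f"stimuli/{tag}_exemplars.csv", f"stimuli/{tag}_order.csv"]

        # -- sensor-space discriminability + excursion ------------------
        sensor_effects = (
            [default_sensor_effect(config.sensor_amplitude,
                                   config.learning_midpoint_trial,
                                   config.learning_rate)]
            if config.scenario == "default"
            else []
        )
        sensor = simulate_sensor_epochs(
            stimuli, sensor_effects, noise,
            np.random.default_rng(stage_seqs["sensor"]),
            n_channels=config.n_sensors, dt_ms=config.dt_ms,
        )
        if config.save_epochs:
            sensor.to_hdf5(out / "epochs" / f"{tag}_sensor.h5")
            written.append(f"epochs/{tag}_sensor.h5")
        binned = sliding_average(remove_baseline(sensor),
                                 config.bin_window_ms, config.bin_step_ms)
        trace = discriminability_trace(binned, variance_fraction=config.variance_fraction)
        nulls = shuffled_traces(
            binned, n_perm=config.n_perm,
            rng=np.random.default_rng(stage_seqs["perm"]),
            variance_fraction=config.variance_fraction,
        )
        trace.to_csv(out / "traces" / f"{tag}_trace.csv")
        nulls.to_csv(out / "traces" / f"{tag}_nulls.csv")
        written += [f"traces/{tag}_trace.csv", f"traces/{tag}_nulls.csv"]

        result = excursion_pvalue(
            find_excursions(trace, config.excursion_threshold),
            nulls, config.excursion_threshold, config.excursion_summary,
        )
        with open(out / "excursion" / f"{tag}.json", "w") as f:
            json.dump(result.to_dict(), f, indent=2, sort_keys=True)
        written.append(f"excursion/{tag}.json")
        subject_p.append(result.p_value)

        # -- region-space decoding --------------------------------------
        region_effects = (
            default_scenario_effects(layout, config.effect_amplitude,
                                     config.learning_midpoint_trial,
                                     config.learning_rate)
            if config.scenario == "default"
            else []
        )
        regions = simulate_region_ensembles(
            stimuli, layout, region_effects, noise,
            np.random.default_rng(stage_seqs["region"]), dt_ms=config.dt_ms,
        )
        regions = {name: remove_baseline(ep) for name, ep in regions.items()}
        if config.save_epochs:
            for name, ep in regions.items():
                ep.to_hdf5(out / "epochs" / f"{tag}_{name}.h5")
                written.append(f"epochs/{tag}_{name}.h5")
        table = decode_grid(
            regions, CANONICAL_WINDOWS, n_phase=config.n_phase,
            variance_fraction=config.variance_fraction, layout=layout,
        )
        save_frame(table, f"decoding/{tag}_accuracy.csv")
        save_frame(compare_phases(table), f"decoding/{tag}_phase_comparison.csv")
        pooled = pool_pathways(table, layout)
        with open(out / "decoding" / f"{tag}_pooled.json", "w") as f:
            json.dump(pooled.to_dict(orient="records"), f, indent=2, sort_keys=True)
        written.append(f"decoding/{tag}_pooled.json")

    group = fisher_combine(subject_p)
    with open(out / "excursion" / "group.json", "w") as f:
        json.dump(group.to_dict(), f, indent=2, sort_keys=True)
    written.append("excursion/group.json")

    config_dict = config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.seed,
        "seed_rule": "SeedSequence(master).spawn(n_subjects), each spawned into "
                     "(stimuli, sensor, region, perm) stage streams",
        "files": sorted(written),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return {"group": group, "subject_p_values": subject_p, "manifest": manifest,
            "out_dir": str(out)}


def generate_fixtures(size: str = "tiny", out_dir: str | Path = "fixtures",
                      seed: int = 0) -> dict:
    """Deterministic miniature datasets for smoke tests and examples.

    ``tiny``: 3 regions x 40 trials x 5 ms sampling; ``default``: the full
    study-scale configuration.
    """
    if size == "tiny":
        config = tiny_config(seed)
        config.save_epochs = True
    elif size == "default":
        config = AnalysisConfig(seed=seed)
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    return run_pipeline(config, out_dir)
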