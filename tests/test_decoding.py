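"""Window averaging, leave-one-out logistic decoding, phase and pathway
contrasts.  The majority-of-seeds properties of the canonical learning
scenario read the session-scoped ``scenario_runs`` fixture."""

import numpy as np
import pytest
from scipy import stats

from megcat import (
    CANONICAL_WINDOWS,
    EffectSpec,
    NoiseParams,
    WindowSpec,
    compare_phases,
    decode_grid,
    loo_logistic_accuracy,
    pool_pathways,
    remove_baseline,
    simulate_region_ensembles,
    tiny_layout,
    window_average,
)
from megcat.simulate import (
    DEFAULT_PFC_TARGET,
    DEFAULT_VVP_TARGET,
    LearningParams,
    learning_curve,
    simulate_sensor_epochs,
)


class TestWindowAverage:
    def test_canonical_windows(self):
        names = {w.name: w.interval_ms for w in CANONICAL_WINDOWS}
        assert names == {
            "baseline": (0.0, 50.0),
            "M100": (50.0, 150.0),
            "M200": (150.0, 250.0),
            "M300": (250.0, 350.0),
        }

    def test_constant_signal_passes_through(self, noise_sensor_epochs):
        ep = remove_baseline(noise_sensor_epochs)
        ep.data[:] = 3.25
        feats = window_average(ep, WindowSpec("M200", (150.0, 250.0)))
        assert feats.shape == (ep.n_trials, ep.n_channels)
        assert np.all(feats == 3.25)

    def test_full_epoch_window_equals_temporal_mean(self, noise_sensor_epochs):
        ep = remove_baseline(noise_sensor_epochs)
        feats = window_average(ep, WindowSpec("all", (0.0, 400.0)))
        np.testing.assert_allclose(feats, ep.data.mean(axis=2))

    def test_effect_shifts_window_means_by_closed_form(self, small_stimuli):
        # the raised-cosine bump averages to 1/2 over its window, so the
        # A-minus-B feature difference along the pattern is
        # 2 x amplitude x 1/2 x mean learning gain, to within noise
        amp = 6.0
        pattern = np.zeros(8)
        pattern[0] = 1.0
        flat = LearningParams(floor=0.7, ceiling=0.7)
        eff = EffectSpec("sensor", (150.0, 250.0), amp, flat, spatial_pattern=pattern)
        diffs = []
        for seed in range(10):
            ep = simulate_sensor_epochs(
                small_stimuli, [eff], NoiseParams(),
                np.random.default_rng(seed), n_channels=8,
            )
            feats = window_average(remove_baseline(ep),
                                   WindowSpec("M200", (150.0, 250.0)))
            labels = ep.labels
            diffs.append(feats[labels == "A", 0].mean() - feats[labels == "B", 0].mean())
        expected = 2.0 * amp * 0.5 * 0.7
        assert np.mean(diffs) == pytest.approx(expected, rel=0.02)

    def test_window_outside_samples_rejected(self, noise_sensor_epochs):
        ep = remove_baseline(noise_sensor_epochs)
        with pytest.raises(ValueError):
            window_average(ep, WindowSpec("bad", (500.0, 600.0)))


class TestLooLogisticAccuracy:
    def test_perfectly_separated_features_decode_perfectly(self, rng):
        x = np.concatenate([rng.normal(-2, 0.1, 15), rng.normal(2, 0.1, 15)])
        labels = np.array(["A"] * 15 + ["B"] * 15)
        res = loo_logistic_accuracy(x[:, None], labels)
        assert res.accuracy == 1.0
        assert res.n_correct == 30

    def test_shuffled_labels_on_noise_stay_within_chance_band(self, rng):
        x = rng.standard_normal((100, 6))
        labels = rng.permutation(np.array(["A", "B"] * 50))
        res = loo_logistic_accuracy(x, labels)
        lo, hi = stats.binom.interval(0.95, 100, 0.5)
        assert lo / 100 <= res.accuracy <= hi / 100

    def test_duplicated_feature_columns_change_nothing(self, rng):
        x = rng.standard_normal((40, 4)) + np.outer(
            np.repeat([0.0, 1.0], 20), np.ones(4)
        )
        labels = np.repeat(["A", "B"], 20)
        ref = loo_logistic_accuracy(x, labels)
        dup = loo_logistic_accuracy(np.hstack([x, x]), labels)
        assert dup.accuracy == ref.accuracy

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_logistic_accuracy(rng.standard_normal((10, 2)), np.array(["A"] * 10))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_logistic_accuracy(
                rng.standard_normal((4, 2)), np.array(["A", "B", "A", "B"])
            )


class TestDecodeGrid:
    def test_grid_covers_region_window_phase_cross(self, small_stimuli, rng):
        layout = tiny_layout()
        regions = simulate_region_ensembles(small_stimuli, layout, [],
                                            NoiseParams(), rng)
        regions = {k: remove_baseline(v) for k, v in regions.items()}
        table = decode_grid(regions, n_phase=12, layout=layout)
        assert len(table) == len(layout) * len(CANONICAL_WINDOWS) * 2
        assert set(table["pathway"]) == {"VVP", "PFC"}
        assert np.all((table["accuracy"] >= 0) & (table["accuracy"] <= 1))
        assert np.all(table["n_trials"] == 12)

    def test_full_grid_has_192_cells(self, scenario_runs):
        table = scenario_runs[0]["table"]
        assert len(table) == 24 * 4 * 2
        assert table.groupby(["region", "window", "phase"]).size().max() == 1

    def test_late_phase_maximum_sits_at_target_region_and_window(self, scenario_runs):
        hits = 0
        for run in scenario_runs:
            late = run["table"][run["table"]["phase"] == "late"]
            best = late.loc[late["accuracy"].idxmax()]
            hits += (best["region"] == DEFAULT_VVP_TARGET) and (best["window"] == "M200")
        assert hits >= 15

    def test_baseline_window_stays_at_chance_in_majority_of_cells(self, scenario_runs):
        lo, hi = stats.binom.interval(0.95, 100, 0.5)
        inside = 0
        total = 0
        for run in scenario_runs[:5]:
            base = run["table"][run["table"]["window"] == "baseline"]
            inside += np.sum((base["accuracy"] >= lo / 100) & (base["accuracy"] <= hi / 100))
            total += len(base)
        assert inside / total >= 0.9


class TestComparePhases:
    def test_identical_accuracies_give_zero_difference_and_p_one(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "region": ["r1"] * 2,
                "window": ["M200"] * 2,
                "phase": ["early", "late"],
                "accuracy": [0.6, 0.6],
                "n_trials": [100, 100],
                "n_correct": [60, 60],
                "dims": [3, 3],
            }
        )
        out = compare_phases(table)
        assert out.loc[0, "difference"] == 0.0
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_z_test_matches_closed_form(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "region": ["r1"] * 2,
                "window": ["M200"] * 2,
                "phase": ["early", "late"],
                "accuracy": [0.5, 0.83],
                "n_trials": [100, 100],
                "n_correct": [50, 83],
                "dims": [3, 3],
            }
        )
        out = compare_phases(table)
        pooled = (50 + 83) / 200
        z = (0.83 - 0.50) / np.sqrt(pooled * (1 - pooled) * (1 / 100 + 1 / 100))
        expected = 2 * stats.norm.sf(abs(z))
        assert out.loc[0, "difference"] == pytest.approx(0.33)
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)
        assert out.loc[0, "p_value"] < 0.001

    def test_largest_learning_gain_is_the_target_m200_cell(self, scenario_runs):
        hits = 0
        for run in scenario_runs:
            cmp = run["phase_comparison"]
            best = cmp.loc[cmp["difference"].idxmax()]
            hits += (best["region"] == DEFAULT_VVP_TARGET) and (best["window"] == "M200")
        assert hits > 10


class TestPoolPathways:
    def test_uniform_half_accuracies_pool_to_half(self):
        import pandas as pd

        layout = tiny_layout()
        rows = []
        for region in layout.names:
            for phase in ("early", "late"):
                rows.append(
                    {
                        "region": region,
                        "window": "M200",
                        "phase": phase,
                        "accuracy": 0.5,
                        "n_trials": 100,
                        "n_correct": 50,
                        "dims": 2,
                    }
                )
        out = pool_pathways(pd.DataFrame(rows), layout)
        assert np.all(out["pooled_accuracy_vvp"] == 0.5)
        assert np.all(out["pooled_accuracy_pfc"] == 0.5)
        assert np.all(out["difference"] == 0.0)

    def test_pooling_invariant_to_region_order(self, scenario_runs):
        from megcat import default_layout

        layout = default_layout()
        table = scenario_runs[0]["table"]
        shuffled = table.sample(frac=1.0, random_state=0)
        a = pool_pathways(table, layout).sort_values(["window", "phase"])
        b = pool_pathways(shuffled, layout).sort_values(["window", "phase"])
        np.testing.assert_allclose(
            a["pooled_accuracy_vvp"].to_numpy(), b["pooled_accuracy_vvp"].to_numpy()
        )
        np.testing.assert_allclose(
            a["pooled_accuracy_pfc"].to_numpy(), b["pooled_accuracy_pfc"].to_numpy()
        )

    def test_late_learning_favours_ventral_visual_pathway_at_m200(self, scenario_runs):
        hits = 0
        for run in scenario_runs:
            pooled = run["pooled"]
            row = pooled[(pooled["window"] == "M200") & (pooled["phase"] == "late")]
            hits += float(row["difference"].iloc[0]) > 0
        assert hits >= 15
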