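from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollenifc import simulate
from pollenifc.simulate import (
    GeneratorConfig,
    default_config,
    generate_buffer_stability,
    generate_genotype_panel,
    generate_hydration_course,
    generate_mixing_series,
    sample_population,
)


def true_viability_pct(events: pd.DataFrame, exclude_sterile: bool = True) -> float:
    """Ground-truth sterile-excluded viability from the hidden labels."""
    counts = events["true_label"].value_counts()
    v = counts.get("viable", 0)
    d = counts.get("dead", 0) + counts.get("intermediate", 0)
    s = counts.get("sterile", 0)
    denom = v + d if exclude_sterile else v + d + s
    return 100.0 * v / denom


class TestSamplePopulation:
    def test_viable_population_mean_phase(self, config80):
        # 200° ± 1.35°; tolerance 3 sd/sqrt(n)
        events = sample_population(config80.populations["viable"], 20_000, seed=1)
        assert events["phase8_deg"].mean() == pytest.approx(200.0, abs=0.05)

    def test_sterile_population_mean_amplitude(self, config80):
        events = sample_population(config80.populations["sterile"], 20_000, seed=2, chip=config80.chip)
        assert events["amp8"].mean() == pytest.approx(0.364, abs=0.004)

    def test_single_event(self, config80):
        events = sample_population(config80.populations["dead"], 1, seed=3)
        assert len(events) == 1
        assert events["true_label"].iloc[0] == "dead"

    def test_nonpositive_n_rejected(self, config80):
        with pytest.raises(ValueError):
            sample_population(config80.populations["dead"], 0)

    def test_amplitudes_truncated_at_trigger(self, config80):
        events = sample_population(config80.populations["sterile"], 50_000, seed=4, chip=config80.chip)
        assert events["amp8"].min() >= config80.chip.trigger_level
        assert events["amp2"].min() >= config80.chip.trigger_level


def test_same_seed_identical_tables():
    a = generate_mixing_series(seed=9, events_per_replica=500)
    b = generate_mixing_series(seed=9, events_per_replica=500)
    pd.testing.assert_frame_equal(a, b)
    c = generate_mixing_series(seed=10, events_per_replica=500)
    assert not a["phase8_deg"].equals(c["phase8_deg"])


def test_class_counts_multinomial():
    """Generated class counts follow the configured fractions (chi-square)."""
    config = default_config(120)
    expected = np.array([config.class_fractions[c] for c in ("viable", "dead", "sterile", "intermediate")])
    for seed in range(20):
        events = generate_hydration_course(config, times=(0.0,), events_per_step=5000, seed=seed)
        counts = events["true_label"].value_counts()
        observed = np.array([counts.get(c, 0) for c in ("viable", "dead", "sterile", "intermediate")])
        p = stats.chisquare(observed, expected * observed.sum()).pvalue
        assert p > 0.001


class TestMixingSeries:
    def test_expected_viability_at_half(self, config80):
        config = replace(config80, mixing_untreated_viability=1.0)
        events = generate_mixing_series(config, ratios=((1, 1),), samples=1, replicas=1,
                                        events_per_replica=20_000, seed=5)
        assert true_viability_pct(events) == pytest.approx(50.0, abs=1.0)

    def test_fully_treated_has_no_viable(self, config80):
        events = generate_mixing_series(config80, ratios=((0, 1),), samples=1, replicas=1,
                                        events_per_replica=5000, seed=6)
        assert (events["true_label"] == "viable").sum() == 0

    def test_three_to_one_ratio(self, config80):
        config = replace(config80, mixing_untreated_viability=1.0)
        events = generate_mixing_series(config, ratios=((3, 1),), samples=1, replicas=1,
                                        events_per_replica=20_000, seed=7)
        assert true_viability_pct(events) == pytest.approx(75.0, abs=1.0)

    def test_sterile_fraction_constant_across_ratios(self, config80):
        events = generate_mixing_series(config80, samples=1, replicas=1,
                                        events_per_replica=10_000, seed=8)
        by_ratio = events.groupby("nominal_viability_pct")["true_label"].apply(
            lambda s: (s == "sterile").mean()
        )
        assert by_ratio.max() - by_ratio.min() < 0.03
        assert by_ratio.mean() == pytest.approx(config80.mixing_sterile_fraction, abs=0.02)

    def test_negative_ratio_rejected(self, config80):
        with pytest.raises(ValueError):
            generate_mixing_series(config80, ratios=((-1, 1),), seed=0)


class TestHydrationCourse:
    def test_dead_phase_endpoints(self, config120):
        events = generate_hydration_course(config120, times=(0.0, 330.0, 420.0),
                                           events_per_step=20_000, seed=12)
        for t, expected in ((0.0, 192.0), (330.0, 188.0), (420.0, 188.0)):
            step = events[(events["time_min"] == t) & (events["true_label"] == "dead")]
            tol = 3 * 0.72 / np.sqrt(len(step))
            assert step["phase8_deg"].mean() == pytest.approx(expected, abs=tol + 0.05)

    def test_viable_mode_fixed(self, config120):
        events = generate_hydration_course(config120, times=(0.0, 420.0),
                                           events_per_step=20_000, seed=13)
        viable = events[events["true_label"] == "viable"]
        for _, grp in viable.groupby("time_min"):
            assert grp["phase8_deg"].mean() == pytest.approx(198.0, abs=0.1)

    def test_no_recovery_viability_non_increasing(self, config120):
        config = replace(config120, hydration=replace(config120.hydration,
                                                      intermediate_recovery_fraction=0.0))
        events = generate_hydration_course(config, events_per_step=10_000, seed=14)
        viab = events.groupby("time_min").apply(true_viability_pct, include_groups=False)
        # without a recovery pathway viability is flat in expectation;
        # allow 3x the binomial standard error per step
        se = 100 * np.sqrt(0.5 * 0.5 / (10_000 * 0.85))
        assert viab.max() - viab.min() < 6 * se

    def test_recovery_increases_viability(self, config120):
        events = generate_hydration_course(config120, events_per_step=10_000, seed=15)
        viab = events.groupby("time_min").apply(true_viability_pct, include_groups=False)
        assert viab.loc[420.0] - viab.loc[0.0] > 3.0

    def test_empty_time_grid_rejected(self, config120):
        with pytest.raises(ValueError):
            generate_hydration_course(config120, times=())


class TestBufferStability:
    def test_rehydrated_viability_stable(self, config120):
        events = generate_buffer_stability(config120, rehydrated=True, samples=3,
                                           events_per_sample=10_000, seed=16)
        viab = events.groupby("time_min").apply(true_viability_pct, include_groups=False)
        assert viab.max() - viab.min() < 2.0

    def test_zero_decay_arms_identical(self, config120):
        config = replace(config120, buffer_decay_rate=0.0)
        a = generate_buffer_stability(config, rehydrated=True, samples=2,
                                      events_per_sample=2000, seed=17)
        b = generate_buffer_stability(config, rehydrated=False, samples=2,
                                      events_per_sample=2000, seed=17)
        pd.testing.assert_frame_equal(a.drop(columns="rehydrated"), b.drop(columns="rehydrated"))

    def test_exponential_decay_endpoint(self, config120):
        config = replace(config120, buffer_decay_rate=0.02)
        events = generate_buffer_stability(config, rehydrated=False, times=(0.0, 90.0),
                                           samples=6, events_per_sample=10_000, seed=18)
        f_via = 0.45 + 0.15  # intermediate folded into the viable pool
        frac0 = (events[events.time_min == 0.0]["true_label"] == "viable").mean()
        frac90 = (events[events.time_min == 90.0]["true_label"] == "viable").mean()
        assert frac0 == pytest.approx(f_via, abs=0.01)
        assert frac90 == pytest.approx(f_via * np.exp(-1.8), abs=0.01)


class TestGenotypePanel:
    def test_low_sterility_genotype_replicas(self, reference_panel, config120):
        row = reference_panel[reference_panel.genotype == "Tonda Bianca"]
        events = generate_genotype_panel(row, config120, replicas=3,
                                         events_per_replica=20_000, seed=19)
        for _, rep in events.groupby("replica"):
            pct = 100 * (rep["true_label"] == "sterile").mean()
            assert 0.7 <= pct <= 1.3

    def test_zero_sd_rows_identical_in_expectation(self, config120):
        panel = pd.DataFrame(
            {"genotype": ["X"], "sterility_mean": [40.0], "sterility_sd": [0.0],
             "viability_mean": [55.0]}
        )
        events = generate_genotype_panel(panel, config120, replicas=4,
                                         events_per_replica=20_000, seed=20)
        pcts = events.groupby("replica")["true_label"].apply(lambda s: 100 * (s == "sterile").mean())
        se = 100 * np.sqrt(0.4 * 0.6 / 20_000)
        assert pcts.std() < 3 * se

    def test_missing_column_rejected(self, config120):
        with pytest.raises(ValueError, match="sterility_sd"):
            generate_genotype_panel(
                pd.DataFrame({"genotype": ["X"], "sterility_mean": [1.0], "viability_mean": [98.0]}),
                config120,
            )

    def test_zero_coupling_equalises_viable_amplitude(self, config120):
        panel = pd.DataFrame(
            {"genotype": ["lo", "hi"], "sterility_mean": [5.0, 70.0],
             "sterility_sd": [0.1, 0.1], "viability_mean": [93.0, 28.0]}
        )
        events = generate_genotype_panel(panel, config120, replicas=2, events_per_replica=10_000,
                                         viable_size_coupling=0.0, sterile_size_coupling=0.0, seed=21)
        amp = events[events.true_label == "viable"].groupby("genotype")["amp2"].mean()
        assert abs(amp["lo"] - amp["hi"]) < 0.01

    def test_positive_coupling_orders_viable_amplitude(self, config120):
        panel = pd.DataFrame(
            {"genotype": ["lo", "hi"], "sterility_mean": [5.0, 70.0],
             "sterility_sd": [0.1, 0.1], "viability_mean": [93.0, 28.0]}
        )
        events = generate_genotype_panel(panel, config120, replicas=2, events_per_replica=10_000,
                                         seed=22)
        amp = events[events.true_label == "viable"].groupby("genotype")["amp2"].mean()
        assert amp["hi"] - amp["lo"] == pytest.approx(0.002 * 65.0, abs=0.01)


def test_config_validation():
    base = default_config(80)
    with pytest.raises(ValueError, match="sum to 1"):
        GeneratorConfig(populations=base.populations,
                        class_fractions={"viable": 0.5, "dead": 0.4})
    with pytest.raises(ValueError, match="channel_size_um"):
        simulate.ChipProfile(channel_size_um=100)
    with pytest.raises(ValueError):
        default_config(90)
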