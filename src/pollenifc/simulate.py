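"""Seeded simulation of impedance flow cytometry (IFC) event tables.

Real IFC exports are CSV tables with one row per particle transit: phase and
amplitude at each measurement frequency plus sample metadata.  No public
hazelnut-pollen event data exist, so this module generates event clouds with
the statistical structure the downstream analysis assumes:

* three to four Gaussian populations in phase–amplitude space (viable, dead,
  sterile, and a partially-dehydrated "intermediate" class),
* heat inactivation (viable and intermediate grains acquire the dead-class
  signature; sterile grains are unaffected),
* mixing series of untreated and heat-inactivated pollen,
* a pre-hydration time course in which the dead-population phase mode drifts
  from 192° down to 188° over ~5.5 h while the viable mode sits at 198°,
* exponential viability decay of non-rehydrated pollen in buffer,
* a genotype panel whose per-replica sterile fractions are drawn from a
  reference table of per-cultivar means ± sd, with an optional coupling
  between sterility and viable-pollen size (2 MHz amplitude).

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, one child stream per (condition, sample, replica) unit in iteration
order, so replicas are independent but the whole experiment is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationProfile",
    "ChipProfile",
    "HydrationParams",
    "GeneratorConfig",
    "default_config",
    "sample_population",
    "generate_mixing_series",
    "generate_hydration_course",
    "generate_buffer_stability",
    "generate_genotype_panel",
    "EVENT_COLUMNS",
]

#: canonical event-table schema (true_label only present for synthetic data)
EVENT_COLUMNS = [
    "genotype",
    "sample",
    "replica",
    "time_min",
    "phase2_deg",
    "amp2",
    "phase8_deg",
    "amp8",
    "true_label",
]

CLASSES = ("viable", "dead", "sterile", "intermediate")


@dataclass(frozen=True)
class PopulationProfile:
    """Marginal Gaussian parameters of one pollen class on both channels.

    Phases are degrees; amplitudes are arbitrary instrument units.  The
    8 MHz channel carries the viability signal (membrane integrity); the
    2 MHz amplitude is a proxy for grain volume.  Phase/amplitude draws are
    independent: the instrument clouds are roughly elliptical and only
    marginal means ± sd are known, so no correlation term is modelled.
    """

    label: str
    phase8_mean: float
    phase8_sd: float
    amp8_mean: float
    amp8_sd: float
    phase2_mean: float
    phase2_sd: float
    amp2_mean: float
    amp2_sd: float

    def __post_init__(self) -> None:
        for name in ("phase8_sd", "amp8_sd", "phase2_sd", "amp2_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.amp8_mean <= 0 or self.amp2_mean <= 0:
            raise ValueError("amplitude means must be > 0")


@dataclass(frozen=True)
class ChipProfile:
    """Microfluidic chip metadata; only the trigger level affects events.

    Amplitudes below the trigger voltage never register as events, so
    sampled amplitudes are truncated below at ``trigger_level``.
    """

    channel_size_um: int = 80
    modulation_gain_v: float = 0.35
    amplification_fold: int = 12
    trigger_level: float = 0.07

    def __post_init__(self) -> None:
        if self.channel_size_um not in (80, 120):
            raise ValueError("channel_size_um must be 80 or 120")
        if self.trigger_level <= 0:
            raise ValueError("trigger_level must be > 0")


@dataclass(frozen=True)
class HydrationParams:
    """Parameters of the pre-hydration time course.

    The dead-population phase mode drifts linearly from ``dead_mode_start``
    (192°) to ``dead_mode_end`` (188°) over ``drift_duration_min`` (330 min ≈
    5.5 h) and then holds; the viable mode is fixed at ``viable_mode`` (198°,
    120 μm chip).  An intermediate class of partially dehydrated grains
    starts at the dead-mode phase and converts over the same window: a
    fraction ``intermediate_recovery_fraction`` rehydrates and joins the
    viable class, the remainder joins the dead class.  Dead-grain amplitude
    declines slowly at ``dead_amp_decline_rate`` as the grains shrink.
    """

    dead_mode_start: float = 192.0
    dead_mode_end: float = 188.0
    drift_duration_min: float = 330.0
    viable_mode: float = 198.0
    dead_amp_decline_rate: float = 2e-4  # a.u. per minute
    intermediate_recovery_fraction: float = 0.3

    def __post_init__(self) -> None:
        for v in (self.dead_mode_start, self.dead_mode_end, self.viable_mode):
            if not 0.0 <= v < 360.0:
                raise ValueError("phase modes must lie in [0, 360)")
        if not 0.0 <= self.intermediate_recovery_fraction <= 1.0:
            raise ValueError("intermediate_recovery_fraction must be in [0, 1]")

    def dead_mode_at(self, t_min: float) -> float:
        """Linearly interpolated dead-population phase mode at time ``t_min``."""
        frac = min(max(t_min, 0.0) / self.drift_duration_min, 1.0)
        return self.dead_mode_start + frac * (self.dead_mode_end - self.dead_mode_start)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic IFC experiment."""

    populations: dict[str, PopulationProfile]
    class_fractions: dict[str, float]
    hydration: HydrationParams = field(default_factory=HydrationParams)
    chip: ChipProfile = field(default_factory=ChipProfile)
    #: per-minute decay rate of viable pollen in buffer when not rehydrated
    buffer_decay_rate: float = 0.02
    #: sterile-excluded viability of the untreated arm of the mixing series
    mixing_untreated_viability: float = 0.95
    #: sterile fraction, constant across the mixing series
    mixing_sterile_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for label in self.class_fractions:
            if label not in self.populations:
                raise ValueError(f"no population profile for class {label!r}")
        if self.buffer_decay_rate < 0:
            raise ValueError("buffer_decay_rate must be >= 0")


def _profiles_80um() -> dict[str, PopulationProfile]:
    # 8 MHz parameters of the heat-inactivation validation experiment
    # (80 μm chip): viable 200° ± 1.35°, amp 0.9 ± 0.23; dead 188° ± 0.72°,
    # amp 0.9 ± 0.25; sterile 190° ± 1.1°, amp 0.364 ± 0.11.  The 2 MHz
    # channel is uncalibrated in the source data; the low-frequency
    # amplitude mirrors grain volume (sterile grains are small), phases
    # cluster near 185° with little class contrast.
    return {
        "viable": PopulationProfile("viable", 200.0, 1.35, 0.9, 0.23, 185.0, 1.5, 0.9, 0.10),
        "dead": PopulationProfile("dead", 188.0, 0.72, 0.9, 0.25, 185.0, 1.5, 0.85, 0.10),
        "sterile": PopulationProfile("sterile", 190.0, 1.1, 0.364, 0.11, 185.0, 1.5, 0.35, 0.08),
        "intermediate": PopulationProfile("intermediate", 192.0, 0.9, 0.9, 0.23, 185.0, 1.5, 0.88, 0.10),
    }


def _profiles_120um() -> dict[str, PopulationProfile]:
    # 120 μm chip (hydration course and genotype panel): viable stabilises
    # at 198°, dead at 188° after full hydration, sterile keeps its low
    # amplitude.  Phase spreads reuse the values measured on the 80 μm chip;
    # amplitude spreads are tight (0.08 a.u.), consistent with the clean,
    # essentially unambiguous sterile separation this chip achieves (panel
    # sterility sds go down to 0.08 percentage points).
    return {
        "viable": PopulationProfile("viable", 198.0, 1.35, 0.9, 0.08, 185.0, 1.5, 0.9, 0.08),
        "dead": PopulationProfile("dead", 188.0, 0.72, 0.9, 0.08, 185.0, 1.5, 0.85, 0.08),
        "sterile": PopulationProfile("sterile", 190.0, 1.1, 0.364, 0.08, 185.0, 1.5, 0.35, 0.08),
        "intermediate": PopulationProfile("intermediate", 192.0, 0.72, 0.9, 0.08, 185.0, 1.5, 0.88, 0.08),
    }


def default_config(chip_size_um: int = 80, seed: int = 0) -> GeneratorConfig:
    """Default experiment configuration for the given chip size.

    The 80 μm chip is the heat-inactivation/mixing validation setup; the
    120 μm chip is used for hydration monitoring and the genotype panel.
    """
    if chip_size_um == 80:
        populations = _profiles_80um()
        chip = ChipProfile(80, 0.35, 12, 0.07)
    elif chip_size_um == 120:
        populations = _profiles_120um()
        chip = ChipProfile(120, 0.7, 12, 0.05)
    else:
        raise ValueError("chip_size_um must be 80 or 120")
    fractions = {"viable": 0.45, "dead": 0.25, "sterile": 0.15, "intermediate": 0.15}
    return GeneratorConfig(
        populations=populations, class_fractions=fractions, chip=chip, seed=seed
    )


def _draw_class(
    profile: PopulationProfile,
    n: int,
    rng: np.random.Generator,
    trigger: float,
) -> dict[str, np.ndarray]:
    """Draw n events from one population; amplitudes truncated at trigger."""

    def trunc_amp(mean: float, sd: float) -> np.ndarray:
        a = (trigger - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    return {
        "phase8_deg": rng.normal(profile.phase8_mean, profile.phase8_sd, n),
        "amp8": trunc_amp(profile.amp8_mean, profile.amp8_sd),
        "phase2_deg": rng.normal(profile.phase2_mean, profile.phase2_sd, n),
        "amp2": trunc_amp(profile.amp2_mean, profile.amp2_sd),
    }


def _assemble(
    parts: list[tuple[str, dict[str, np.ndarray]]],
    rng: np.random.Generator,
    *,
    genotype: str,
    sample: str,
    replica: int,
    time_min: float,
) -> pd.DataFrame:
    """Stack per-class draws into one event table and shuffle row order."""
    frames = []
    for label, cols in parts:
        df = pd.DataFrame(cols)
        df["true_label"] = label
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.iloc[rng.permutation(len(out))].reset_index(drop=True)
    out.insert(0, "genotype", genotype)
    out.insert(1, "sample", sample)
    out.insert(2, "replica", replica)
    out.insert(3, "time_min", float(time_min))
    return out[EVENT_COLUMNS]


def sample_population(
    profile: PopulationProfile,
    n: int,
    seed: int | np.random.Generator = 0,
    *,
    chip: ChipProfile | None = None,
    genotype: str = "synthetic",
    sample: str = "S1",
    replica: int = 1,
    time_min: float = 0.0,
) -> pd.DataFrame:
    """Draw ``n`` events from a single population profile.

    Phases are Normal(mean, sd); amplitudes are Normal(mean, sd) truncated
    below at the chip trigger level.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chip = chip or ChipProfile()
    cols = _draw_class(profile, n, rng, chip.trigger_level)
    return _assemble(
        [(profile.label, cols)],
        rng,
        genotype=genotype,
        sample=sample,
        replica=replica,
        time_min=time_min,
    )


def _spawn_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one master seed (documented rule:
    ``SeedSequence(seed).spawn(n)`` in unit iteration order)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


DEFAULT_MIXING_RATIOS = ((1, 0), (3, 1), (1, 1), (1, 3), (0, 1))


def generate_mixing_series(
    config: GeneratorConfig | None = None,
    ratios: tuple[tuple[float, float], ...] = DEFAULT_MIXING_RATIOS,
    samples: int = 2,
    replicas: int = 3,
    events_per_replica: int = 20_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the untreated : heat-inactivated mixing validation series.

    Heat treatment converts viable and intermediate grains to the dead-class
    signature; sterile grains are unaffected and keep a constant fraction
    ``s`` across the series.  At untreated weight fraction ``r`` the class
    fractions are ``sterile = s``, ``viable = (1 − s)·r·v0`` and the rest
    dead, so the expected sterile-excluded viability is ``r·v0`` with
    ``v0 = config.mixing_untreated_viability``.

    Returns one tidy event table; each (ratio, sample, replica) group is one
    replica's 20 000-event table, tagged with ``nominal_viability_pct``.
    """
    config = config or default_config(80)
    if seed is None:
        seed = config.seed
    for u, t in ratios:
        if u < 0 or t < 0 or (u + t) == 0:
            raise ValueError(f"invalid ratio weights ({u}, {t})")
    v0 = config.mixing_untreated_viability
    s = config.mixing_sterile_fraction
    trigger = config.chip.trigger_level
    units = [
        (u, t, si, ri)
        for (u, t) in ratios
        for si in range(1, samples + 1)
        for ri in range(1, replicas + 1)
    ]
    streams = _spawn_streams(seed, len(units))
    frames = []
    for (u, t, si, ri), rng in zip(units, streams):
        r = u / (u + t)
        frac = {
            "sterile": s,
            "viable": (1 - s) * r * v0,
            "dead": (1 - s) * (1 - r * v0),
        }
        counts = rng.multinomial(events_per_replica, [frac[c] for c in ("viable", "dead", "sterile")])
        parts = [
            (label, _draw_class(config.populations[label], int(m), rng, trigger))
            for label, m in zip(("viable", "dead", "sterile"), counts)
            if m > 0
        ]
        df = _assemble(
            parts,
            rng,
            genotype="Camponica UNITO",
            sample=f"S{si}",
            replica=ri,
            time_min=0.0,
        )
        df["ratio_untreated"] = float(u)
        df["ratio_treated"] = float(t)
        df["nominal_viability_pct"] = 100.0 * r * v0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_hydration_course(
    config: GeneratorConfig | None = None,
    times: tuple[float, ...] = tuple(range(0, 421, 30)),
    events_per_step: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the pre-hydration monitoring course (one table per step).

    Per step ``t``: the dead-class phase mean follows the configured linear
    drift; the viable mean is fixed; each intermediate grain has converted
    with probability ``min(t / drift_duration, 1)`` — converted grains join
    the viable class with probability ``intermediate_recovery_fraction`` and
    otherwise the dead class (at the current dead phase); dead amplitude
    declines linearly at the configured rate.  ``true_label`` records the
    class a grain currently belongs to.
    """
    if len(times) == 0:
        raise ValueError("time grid must be non-empty")
    config = config or default_config(120)
    if seed is None:
        seed = config.seed
    hyd = config.hydration
    trigger = config.chip.trigger_level
    frac = config.class_fractions
    streams = _spawn_streams(seed, len(times))
    frames = []
    for t, rng in zip(times, streams):
        dead_mean = hyd.dead_mode_at(t)
        amp_drop = hyd.dead_amp_decline_rate * t
        dead_prof = replace(
            config.populations["dead"],
            phase8_mean=dead_mean,
            amp8_mean=max(config.populations["dead"].amp8_mean - amp_drop, trigger + 1e-6),
        )
        labels = ("viable", "dead", "sterile", "intermediate")
        counts = rng.multinomial(events_per_step, [frac.get(c, 0.0) for c in labels])
        n_via, n_dead, n_ster, n_int = (int(m) for m in counts)
        # intermediate conversion
        conv_p = min(t / hyd.drift_duration_min, 1.0) if hyd.drift_duration_min > 0 else 1.0
        n_conv = rng.binomial(n_int, conv_p)
        n_rec = rng.binomial(n_conv, hyd.intermediate_recovery_fraction)
        n_via += n_rec
        n_dead += n_conv - n_rec
        n_int -= n_conv
        parts = []
        for label, m, prof in (
            ("viable", n_via, config.populations["viable"]),
            ("dead", n_dead, dead_prof),
            ("sterile", n_ster, config.populations["sterile"]),
            ("intermediate", n_int, config.populations["intermediate"]),
        ):
            if m > 0:
                parts.append((label, _draw_class(prof, m, rng, trigger)))
        frames.append(
            _assemble(parts, rng, genotype="hydration", sample="S1", replica=1, time_min=t)
        )
    return pd.concat(frames, ignore_index=True)


def generate_buffer_stability(
    config: GeneratorConfig | None = None,
    rehydrated: bool = True,
    times: tuple[float, ...] = tuple(range(0, 91, 15)),
    samples: int = 9,
    events_per_sample: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate buffer-stability monitoring of (non-)rehydrated pollen.

    Rehydrated pollen keeps a constant viable fraction; without rehydration
    the viable fraction decays as ``exp(−λ t)`` (λ = ``buffer_decay_rate``
    per minute) and decayed grains acquire the dead-class signature.  The
    intermediate class is folded into the viable pool here: the experiment
    contrasts fully rehydrated against non-rehydrated material.
    """
    config = config or default_config(120)
    if seed is None:
        seed = config.seed
    lam = config.buffer_decay_rate
    trigger = config.chip.trigger_level
    f_via = config.class_fractions.get("viable", 0.0) + config.class_fractions.get(
        "intermediate", 0.0
    )
    f_dead = config.class_fractions.get("dead", 0.0)
    f_ster = config.class_fractions.get("sterile", 0.0)
    units = [(t, si) for t in times for si in range(1, samples + 1)]
    streams = _spawn_streams(seed, len(units))
    frames = []
    for (t, si), rng in zip(units, streams):
        survive = 1.0 if rehydrated else float(np.exp(-lam * t))
        probs = [f_via * survive, f_dead + f_via * (1 - survive), f_ster]
        counts = rng.multinomial(events_per_sample, probs)
        parts = [
            (label, _draw_class(config.populations[label], int(m), rng, trigger))
            for label, m in zip(("viable", "dead", "sterile"), counts)
            if m > 0
        ]
        df = _assemble(
            parts,
            rng,
            genotype="buffer-stability",
            sample=f"S{si}",
            replica=1,
            time_min=t,
        )
        df["rehydrated"] = bool(rehydrated)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


REQUIRED_PANEL_COLUMNS = ("genotype", "sterility_mean", "sterility_sd", "viability_mean")


def generate_genotype_panel(
    panel: pd.DataFrame,
    config: GeneratorConfig | None = None,
    replicas: int = 3,
    events_per_replica: int = 20_000,
    viable_size_coupling: float = 0.002,
    sterile_size_coupling: float = -0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the genotype screening panel from a reference sterility table.

    ``panel`` needs columns genotype, sterility_mean, sterility_sd and
    viability_mean (percent scale).  Per replica the sterile fraction is
    drawn Normal(mean, sd) clipped to [0, 100]; the non-sterile remainder is
    split between viable and dead so that expected viability matches the
    reference.  The viable-class 2 MHz amplitude mean is offset by
    ``viable_size_coupling · (sterility − panel mean sterility)`` (and the
    sterile class by ``sterile_size_coupling``), reproducing the observed
    trend that highly sterile genotypes shed larger viable and smaller
    sterile pollen.
    """
    for col in REQUIRED_PANEL_COLUMNS:
        if col not in panel.columns:
            raise ValueError(f"panel is missing required column {col!r}")
    config = config or default_config(120)
    if seed is None:
        seed = config.seed
    trigger = config.chip.trigger_level
    panel_mean_ster = float(panel["sterility_mean"].mean())
    units = [(row, ri) for _, row in panel.iterrows() for ri in range(1, replicas + 1)]
    streams = _spawn_streams(seed, len(units))
    frames = []
    for (row, ri), rng in zip(units, streams):
        s_mean, s_sd = float(row["sterility_mean"]), float(row["sterility_sd"])
        v_mean = float(row["viability_mean"])
        ster_pct = float(np.clip(rng.normal(s_mean, s_sd), 0.0, 100.0))
        # viable share of the non-sterile remainder, from the reference ratio
        if s_mean < 100.0:
            viable_given_alive = min(v_mean / (100.0 - s_mean), 1.0)
        else:
            viable_given_alive = 0.0
        f_ster = ster_pct / 100.0
        f_via = (1.0 - f_ster) * viable_given_alive
        f_dead = 1.0 - f_ster - f_via
        delta = s_mean - panel_mean_ster
        prof_via = replace(
            config.populations["viable"],
            amp2_mean=config.populations["viable"].amp2_mean + viable_size_coupling * delta,
        )
        prof_ster = replace(
            config.populations["sterile"],
            amp2_mean=max(
                config.populations["sterile"].amp2_mean + sterile_size_coupling * delta,
                trigger + 1e-6,
            ),
        )
        counts = rng.multinomial(events_per_replica, [f_via, f_dead, f_ster])
        parts = [
            (label, _draw_class(prof, int(m), rng, trigger))
            for label, m, prof in zip(
                ("viable", "dead", "sterile"),
                counts,
                (prof_via, config.populations["dead"], prof_ster),
            )
            if m > 0
        ]
        frames.append(
            _assemble(
                parts,
                rng,
                genotype=str(row["genotype"]),
                sample="S1",
                replica=ri,
                time_min=360.0,
            )
        )
    return pd.concat(frames, ignore_index=True)
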