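"""File formats: event-table CSV, gate JSON, config YAML, series CSV.

CSV is the exchange format throughout (matching how instrument exports are
distributed); units are fixed in the column names — ``phase2_deg``/``amp2``
and ``phase8_deg``/``amp8`` — to prevent unit drift.  Gate files are JSON,
one object per gate with ``label``, ``channel_mhz`` and ``vertices`` as
``[[phase_deg, amplitude], ...]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .gating import GateSet, PolygonGate
from .simulate import (
    ChipProfile,
    GeneratorConfig,
    HydrationParams,
    PopulationProfile,
    default_config,
)

__all__ = [
    "read_events",
    "write_events",
    "read_gates",
    "write_gates",
    "load_generator_config",
    "SchemaError",
]

REQUIRED_EVENT_COLUMNS = [
    "genotype",
    "sample",
    "replica",
    "time_min",
    "phase2_deg",
    "amp2",
    "phase8_deg",
    "amp8",
]


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


def read_events(path) -> pd.DataFrame:
    """Read an event-table CSV, validating the documented schema."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing event column(s) {missing}")
    return df


def write_events(df: pd.DataFrame, path, blinded: bool = False) -> None:
    """Write an event table; ``blinded`` drops the synthetic true_label."""
    out = df.drop(columns=["true_label"]) if blinded and "true_label" in df.columns else df
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_gates(path) -> GateSet:
    """Load a gate set from JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        gates_raw = payload["gates"]
        channel = payload.get("channel_mhz", 8.0)
        genotype = payload.get("genotype", "")
    else:
        gates_raw = payload
        channel = gates_raw[0].get("channel_mhz", 8.0) if gates_raw else 8.0
        genotype = ""
    try:
        gates = tuple(
            PolygonGate(g["label"], tuple((float(p), float(a)) for p, a in g["vertices"]))
            for g in gates_raw
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed gate file ({exc})") from exc
    return GateSet(gates, channel_mhz=channel, genotype=genotype)


def write_gates(gateset: GateSet, path) -> None:
    payload = {
        "channel_mhz": gateset.channel_mhz,
        "genotype": gateset.genotype,
        "gates": [
            {
                "label": g.label,
                "channel_mhz": gateset.channel_mhz,
                "vertices": [[float(p), float(a)] for p, a in g.vertices],
            }
            for g in gateset.gates
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_generator_config(path) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML file.

    The file mirrors the config dataclasses field-for-field; omitted
    sections fall back to the chip-size defaults.  Example::

        chip_size_um: 120
        seed: 7
        class_fractions: {viable: 0.45, dead: 0.25, sterile: 0.15, intermediate: 0.15}
        hydration:
          dead_mode_start: 192.0
          dead_mode_end: 188.0
        populations:
          viable: {phase8_mean: 198.0, phase8_sd: 1.2, ...}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_config(raw.get("chip_size_um", 80), seed=raw.get("seed", 0))
    populations = dict(base.populations)
    for label, fields in (raw.get("populations") or {}).items():
        ref = populations.get(label)
        merged = {**(ref.__dict__ if ref else {}), **fields, "label": label}
        populations[label] = PopulationProfile(**merged)
    hydration = HydrationParams(**{**base.hydration.__dict__, **(raw.get("hydration") or {})})
    chip_fields = {**base.chip.__dict__, **(raw.get("chip") or {})}
    return GeneratorConfig(
        populations=populations,
        class_fractions=raw.get("class_fractions", base.class_fractions),
        hydration=hydration,
        chip=ChipProfile(**chip_fields),
        buffer_decay_rate=raw.get("buffer_decay_rate", base.buffer_decay_rate),
        mixing_untreated_viability=raw.get(
            "mixing_untreated_viability", base.mixing_untreated_viability
        ),
        mixing_sterile_fraction=raw.get(
            "mixing_sterile_fraction", base.mixing_sterile_fraction
        ),
        seed=raw.get("seed", base.seed),
    )
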