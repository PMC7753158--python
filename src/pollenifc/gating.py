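"""Polygon gating of IFC events and population quantification.

Events are assigned to the sterile / dead / viable populations by membership
in polygon gates drawn in (phase, amplitude) space on one measurement
channel.  Gates are fixed per genotype and applied unchanged across time
steps.  Because the hand-drawn vendor-software gates are not portable, the
module supports both user-supplied polygons (JSON) and an automated
derivation: a two-stage univariate split that first isolates the
low-amplitude sterile population and then separates dead from viable by
phase.

Precedence is sterile → dead → viable (sterile is defined primarily by
amplitude, so it is tested first); boundary points count as inside, so no
event is silently lost to edge effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats as scipy_stats

from .clustering import ckmeans_1d

__all__ = [
    "PolygonGate",
    "GateSet",
    "PopulationStats",
    "point_in_gate",
    "assign_events",
    "derive_gates",
    "population_stats",
    "quantify_replicas",
    "viability_percent",
    "GATE_PRECEDENCE",
]

GATE_PRECEDENCE = ("sterile", "dead", "viable")


@dataclass(frozen=True)
class PolygonGate:
    """A named simple polygon in (phase°, amplitude) space."""

    label: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon gate needs at least 3 vertices")
        pts = np.asarray(self.vertices, dtype=float)
        u = pts[1:-1] - pts[0]
        v = pts[2:] - pts[0]
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        if np.all(np.abs(cross) < 1e-12):
            raise ValueError(f"gate {self.label!r} has collinear vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"gate {self.label!r} is not a simple polygon")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass(frozen=True)
class GateSet:
    """Ordered polygon gates for one genotype on one channel.

    Gates are evaluated in ``GATE_PRECEDENCE`` order and the first match
    wins; events matching no gate are labelled ``unclassified``.
    """

    gates: tuple[PolygonGate, ...]
    channel_mhz: float = 8.0
    genotype: str = ""

    def __post_init__(self) -> None:
        labels = [g.label for g in self.gates]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate gate labels in gate set")
        order = {lab: i for i, lab in enumerate(GATE_PRECEDENCE)}
        ranked = sorted(self.gates, key=lambda g: order.get(g.label, len(order)))
        object.__setattr__(self, "gates", tuple(ranked))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.gates)


def point_in_gate(phase, amplitude, gate: PolygonGate):
    """Membership of (phase, amplitude) points in a polygon gate.

    Boundary points count as inside.  Accepts scalars or arrays; returns a
    bool or boolean array.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    pts = shapely.points(phase.ravel(), amp.ravel())
    inside = shapely.covers(gate.polygon, pts)
    if phase.ndim == 0:
        return bool(inside[0])
    return inside.reshape(phase.shape)


def _channel_columns(channel_mhz: float) -> tuple[str, str]:
    ch = int(round(channel_mhz))
    return f"phase{ch}_deg", f"amp{ch}"


def assign_events(events: pd.DataFrame, gateset: GateSet) -> np.ndarray:
    """Label every event by the first matching gate in precedence order.

    Returns an object array of class labels aligned with ``events`` rows;
    events outside every gate are ``"unclassified"``.  Pure: identical
    inputs always give identical labels and the gate set is never mutated.
    """
    pcol, acol = _channel_columns(gateset.channel_mhz)
    for col in (pcol, acol):
        if col not in events.columns:
            raise ValueError(f"event table lacks column {col!r} for {gateset.channel_mhz} MHz gating")
    labels = np.full(len(events), "unclassified", dtype=object)
    unassigned = np.ones(len(events), dtype=bool)
    phase = events[pcol].to_numpy(dtype=float)
    amp = events[acol].to_numpy(dtype=float)
    for gate in gateset.gates:
        if not unassigned.any():
            break
        hit = point_in_gate(phase[unassigned], amp[unassigned], gate)
        idx = np.flatnonzero(unassigned)[hit]
        labels[idx] = gate.label
        unassigned[idx] = False
    return labels


def _rect(label: str, p_lo: float, p_hi: float, a_lo: float, a_hi: float) -> PolygonGate:
    return PolygonGate(label, ((p_lo, a_lo), (p_hi, a_lo), (p_hi, a_hi), (p_lo, a_hi)))


MAX_VALLEY_RATIO = 0.85


def _split_1d(values: np.ndarray, min_separation: float, max_points: int = 4096):
    """Optimal 2-cluster split of 1D values with a bimodality guard.

    Returns (threshold, separation): the threshold is the midpoint of the
    two cluster means — the nearest-centroid decision boundary of the
    optimal 1D k-means partition, which stays put when one population later
    drifts toward the boundary — and separation is the distance between the
    cluster means in pooled-sd units.  Returns (None, separation) for
    unimodal data, detected by two conditions: separation below
    ``min_separation``, or no real density valley between the cluster means
    (the k-means objective happily bisects a single Gaussian, so the kernel
    density at the boundary must fall below ``MAX_VALLEY_RATIO`` of the
    density at both cluster means).  Large inputs are thinned to
    ``max_points`` evenly spaced order statistics before the exact DP split
    (deterministic; preserves the split location).
    """
    values = np.sort(values)
    if values.size > max_points:
        values = values[np.linspace(0, values.size - 1, max_points).astype(int)]
    res = ckmeans_1d(values, 2)
    pooled = np.sqrt(res.total_withinss / max(len(values) - 2, 1))
    separation = (res.means[1] - res.means[0]) / max(pooled, 1e-12)
    if separation < min_separation:
        return None, float(separation)
    kde = scipy_stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(res.means[0], res.means[1], 128)
    density = kde(grid)
    valley = density[1:-1].min()
    if valley > MAX_VALLEY_RATIO * min(density[0], density[-1]):
        return None, float(separation)
    return float((res.means[0] + res.means[1]) / 2.0), float(separation)


def derive_gates(
    events: pd.DataFrame,
    channel_mhz: float = 8.0,
    min_separation: float = 2.0,
    margin: float = 0.05,
    genotype: str = "",
) -> GateSet:
    """Derive rectangular sterile/dead/viable gates from the data itself.

    Two-stage univariate split: (1) optimal 2-cluster k-means on amplitude
    isolates the low-amplitude sterile population, the gate boundary being
    the midpoint of the two cluster means (the k-means decision boundary);
    (2) among high-amplitude events, 2-cluster k-means on phase separates
    dead (low phase) from viable (high phase) the same way.  This keeps the
    dead gate roomy enough that a population drifting toward the boundary
    (the not-yet-hydrated dead cloud) stays inside its gate across a time
    course.  Thresholds become rectangles spanning the observed
    data range with 5 % margins.  If a split's cluster separation falls
    below ``min_separation`` pooled sds the data are treated as unimodal at
    that stage: a warning is emitted and fewer classes are gated.
    """
    pcol, acol = _channel_columns(channel_mhz)
    phase = events[pcol].to_numpy(dtype=float)
    amp = events[acol].to_numpy(dtype=float)
    if len(events) < 1000:
        warnings.warn(
            f"derive_gates on only {len(events)} events; thresholds may be unstable",
            stacklevel=2,
        )
    p_lo, p_hi = phase.min(), phase.max()
    a_lo, a_hi = amp.min(), amp.max()
    p_pad = margin * max(p_hi - p_lo, 1e-9)
    a_pad = margin * max(a_hi - a_lo, 1e-9)
    p_lo, p_hi = p_lo - p_pad, p_hi + p_pad
    a_lo, a_hi = a_lo - a_pad, a_hi + a_pad

    amp_cut, amp_sep = _split_1d(amp, min_separation)
    if amp_cut is None:
        warnings.warn(
            f"amplitude distribution looks unimodal (separation {amp_sep:.2f}); "
            "single-class gate set (all viable)",
            stacklevel=2,
        )
        return GateSet((_rect("viable", p_lo, p_hi, a_lo, a_hi),), channel_mhz, genotype)

    high = amp > amp_cut
    phase_cut, phase_sep = _split_1d(phase[high], min_separation)
    sterile = _rect("sterile", p_lo, p_hi, a_lo, amp_cut)
    if phase_cut is None:
        warnings.warn(
            f"phase distribution looks unimodal (separation {phase_sep:.2f}); "
            "no dead/viable distinction",
            stacklevel=2,
        )
        return GateSet(
            (sterile, _rect("viable", p_lo, p_hi, amp_cut, a_hi)), channel_mhz, genotype
        )
    return GateSet(
        (
            sterile,
            _rect("dead", p_lo, phase_cut, amp_cut, a_hi),
            _rect("viable", phase_cut, p_hi, amp_cut, a_hi),
        ),
        channel_mhz,
        genotype,
    )


@dataclass(frozen=True)
class PopulationStats:
    """Per-class counts, fractions and channel statistics of gated events.

    ``table`` has one row per class with columns count, fraction_pct (of
    classified events) and mean/sd of phase and amplitude on both channels.
    """

    table: pd.DataFrame
    unclassified: int
    total: int
    genotype: str = ""
    sample: str = ""
    replica: int = 0
    classes: tuple[str, ...] = field(default=GATE_PRECEDENCE)

    def count(self, label: str) -> int:
        if label in self.table.index:
            return int(self.table.loc[label, "count"])
        return 0

    def fraction_pct(self, label: str) -> float:
        if label in self.table.index:
            return float(self.table.loc[label, "fraction_pct"])
        return 0.0


def population_stats(events: pd.DataFrame, labels) -> PopulationStats:
    """Summarise gated events per class.

    Fractions are percentages of classified (non-``unclassified``) events
    and sum to 100 exactly; means/sds cover both channels where present.
    """
    labels = np.asarray(labels)
    if len(labels) != len(events):
        raise ValueError("labels not aligned with events")
    classified = labels != "unclassified"
    n_classified = int(classified.sum())
    rows = {}
    present = [lab for lab in GATE_PRECEDENCE if (labels == lab).any()]
    present += [
        lab
        for lab in pd.unique(labels[classified])
        if lab not in present
    ]
    for lab in present:
        mask = labels == lab
        row = {
            "count": int(mask.sum()),
            "fraction_pct": 100.0 * mask.sum() / n_classified if n_classified else 0.0,
        }
        for col in ("phase2_deg", "amp2", "phase8_deg", "amp8"):
            if col in events.columns:
                vals = events.loc[mask, col].to_numpy(dtype=float)
                row[f"{col}_mean"] = float(vals.mean()) if vals.size else np.nan
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rows[lab] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class"
    meta = {}
    for key in ("genotype", "sample", "replica"):
        if key in events.columns and len(events):
            vals = events[key].unique()
            if len(vals) == 1:
                meta[key] = vals[0]
    return PopulationStats(
        table=table,
        unclassified=int(len(events) - n_classified),
        total=int(len(events)),
        genotype=str(meta.get("genotype", "")),
        sample=str(meta.get("sample", "")),
        replica=int(meta.get("replica", 0)),
        classes=tuple(present),
    )


def quantify_replicas(
    events: pd.DataFrame,
    gates: GateSet | dict[str, GateSet] | None = None,
    channel_mhz: float = 8.0,
) -> pd.DataFrame:
    """Per-replica class percentages for a (multi-genotype) event table.

    Gates may be one :class:`GateSet` for all genotypes, a mapping genotype →
    gate set, the string ``"per-genotype"`` to derive gates from each
    genotype's own pooled events, or ``None`` (default) to derive one fixed
    gate set from the whole table.  Pooled derivation is the robust default:
    the population positions do not depend on the genotype, and deriving
    from a single genotype whose sterile or dead fraction is near zero is
    ill-posed (the optimal split then falls inside the dominant cloud).
    Returns one row per (genotype, sample, replica) with class percentages
    over all gated events (sterile in the denominator), sterile-excluded
    viability, and per-class 2 MHz amplitude means.
    """
    if gates is None:
        gates = derive_gates(events, channel_mhz)
    rows = []
    for genotype, geno_events in events.groupby("genotype", sort=False):
        if isinstance(gates, str) and gates == "per-genotype":
            gateset = derive_gates(geno_events, channel_mhz, genotype=str(genotype))
        elif isinstance(gates, GateSet):
            gateset = gates
        else:
            gateset = gates[str(genotype)]
        for (sample, replica), rep in geno_events.groupby(["sample", "replica"], sort=False):
            labels = assign_events(rep, gateset)
            st = population_stats(rep, labels)
            row = {
                "genotype": genotype,
                "sample": sample,
                "replica": replica,
                "n_events": st.total,
                "n_unclassified": st.unclassified,
                "pct_viable": st.fraction_pct("viable"),
                "pct_dead": st.fraction_pct("dead"),
                "pct_sterile": st.fraction_pct("sterile"),
                "viability_excl_sterile_pct": viability_percent(st, exclude_sterile=True),
            }
            for cls in GATE_PRECEDENCE:
                if cls in st.table.index and "amp2_mean" in st.table.columns:
                    row[f"amp2_{cls}"] = float(st.table.loc[cls, "amp2_mean"])
            rows.append(row)
    return pd.DataFrame(rows)


def viability_percent(stats: PopulationStats, exclude_sterile: bool = True) -> float:
    """Viable percentage of a gated replica.

    With ``exclude_sterile`` (the mixing-validation convention) the
    denominator is viable + dead; otherwise sterile is included (the
    genotype-panel convention, where viable + dead + sterile ≈ 100 %).
    Returns NaN if the denominator is empty.
    """
    v = stats.count("viable")
    d = stats.count("dead")
    s = stats.count("sterile")
    denom = v + d if exclude_sterile else v + d + s
    if denom == 0:
        warnings.warn("no events in the viability denominator", stacklevel=2)
        return float("nan")
    return 100.0 * v / denom
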