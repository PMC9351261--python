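"""Quality (primary) gating and hierarchical threshold gating trees.

The gated comparator model consumes counts of mutually exclusive cell types
produced by a hierarchy of threshold gates.  A :class:`GateNode` splits its
events on one channel at one or more thresholds; its children partition the
real line into half-open intervals, so sibling gates are mutually exclusive
and exhaustive by construction — every event reaches exactly one leaf and
leaf counts always sum to the gated event count.

Primary gating reproduces the standard quality sequence applied before any
analysis, shared by the continuous and gated arms: debris exclusion on a
rectangular FSC-A/SSC-A region, a singlet band on the FSC-H/FSC-A ratio,
exclusion of events absorbing the viability stain, and a CD45+ gate to keep
leukocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable
from .panel import ChannelPanel


class GatingError(ValueError):
    pass


@dataclass
class GateNode:
    """One node of a threshold gating tree.

    A leaf (no children) names a cell type.  An internal node carries a
    channel and ``k`` strictly increasing thresholds splitting events into
    ``k + 1`` children: child ``i`` receives values in ``[t_{i-1}, t_i)``
    (unbounded at the extremes), which makes siblings exclusive and
    exhaustive without a separate residual gate.
    """

    name: str
    channel: str | None = None
    thresholds: tuple[float, ...] = ()
    children: list["GateNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def validate(self) -> None:
        if self.is_leaf:
            return
        if self.channel is None:
            raise GatingError(f"internal gate {self.name!r} has no channel")
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or not np.all(np.diff(t) > 0):
            raise GatingError(
                f"gate {self.name!r}: thresholds must be non-empty and strictly increasing"
            )
        if len(self.children) != t.size + 1:
            raise GatingError(
                f"gate {self.name!r}: {t.size} thresholds require {t.size + 1} children, "
                f"got {len(self.children)}"
            )
        for child in self.children:
            child.validate()

    def leaves(self) -> list["GateNode"]:
        if self.is_leaf:
            return [self]
        out: list[GateNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if not self.is_leaf:
            d["channel"] = self.channel
            d["thresholds"] = [float(t) for t in self.thresholds]
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateNode":
        node = cls(
            name=d["name"],
            channel=d.get("channel"),
            thresholds=tuple(d.get("thresholds", ())),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )
        return node


@dataclass
class CellTypeCounts:
    """Counts per mutually exclusive leaf cell type for one individual."""

    individual_id: str
    leaf_names: list[str]
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.leaf_names):
            raise ValueError("counts/leaf_names length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if int(self.counts.sum()) != self.total:
            raise ValueError("counts do not sum to total gated events")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.leaf_names, name=self.individual_id)


def apply_gating_tree(events: EventTable, tree: GateNode) -> CellTypeCounts:
    """Assign every event to exactly one leaf of the tree and count them."""
    tree.validate()
    needed = {n.channel for n in _internal_nodes(tree)}
    missing = sorted(c for c in needed if c not in events.channels)
    if missing:
        raise GatingError(f"event table lacks gating channels: {missing}")

    leaf_names = tree.leaf_names()
    counts = dict.fromkeys(leaf_names, 0)
    _count_recursive(tree, events, np.ones(events.n_events, dtype=bool), counts)
    vec = np.array([counts[name] for name in leaf_names], dtype=np.int64)
    return CellTypeCounts(events.individual_id, leaf_names, vec, events.n_events)


def _internal_nodes(node: GateNode) -> list[GateNode]:
    if node.is_leaf:
        return []
    out = [node]
    for c in node.children:
        out.extend(_internal_nodes(c))
    return out


def _count_recursive(node: GateNode, events: EventTable, mask: np.ndarray,
                     counts: dict[str, int]) -> None:
    if node.is_leaf:
        counts[node.name] += int(mask.sum())
        return
    vals = events.column(node.channel)
    bucket = np.searchsorted(np.asarray(node.thresholds, dtype=float), vals, side="right")
    for i, child in enumerate(node.children):
        _count_recursive(child, events, mask & (bucket == i), counts)


def counts_to_frame(counts: list[CellTypeCounts],
                    proportions: bool = False) -> pd.DataFrame:
    """Individuals x leaf-types count matrix (the gated model's input).

    With ``proportions=True`` each row is divided by its total gated events;
    default is raw counts, mirroring the continuous model's raw section
    counts.
    """
    df = pd.DataFrame([c.as_series() for c in counts])
    df.index.name = "individual_id"
    if proportions:
        totals = df.sum(axis=1)
        df = df.div(totals.where(totals > 0, 1.0), axis=0)
    return df


# ---------------------------------------------------------------------------
# Primary (quality) gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimaryGateRules:
    """Rectangular/ratio rules for the four quality gates, applied in order.

    Defaults match the synthetic cohort's population layout; real panels
    tune these per experiment.
    """

    fsc_a_range: tuple[float, float] = (30_000.0, 250_000.0)
    ssc_a_range: tuple[float, float] = (0.0, 150_000.0)
    singlet_ratio_range: tuple[float, float] = (0.75, 1.25)  # FSC-H / FSC-A
    viability_max: float = 10_000.0   # events above absorb the live/dead stain
    cd45_min: float = 1_000.0
    cd45_marker: str = "CD45"

    @classmethod
    def permissive(cls) -> "PrimaryGateRules":
        return cls(fsc_a_range=(-np.inf, np.inf), ssc_a_range=(-np.inf, np.inf),
                   singlet_ratio_range=(-np.inf, np.inf), viability_max=np.inf,
                   cd45_min=-np.inf)

    @classmethod
    def blocking(cls) -> "PrimaryGateRules":
        return cls(fsc_a_range=(np.inf, np.inf), ssc_a_range=(np.inf, np.inf),
                   singlet_ratio_range=(np.inf, np.inf), viability_max=-np.inf,
                   cd45_min=np.inf)


def primary_gate(events: EventTable, panel: ChannelPanel,
                 rules: PrimaryGateRules = PrimaryGateRules()) -> EventTable:
    """Debris, singlet, viability and CD45+ gates, in that order.

    Returns the surviving events in acquisition order; the cumulative event
    counts after each gate are recorded in ``meta["primary_gate_counts"]``.
    """
    fsc_a_name, fsc_h_name, ssc_a_name = panel.scatter_channels
    for ch in (*panel.scatter_channels, panel.viability_channel):
        if ch not in events.channels:
            raise GatingError(f"missing required channel {ch!r}")
    cd45_channel = panel.channel_of(rules.cd45_marker)
    if cd45_channel not in events.channels:
        raise GatingError(f"missing required channel {cd45_channel!r}")

    fsc_a = events.column(fsc_a_name)
    fsc_h = events.column(fsc_h_name)
    ssc_a = events.column(ssc_a_name)

    keep = ((fsc_a >= rules.fsc_a_range[0]) & (fsc_a <= rules.fsc_a_range[1])
            & (ssc_a >= rules.ssc_a_range[0]) & (ssc_a <= rules.ssc_a_range[1]))
    stages = {"debris": int(keep.sum())}

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_a != 0, fsc_h / fsc_a, np.inf)
    keep &= (ratio >= rules.singlet_ratio_range[0]) & (ratio <= rules.singlet_ratio_range[1])
    stages["singlet"] = int(keep.sum())

    keep &= events.column(panel.viability_channel) <= rules.viability_max
    stages["viable"] = int(keep.sum())

    keep &= events.column(cd45_channel) >= rules.cd45_min
    stages["cd45_positive"] = int(keep.sum())

    return events.take(np.flatnonzero(keep), primary_gate_counts=stages)


# ---------------------------------------------------------------------------
# Synthetic gating-tree construction
# ---------------------------------------------------------------------------

def find_valley(values: np.ndarray, n_bins: int = 64) -> float:
    """Threshold at the deepest histogram valley between the two main modes.

    Falls back to the median when the smoothed histogram has fewer than two
    modes (unimodal channels).  Deterministic for a given sample.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = np.percentile(values, [1, 99])
    if not hi > lo:
        return float(values[0])
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    padded = np.concatenate(([-np.inf], smooth, [-np.inf]))
    peaks = [i for i in range(n_bins)
             if padded[i + 1] >= padded[i] and padded[i + 1] >= padded[i + 2]
             and smooth[i] > 0]
    if len(peaks) < 2:
        return float(np.median(values))
    top_two = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    left, right = top_two
    if right - left < 2:
        return float(np.median(values))
    valley = left + 1 + int(np.argmin(smooth[left + 1:right]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))


def default_synthetic_tree(panel: ChannelPanel, reference_events: list[EventTable],
                           n_leaves: int = 64,
                           max_events_per_individual: int = 2000) -> GateNode:
    """Balanced threshold tree over the panel's channels with valley thresholds.

    A stand-in for an expert gating strategy: leaves are split breadth-first,
    cycling through fluorescence channels (never reusing a channel along one
    path), each split thresholded at the pooled-cohort histogram valley of
    its channel.  ``n_leaves`` mutually exclusive cell types result; the same
    cohort yields identical thresholds on rerun.
    """
    if n_leaves < 2:
        raise GatingError("n_leaves must be >= 2")
    channels = panel.fluorescence_channels
    import math
    depth_needed = math.ceil(math.log2(n_leaves))
    if depth_needed > len(channels):
        raise GatingError(
            f"{n_leaves} leaves need depth {depth_needed} > {len(channels)} channels"
        )

    pooled = {
        ch: np.concatenate([ev.column(ch)[:max_events_per_individual]
                            for ev in reference_events])
        for ch in channels
    }
    thresholds = {ch: find_valley(pooled[ch]) for ch in channels}

    root = GateNode(name="root")
    frontier: list[tuple[GateNode, int]] = [(root, 0)]  # (leaf node, depth)
    count = 1
    serial = 0
    while count < n_leaves:
        node, depth = frontier.pop(0)
        ch = channels[depth % len(channels)]
        node.channel = ch
        node.thresholds = (thresholds[ch],)
        lo = GateNode(name=f"T{serial:03d}_{ch}-")
        hi = GateNode(name=f"T{serial:03d}_{ch}+")
        serial += 1
        node.children = [lo, hi]
        frontier.extend([(lo, depth + 1), (hi, depth + 1)])
        count += 1
    root.validate()
    return root
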