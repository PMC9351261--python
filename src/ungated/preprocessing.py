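"""Event-stream cleaning and the 102-section histogram featurization.

The ungated ("continuous") model consumes, per individual and per
fluorescence channel, a 102-section histogram of the channel's intensity
distribution:

* section 1 collects all values **below** the individual's per-channel 2.5th
  percentile,
* section 102 collects all values **above** the 97.5th percentile,
* sections 2..101 partition the interval [p2.5, p97.5] into 100 sections of
  equal width on the absolute RFU scale.

Percentiles use linear interpolation between order statistics (the "type 7"
convention, NumPy's default).  Interior sections are half-open ``[a, b)``
with the final interior section closed at the upper clip point, so counts
always sum to the number of binned events.

Before binning, each individual's event stream is cleaned in a fixed order:

1. trim — drop the first and last ``trim_fraction`` of events by acquisition
   order (acquisition drift is worst at the ends of a run);
2. outlier removal — drop every event with any fluorescence value below the
   RFU floor (default −50,000; a few extreme negative outliers would
   otherwise dominate a distribution-based model);
3. subsample — a seeded simple random sample of ``sample_size`` events
   (default 5,000) for equal representation across individuals; if fewer
   events survive, all are kept and a shortfall is flagged.

Outlier removal precedes subsampling so that the sample holds exactly
``sample_size`` clean events; percentiles are computed on the values that
are actually binned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable
from .panel import ChannelPanel


@dataclass(frozen=True)
class PreprocessConfig:
    trim_fraction: float = 0.10
    sample_size: int = 5000
    outlier_threshold: float = -50_000.0
    n_interior_sections: int = 100
    lower_percentile: float = 2.5
    upper_percentile: float = 97.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.n_interior_sections < 1:
            raise ValueError("n_interior_sections must be >= 1")
        if not (0.0 < self.lower_percentile < self.upper_percentile < 100.0):
            raise ValueError("need 0 < lower_percentile < upper_percentile < 100")
        if not np.isfinite(self.outlier_threshold):
            raise ValueError("outlier_threshold must be finite")

    @property
    def n_sections(self) -> int:
        """Total sections: interior plus the two clip sections."""
        return self.n_interior_sections + 2


@dataclass
class BinnedDistribution:
    """Per-individual, per-channel section counts and the edges behind them."""

    individual_id: str
    channel: str
    counts: np.ndarray   # (n_interior + 2,) non-negative ints
    edges: np.ndarray    # (n_interior + 1,) boundaries in RFU, ascending
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if self.counts.ndim != 1 or self.edges.ndim != 1:
            raise ValueError("counts and edges must be 1-D")
        if len(self.edges) != len(self.counts) - 1:
            raise ValueError("need exactly one more section than edges... "
                             f"got {len(self.counts)} sections, {len(self.edges)} edges")
        if (self.counts < 0).any():
            raise ValueError("negative section count")

    @property
    def n_sections(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def trim_events(events: EventTable, trim_fraction: float) -> EventTable:
    """Drop the first and last ``floor(trim_fraction * n)`` events."""
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    n = events.n_events
    k = int(np.floor(trim_fraction * n))
    return events.take(np.arange(k, n - k), trimmed=2 * k)


def remove_outlier_cells(events: EventTable, threshold: float,
                         fluorescence_channels: list[str] | None = None) -> EventTable:
    """Drop every event having any fluorescence value strictly below ``threshold``.

    When ``fluorescence_channels`` is None all channels are screened.
    """
    cols = (slice(None) if fluorescence_channels is None
            else [events.channels.index(c) for c in fluorescence_channels])
    bad = (events.values[:, cols] < threshold).any(axis=1)
    return events.take(np.flatnonzero(~bad), outliers_removed=int(bad.sum()))


def subsample_events(events: EventTable, sample_size: int, seed: int) -> EventTable:
    """Seeded simple random sample without replacement, acquisition order kept.

    If fewer than ``sample_size`` events are available, all are kept and
    ``meta["shortfall"]`` is set True on the result (auditable; never
    resampled with replacement).
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    n = events.n_events
    if n <= sample_size:
        return events.take(np.arange(n), shortfall=n < sample_size)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=sample_size, replace=False))
    return events.take(idx, shortfall=False)


def bin_channel(values: np.ndarray, config: PreprocessConfig,
                individual_id: str = "", channel: str = "") -> BinnedDistribution:
    """Bin one channel's values into ``n_interior_sections + 2`` sections.

    A degenerate channel (all values equal) cannot support an equal-width
    division; all mass is placed in the first interior section with the edges
    collapsed to the single value, and a warning is issued.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n < 1:
        raise ValueError("bin_channel needs at least one value")
    n_int = config.n_interior_sections

    lo, hi = np.percentile(values, [config.lower_percentile, config.upper_percentile])
    if not hi > lo:
        warnings.warn(
            f"degenerate channel {channel!r} for {individual_id!r}: "
            "clip points coincide; collapsing to a single section",
            stacklevel=2,
        )
        counts = np.zeros(n_int + 2, dtype=np.int64)
        counts[1] = n
        edges = np.full(n_int + 1, values[0])
        return BinnedDistribution(individual_id, channel, counts, edges, degenerate=True)

    below = int((values < lo).sum())
    above = int((values > hi).sum())
    interior = values[(values >= lo) & (values <= hi)]
    # np.histogram uses half-open bins with the last bin closed at `hi`,
    # exactly the documented closure rule.
    inner_counts, inner_edges = np.histogram(interior, bins=n_int, range=(lo, hi))
    counts = np.concatenate(([below], inner_counts, [above]))
    return BinnedDistribution(individual_id, channel, counts, inner_edges)


def preprocess_individual(events: EventTable, panel: ChannelPanel,
                          config: PreprocessConfig) -> list[BinnedDistribution]:
    """Full per-individual pipeline: trim → outlier removal → subsample → bin.

    Returns one :class:`BinnedDistribution` per fluorescence channel of the
    panel (23 for the default panel).  Deterministic given ``config.seed``.
    """
    missing = [c for c in panel.fluorescence_channels if c not in events.channels]
    if missing:
        raise KeyError(f"event table lacks panel channels: {missing}")
    cleaned = trim_events(events, config.trim_fraction)
    cleaned = remove_outlier_cells(cleaned, config.outlier_threshold,
                                   panel.fluorescence_channels)
    if cleaned.n_events == 0:
        raise ValueError(
            f"no events left for {events.individual_id!r} after cleaning"
        )
    # Per-individual sampling seed derived from the configured seed and a
    # stable hash of the id, so cohorts are reproducible file-by-file.
    sub_seed = np.random.SeedSequence(
        [config.seed, _stable_id_hash(events.individual_id)]
    ).generate_state(1)[0]
    sampled = subsample_events(cleaned, config.sample_size, int(sub_seed))
    return [
        bin_channel(sampled.column(ch), config,
                    individual_id=events.individual_id, channel=ch)
        for ch in panel.fluorescence_channels
    ]


def _stable_id_hash(individual_id: str) -> int:
    # Process-independent 32-bit hash (Python's hash() is salted per run).
    h = 2166136261
    for byte in individual_id.encode("utf-8"):
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# Cohort feature assembly / serialization
# ---------------------------------------------------------------------------

def preprocess_cohort(event_tables: list[EventTable], panel: ChannelPanel,
                      config: PreprocessConfig) -> dict[str, list[BinnedDistribution]]:
    """Preprocess every individual; returns id -> list of distributions."""
    return {ev.individual_id: preprocess_individual(ev, panel, config)
            for ev in event_tables}


def bins_to_wide(binned: dict[str, list[BinnedDistribution]]) -> pd.DataFrame:
    """Wide feature matrix: one row per individual, ``channel__s###`` columns.

    Column order is channel-major and section-ascending; this is the input
    layout of the continuous model (channels x sections, flattened).
    """
    rows = {}
    columns: list[str] | None = None
    for iid, dists in binned.items():
        cols, vals = [], []
        for d in dists:
            for s in range(d.n_sections):
                cols.append(f"{d.channel}__s{s + 1:03d}")
                vals.append(d.counts[s])
        if columns is None:
            columns = cols
        elif cols != columns:
            raise ValueError(f"inconsistent channel/section layout for {iid!r}")
        rows[iid] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=np.int64)
    df.index.name = "individual_id"
    return df


def bins_to_long(binned: dict[str, list[BinnedDistribution]]) -> pd.DataFrame:
    """Long export: individual, channel, section, count, lower/upper edge."""
    records = []
    for iid, dists in binned.items():
        for d in dists:
            edges = d.edges
            for s in range(d.n_sections):
                if s == 0:
                    lo, hi = -np.inf, edges[0]
                elif s == d.n_sections - 1:
                    lo, hi = edges[-1], np.inf
                else:
                    lo, hi = edges[s - 1], edges[s]
                records.append((iid, d.channel, s + 1, int(d.counts[s]), lo, hi))
    return pd.DataFrame.from_records(
        records,
        columns=["individual_id", "channel", "section", "count",
                 "lower_edge", "upper_edge"],
    )
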