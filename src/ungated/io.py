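"""Reading and writing the cytometry and tabular formats the pipeline touches.

Two in-memory contracts:

* :class:`EventTable` — one individual's raw events, a dense float matrix of
  shape (n_events, n_channels) in relative fluorescence units (RFU), with row
  order equal to acquisition order.  Every reader and writer preserves row
  order and values.
* :class:`OutcomeTable` — one record per individual with the declared health
  outcomes; rows with missing declared outcomes are flagged, never silently
  dropped (dropping is the evaluation stage's documented job).

CSV is the canonical interchange format.  FCS 3.0/3.1 is supported for both
reading and writing in its common profile: list mode (``$MODE=L``), float
data (``$DATATYPE`` F or D), little- or big-endian ``$BYTEORD``.  Channel
names are taken from ``$PnS`` (stain name) when present, falling back to
``$PnN`` — the usual cytometry convention — and the precedence is
overridable via ``name_keyword``.
"""

from __future__ import annotations

import io as _stdio
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


@dataclass
class EventTable:
    """One individual's cytometry events, rows in acquisition order."""

    individual_id: str
    channels: list[str]
    values: np.ndarray  # (n_events, n_channels), float64, RFU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} columns vs {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate channel names")
        if np.isnan(self.values).any():
            raise FormatError("missing values in event matrix")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        try:
            j = self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in event table") from None
        return self.values[:, j]

    def take(self, row_indices: np.ndarray, **meta) -> "EventTable":
        """New table keeping the given rows (acquisition order preserved)."""
        idx = np.asarray(row_indices)
        return EventTable(
            individual_id=self.individual_id,
            channels=list(self.channels),
            values=self.values[idx],
            meta={**self.meta, **meta},
        )


# ---------------------------------------------------------------------------
# CSV events
# ---------------------------------------------------------------------------

def write_events_csv(events: EventTable, path: str | Path) -> Path:
    """Write events as CSV: header = channel names, one row per event."""
    path = Path(path)
    df = pd.DataFrame(events.values, columns=events.channels)
    df.to_csv(path, index=False)
    return path


def _read_events_csv(path: Path, individual_id: str) -> EventTable:
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: CSV has a header but no event rows")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: CSV has no columns")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values in event matrix") from exc
    return EventTable(individual_id=individual_id, channels=list(df.columns), values=values)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1
# ---------------------------------------------------------------------------

_FCS_VERSIONS = (b"FCS3.0", b"FCS3.1")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of tokens")
    keywords: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", errors="replace").strip().upper()
        keywords[key] = parts[i + 1].decode("utf-8", errors="replace").strip()
    return keywords


def read_fcs(path: str | Path, individual_id: str | None = None,
             name_keyword: str = "S") -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file with float or double data.

    ``name_keyword`` selects the channel-name precedence: ``"S"`` prefers the
    stain name ``$PnS`` over the detector name ``$PnN`` (default), ``"N"``
    inverts it.
    """
    path = Path(path)
    raw = path.read_bytes()
    if raw[:6] not in _FCS_VERSIONS:
        raise FormatError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header offsets") from exc
    kw = _parse_text_segment(raw[text_start:text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if data_start == 0 or data_end == 0:
        raise FormatError(f"{path}: no DATA segment offsets")

    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list mode ($MODE=L) is supported")
    datatype = kw.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D"):
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r} (need F or D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    names: list[str] = []
    primary, fallback = ("S", "N") if name_keyword.upper() == "S" else ("N", "S")
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}{primary}") or kw.get(f"$P{i}{fallback}")
        if not name:
            raise FormatError(f"{path}: parameter {i} has neither $P{i}N nor $P{i}S")
        names.append(name)
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate channel names")

    itemsize = 4 if datatype == "F" else 8
    expected = n_par * n_tot * itemsize
    blob = raw[data_start:data_end + 1]
    if len(blob) < expected:
        raise FormatError(f"{path}: DATA segment shorter than $PAR*$TOT values")
    dtype = np.dtype(f"{endian}f{itemsize}")
    values = np.frombuffer(blob[:expected], dtype=dtype).reshape(n_tot, n_par)
    return EventTable(
        individual_id=individual_id or path.stem,
        channels=names,
        values=values.astype(np.float64),
    )


def write_fcs(events: EventTable, path: str | Path) -> Path:
    """Write events as FCS 3.1, list mode, little-endian float32."""
    path = Path(path)
    n_tot, n_par = events.values.shape
    delim = "/"
    pairs = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(events.channels, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}S"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = "262144"

    data = events.values.astype("<f4").tobytes()
    # The TEXT segment must carry its own data offsets; sizes of the offset
    # strings feed back into the segment length, so iterate to a fixed point.
    begin_data, end_data = 0, 0
    for _ in range(4):
        pairs["$BEGINDATA"] = str(begin_data)
        pairs["$ENDDATA"] = str(end_data)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
        text_start = 58  # header is 58 bytes: version + 4 spaces + 6 offsets
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    header = b"FCS3.1    " + (
        f"{text_start:8d}{text_end:8d}{begin_data:8d}{end_data:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == 58
    path.write_bytes(header + text.encode("utf-8") + data)
    return path


def read_events(path: str | Path, format: str | None = None,
                individual_id: str | None = None, name_keyword: str = "S") -> EventTable:
    """Read an event table from CSV or FCS; format inferred from suffix if None."""
    path = Path(path)
    fmt = (format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")).lower()
    if fmt == "csv":
        return _read_events_csv(path, individual_id or path.stem)
    if fmt == "fcs":
        return read_fcs(path, individual_id=individual_id, name_keyword=name_keyword)
    raise ValueError(f"unknown event format {fmt!r}")


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeTable:
    """Per-individual outcome records; missing values flagged, not dropped."""

    data: pd.DataFrame  # index: individual id (string); columns: outcomes

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate individual ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def complete_mask(self) -> pd.Series:
        """True for individuals with no missing declared outcome."""
        return ~self.data.isna().any(axis=1)

    @property
    def incomplete_ids(self) -> list[str]:
        return list(self.data.index[~self.complete_mask])

    def complete_cases(self) -> "OutcomeTable":
        return OutcomeTable(self.data.loc[self.complete_mask].copy())

    def reconcile(self, event_ids: list[str]) -> dict[str, list[str]]:
        """Cross-check outcome ids against available event tables.

        Returns a report with ids lacking events and events lacking outcomes;
        neither set is silently discarded.
        """
        ev = set(event_ids)
        out = set(self.data.index)
        return {
            "outcomes_without_events": sorted(out - ev),
            "events_without_outcomes": sorted(ev - out),
        }


def read_outcomes(path: str | Path, id_column: str = "individual_id") -> OutcomeTable:
    path = Path(path)
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise FormatError(f"{path}: missing id column {id_column!r}")
    df[id_column] = df[id_column].astype(str)
    df = df.set_index(id_column)
    return OutcomeTable(df)


def write_outcomes(outcomes: OutcomeTable, path: str | Path,
                   id_column: str = "individual_id") -> Path:
    path = Path(path)
    outcomes.data.to_csv(path, index_label=id_column)
    return path
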