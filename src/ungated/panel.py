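"""Surface-marker panel: 27 markers multiplexed onto 23 fluorescence channels.

Four marker pairs sit on mutually exclusive cell types and therefore share a
fluorescence channel, a standard panel-design trick: CD19 & Pan-GDT,
TCRVg1 & TCRVa7.2, CD8 & CD14, and TCRVg2 & IgD.  In addition to the
fluorescence channels every event carries three scatter channels
(FSC-A, FSC-H, SSC-A) used for debris/doublet quality gating, and a viability
(live/dead stain) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The 27 surface markers of the SLAS-2 aging-cohort panel.
DEFAULT_MARKERS: tuple[str, ...] = (
    "Slan", "CD19", "Pan-GDT", "TCRVg1", "TCRVa7.2", "CD45RO", "CD127",
    "CD56", "HLADR", "CCR6", "CD45", "CRTH2", "CD34", "CD38", "CD57",
    "CD25", "CD16", "CD123", "CD27", "CD3", "CD8", "CD14", "CXCR3",
    "TCRVg2", "IgD", "CD4", "CD161",
)

#: Marker pairs multiplexed onto a single channel (mutually exclusive lineages).
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("CD19", "Pan-GDT"),
    ("TCRVg1", "TCRVa7.2"),
    ("CD8", "CD14"),
    ("TCRVg2", "IgD"),
)

SCATTER_CHANNELS: tuple[str, str, str] = ("FSC-A", "FSC-H", "SSC-A")
VIABILITY_CHANNEL: str = "LiveDead"


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class ChannelPanel:
    """Assignment of markers to cytometer channels.

    Parameters
    ----------
    markers
        All surface markers in the panel.
    channel_map
        Mapping marker name -> fluorescence channel name.  Paired markers map
        to the same channel; no channel carries more than two markers.
    scatter_channels
        Forward/side scatter channel names, order (FSC-A, FSC-H, SSC-A).
    viability_channel
        Name of the live/dead stain channel.
    """

    markers: tuple[str, ...]
    channel_map: dict[str, str]
    scatter_channels: tuple[str, ...] = SCATTER_CHANNELS
    viability_channel: str = VIABILITY_CHANNEL

    def __post_init__(self) -> None:
        missing = [m for m in self.markers if m not in self.channel_map]
        if missing:
            raise PanelError(f"markers without a channel assignment: {missing}")
        counts: dict[str, int] = {}
        for marker in self.markers:
            ch = self.channel_map[marker]
            counts[ch] = counts.get(ch, 0) + 1
        overloaded = [ch for ch, k in counts.items() if k > 2]
        if overloaded:
            raise PanelError(f"channels carrying more than two markers: {overloaded}")
        n_pairs = sum(1 for k in counts.values() if k == 2)
        if len(counts) != len(self.markers) - n_pairs:
            raise PanelError("channel count inconsistent with pairing")

    @property
    def fluorescence_channels(self) -> list[str]:
        """Distinct fluorescence channel names, in first-marker order."""
        seen: list[str] = []
        for marker in self.markers:
            ch = self.channel_map[marker]
            if ch not in seen:
                seen.append(ch)
        return seen

    @property
    def all_channels(self) -> list[str]:
        """Scatter + viability + fluorescence channels, the full event layout."""
        return [*self.scatter_channels, self.viability_channel, *self.fluorescence_channels]

    @property
    def n_fluorescence(self) -> int:
        return len(self.fluorescence_channels)

    def channel_of(self, marker: str) -> str:
        try:
            return self.channel_map[marker]
        except KeyError:
            raise PanelError(f"unknown marker {marker!r}") from None


def default_panel() -> ChannelPanel:
    """The 27-marker / 23-channel panel with the four stated co-channel pairs.

    Shared channels are named ``"A|B"`` after the two markers they carry;
    single-marker channels are named after their marker.
    """
    pair_channel = {}
    for a, b in DEFAULT_PAIRS:
        name = f"{a}|{b}"
        pair_channel[a] = name
        pair_channel[b] = name
    channel_map = {m: pair_channel.get(m, m) for m in DEFAULT_MARKERS}
    return ChannelPanel(markers=DEFAULT_MARKERS, channel_map=channel_map)
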