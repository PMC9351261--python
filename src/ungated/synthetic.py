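"""Synthetic cytometry cohorts with known ground truth.

Real per-individual cytometry event files for the SLAS-2 aging cohort are not
publicly deposited, so every downstream stage is exercised on simulated
cohorts that emulate the statistical structure the analysis assumes:

* ~567 individuals, thousands to hundreds of thousands of events each;
* 27 surface markers multiplexed on 23 fluorescence channels, with scatter
  (FSC-A/FSC-H/SSC-A) and viability channels for quality gating;
* per-channel intensity distributions that are two-component location-scale
  mixtures on the raw RFU scale — clearly bimodal for lineage markers such
  as CD3, closer to a single normal for gradient markers such as CD161;
* a scalar latent health state ``z`` per individual (think "immune age")
  that perturbs the mixtures, either by shifting mixing weights (cell-type
  proportions — visible to gated counts) or by shifting the positive
  component's mean (within-gate intensity — invisible to counts by
  construction, the scenario the ungated model exists for);
* nuisance structure: debris, doublets and dead cells at configurable
  fractions, rare extreme negative outliers below −50,000 RFU, and a smooth
  multiplicative acquisition drift over event order;
* an outcome table emulating 20 health measures plus one negative-control
  outcome generated from an independent random stream.

Identical seeds yield bit-identical cohorts.  The generator's defaults are
the study conditions; scenario builders (e.g.
:func:`intensity_shift_channel_models`) construct cohorts for specific
hypotheses without touching the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .gating import GateNode, CellTypeCounts, apply_gating_tree
from .io import EventTable, OutcomeTable
from .panel import ChannelPanel, default_panel

EVENT_CLEAN, EVENT_DEBRIS, EVENT_DOUBLET, EVENT_DEAD = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# Channel intensity models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelModel:
    """Generative model for one fluorescence channel.

    A two-component normal mixture on the raw RFU scale; a unimodal channel
    is the special case ``base_weights=(0, 1)``.  ``signal`` routes the
    latent state ``z`` into the channel: ``"weight"`` moves the positive
    mixing weight on the logit scale, ``"mean"`` scales the positive
    component's mean, ``"none"`` leaves the channel uninformative.
    """

    base_weights: tuple[float, float] = (0.45, 0.55)
    base_means: tuple[float, float] = (500.0, 30_000.0)
    base_sds: tuple[float, float] = (300.0, 5_000.0)
    signal: str = "none"           # none | weight | mean
    effect: float = 0.0            # per-unit-z effect size

    def mixture_for(self, z: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.asarray(self.base_weights, dtype=float)
        means = np.asarray(self.base_means, dtype=float)
        sds = np.asarray(self.base_sds, dtype=float)
        if self.signal == "weight":
            # shift the positive weight on the logit scale, keep it in (0,1)
            w_pos = float(expit(logit(np.clip(w[1], 1e-6, 1 - 1e-6)) + self.effect * z))
            w = np.array([1.0 - w_pos, w_pos])
        elif self.signal == "mean":
            means = means.copy()
            means[1] = means[1] * (1.0 + self.effect * z)
        elif self.signal != "none":
            raise ValueError(f"unknown signal kind {self.signal!r}")
        return w, means, sds


def default_channel_models(panel: ChannelPanel) -> dict[str, ChannelModel]:
    """Mixed cohort: some weight-signal, some mean-signal, some silent channels.

    Lineage-marker channels (CD3, CD4, the CD8|CD14 and CD19|Pan-GDT pairs,
    CD45RO, CD27, CD56, HLADR, CD38, IgD|TCRVg2) are bimodal; the rest are
    unimodal gradients.  CD45 is uniformly high so the CD45+ quality gate
    keeps leukocytes.
    """
    bimodal_markers = {"CD3", "CD4", "CD8", "CD19", "CD45RO", "CD27",
                       "CD56", "HLADR", "CD38", "IgD"}
    weight_markers = {"CD45RO", "CD27", "CD8"}      # proportion shifts with z
    mean_markers = {"CD3", "CD38", "CD161"}         # intensity shifts with z

    models: dict[str, ChannelModel] = {}
    for ch in panel.fluorescence_channels:
        carried = [m for m in panel.markers if panel.channel_map[m] == ch]
        if "CD45" in carried:
            models[ch] = ChannelModel(base_weights=(0.0, 1.0),
                                      base_means=(500.0, 50_000.0),
                                      base_sds=(300.0, 8_000.0))
            continue
        bimodal = any(m in bimodal_markers for m in carried)
        if any(m in weight_markers for m in carried):
            signal, effect = "weight", 0.30
        elif any(m in mean_markers for m in carried):
            signal, effect = "mean", 0.08
        else:
            signal, effect = "none", 0.0
        if bimodal:
            models[ch] = ChannelModel(signal=signal, effect=effect)
        else:
            models[ch] = ChannelModel(base_weights=(0.0, 1.0),
                                      base_means=(0.0, 8_000.0),
                                      base_sds=(1.0, 3_000.0),
                                      signal=signal, effect=effect)
    return models


def intensity_shift_channel_models(panel: ChannelPanel, n_signal: int = 8,
                                   effect: float = 0.10) -> dict[str, ChannelModel]:
    """Scenario: all latent signal in within-population intensity shifts.

    Mixing weights are held fixed for every channel and the signal channels
    are widely separated bimodal mixtures whose *positive-component mean*
    moves with ``z``: any threshold placed at the mixture valley sees the
    same below/above counts regardless of ``z`` (the moving mass stays
    several SDs above the valley), so gated counts carry no information
    about the latent state by construction; only positions within the
    positive population move.  This is the cohort on which a counts-based
    model cannot beat the mean predictor while a distribution-based model
    can.
    """
    models = default_channel_models(panel)
    signal_channels = [ch for ch in panel.fluorescence_channels
                       if "CD45" not in ch][:n_signal]
    for ch, model in models.items():
        if ch in signal_channels:
            models[ch] = ChannelModel(base_weights=(0.45, 0.55),
                                      base_means=(500.0, 30_000.0),
                                      base_sds=(300.0, 4_000.0),
                                      signal="mean", effect=effect)
        else:
            models[ch] = replace(model, signal="none", effect=0.0)
    return models


# ---------------------------------------------------------------------------
# Outcome models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """One emulated health measure linked (or not) to the latent state.

    ``kind``: continuous | ordinal | binary.  Continuous and ordinal
    outcomes follow ``mean_target + coef * z + noise``; ordinal values are
    rounded and clipped to ``levels``.  Binary outcomes threshold a latent
    probit risk ``coef * z + noise`` at the quantile matching
    ``prevalence``.  ``control=True`` marks a negative control generated
    from an independent stream, ignoring ``z`` entirely.
    """

    name: str
    kind: str = "continuous"
    coef: float = 0.0
    noise_sd: float = 1.0
    mean_target: float = 0.0
    levels: tuple[float, float] = (-np.inf, np.inf)
    prevalence: float = 0.5
    control: bool = False

    def realize(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = len(z)
        noise = rng.normal(0.0, self.noise_sd, size=n) if self.noise_sd > 0 else np.zeros(n)
        if self.control:
            z = np.zeros(n)
        if self.kind == "continuous":
            return self.mean_target + self.coef * z + noise
        if self.kind == "ordinal":
            raw = self.mean_target + self.coef * z + noise
            return np.clip(np.round(raw), self.levels[0], self.levels[1])
        if self.kind == "binary":
            scale = float(np.hypot(self.coef, self.noise_sd))
            tau = norm.ppf(1.0 - self.prevalence) * (scale if scale > 0 else 1.0)
            return (self.coef * z + noise > tau).astype(float)
        raise ValueError(f"unknown outcome kind {self.kind!r}")


def default_outcome_specs() -> list[OutcomeSpec]:
    """Twenty health measures plus the negative control, with cohort means
    emulating an aging cohort (age ~67, MMSE ~28, mostly low-prevalence
    dichotomies)."""
    binaries = [
        ("Mortality", 0.058), ("High blood pressure", 0.432),
        ("High cholesterol", 0.464), ("Diabetes", 0.136), ("Stroke", 0.040),
        ("Heart attack", 0.053), ("Atrial fibrillation", 0.034),
        ("Eye problem", 0.301), ("Asthma", 0.049), ("Arthritis", 0.141),
        ("Osteoporosis", 0.049), ("Gastrointestinal problem", 0.088),
        ("Thyroid problem", 0.049), ("Cancer", 0.034), ("Depression", 0.032),
    ]
    specs = [
        OutcomeSpec("Age", "continuous", coef=6.0, noise_sd=4.5, mean_target=67.1),
        OutcomeSpec("Self-assessed Health", "ordinal", coef=0.5, noise_sd=0.6,
                    mean_target=3.07, levels=(1, 5)),
        OutcomeSpec("Frailty", "ordinal", coef=0.5, noise_sd=0.5,
                    mean_target=0.83, levels=(0, 5)),
        OutcomeSpec("MMSE", "ordinal", coef=-1.5, noise_sd=2.3,
                    mean_target=27.8, levels=(0, 30)),
        OutcomeSpec("Comorbidity", "ordinal", coef=0.8, noise_sd=1.3,
                    mean_target=2.4, levels=(0, 23)),
    ]
    specs += [OutcomeSpec(name, "binary", coef=0.6, noise_sd=1.0, prevalence=p)
              for name, p in binaries]
    specs.append(OutcomeSpec("Religion", "ordinal", coef=0.0, noise_sd=0.9,
                             mean_target=2.26, levels=(1, 4), control=True))
    return specs


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 567
    n_events_per_individual: int = 20_000
    panel: ChannelPanel = field(default_factory=default_panel)
    seed: int = 0
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    dead_fraction: float = 0.05
    outlier_rate: float = 0.001
    drift_amplitude: float = 0.05
    channel_models: dict[str, ChannelModel] | None = None
    outcome_specs: tuple[OutcomeSpec, ...] = field(
        default_factory=lambda: tuple(default_outcome_specs()))

    def __post_init__(self) -> None:
        props = {"debris_fraction": self.debris_fraction,
                 "doublet_fraction": self.doublet_fraction,
                 "dead_fraction": self.dead_fraction,
                 "outlier_rate": self.outlier_rate}
        for name, p in props.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.debris_fraction + self.doublet_fraction + self.dead_fraction >= 1.0:
            raise ValueError("debris + doublet + dead fractions must sum below 1")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_events_per_individual < 1:
            raise ValueError("n_events_per_individual must be >= 1")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")

    def resolved_channel_models(self) -> dict[str, ChannelModel]:
        return (dict(self.channel_models) if self.channel_models is not None
                else default_channel_models(self.panel))


@dataclass
class LatentState:
    """Per-individual latent health state and the mixtures it induces."""

    individual_id: str
    z: float
    # channel -> (weights, means, sds); weights sum to 1
    mixtures: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for ch, (w, _, _) in self.mixtures.items():
            if not np.isclose(w.sum(), 1.0):
                raise ValueError(f"mixture weights for {ch!r} must sum to 1")


def derive_latent(individual_id: str, z: float,
                  channel_models: dict[str, ChannelModel]) -> LatentState:
    return LatentState(
        individual_id=individual_id, z=z,
        mixtures={ch: m.mixture_for(z) for ch, m in channel_models.items()},
    )


# ---------------------------------------------------------------------------
# Event generation
# ---------------------------------------------------------------------------

def generate_events_for_individual(latent: LatentState, config: CohortConfig,
                                   rng: np.random.Generator | None = None) -> EventTable:
    """Draw one individual's event table from their latent mixtures.

    Events are i.i.d. draws tagged as clean/debris/doublet/dead, then
    acquisition drift multiplies fluorescence intensities by a linear ramp
    ``1 ± drift_amplitude`` over event order, and a fraction
    ``outlier_rate`` of events get one random fluorescence channel pushed
    below −50,000 RFU.  Ground-truth labels land in ``meta``:
    ``event_class`` (0 clean, 1 debris, 2 doublet, 3 dead),
    ``outlier_channel`` (column index or −1) and ``positive_counts`` (clean
    events drawn from the positive component, per channel).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.panel
    n = config.n_events_per_individual
    fluor = panel.fluorescence_channels
    missing = [ch for ch in fluor if ch not in latent.mixtures]
    if missing:
        raise ValueError(f"latent state lacks channels: {missing}")

    probs = np.array([
        1.0 - config.debris_fraction - config.doublet_fraction - config.dead_fraction,
        config.debris_fraction, config.doublet_fraction, config.dead_fraction,
    ])
    event_class = rng.choice(4, size=n, p=probs)
    clean_like = event_class != EVENT_DEBRIS  # doublets/dead still stain

    # scatter channels
    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc_a = np.empty(n)
    for cls, (mu_a, sd_a, ratio_mu, ratio_sd, mu_s, sd_s) in {
        EVENT_CLEAN: (100_000, 20_000, 1.00, 0.03, 60_000, 20_000),
        EVENT_DEBRIS: (15_000, 5_000, 1.00, 0.10, 20_000, 10_000),
        EVENT_DOUBLET: (180_000, 20_000, 0.55, 0.05, 80_000, 20_000),
        EVENT_DEAD: (100_000, 20_000, 1.00, 0.03, 60_000, 20_000),
    }.items():
        m = event_class == cls
        k = int(m.sum())
        fsc_a[m] = rng.normal(mu_a, sd_a, size=k)
        fsc_h[m] = fsc_a[m] * rng.normal(ratio_mu, ratio_sd, size=k)
        ssc_a[m] = rng.normal(mu_s, sd_s, size=k)

    viability = np.where(event_class == EVENT_DEAD,
                         rng.normal(30_000, 5_000, size=n),
                         rng.normal(2_000, 1_000, size=n))

    columns = {panel.scatter_channels[0]: fsc_a,
               panel.scatter_channels[1]: fsc_h,
               panel.scatter_channels[2]: ssc_a,
               panel.viability_channel: viability}

    positive_counts: dict[str, int] = {}
    for ch in fluor:
        w, means, sds = latent.mixtures[ch]
        comp = rng.choice(len(w), size=n, p=w)
        vals = rng.normal(means[comp], sds[comp])
        # doublets carry roughly double signal; debris barely stains
        vals = np.where(event_class == EVENT_DOUBLET, 1.8 * vals, vals)
        debris_mask = event_class == EVENT_DEBRIS
        vals = np.where(debris_mask, rng.normal(200, 200, size=n), vals)
        columns[ch] = vals
        positive_counts[ch] = int(((comp == len(w) - 1) & (event_class == EVENT_CLEAN)).sum())

    values = np.column_stack([columns[ch] for ch in panel.all_channels])

    # acquisition drift: smooth multiplicative ramp over event order
    if config.drift_amplitude > 0 and n > 1:
        ramp = 1.0 + config.drift_amplitude * np.linspace(-1.0, 1.0, n)
        fluor_cols = [panel.all_channels.index(ch) for ch in fluor]
        values[:, fluor_cols] *= ramp[:, None]

    # extreme negative outliers on one random fluorescence channel
    outlier_channel = np.full(n, -1, dtype=np.int64)
    if config.outlier_rate > 0:
        hit = rng.random(n) < config.outlier_rate
        k = int(hit.sum())
        if k:
            cols = rng.integers(0, len(fluor), size=k)
            col_idx = np.array([panel.all_channels.index(ch) for ch in fluor])[cols]
            values[np.flatnonzero(hit), col_idx] = (
                -50_000.0 - 1.0 - rng.exponential(10_000.0, size=k))
            outlier_channel[hit] = col_idx

    return EventTable(
        individual_id=latent.individual_id,
        channels=list(panel.all_channels),
        values=values,
        meta={"event_class": event_class, "outlier_channel": outlier_channel,
              "positive_counts": positive_counts, "z": latent.z},
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Every latent draw behind a synthetic cohort, for recovery tests."""

    z: pd.Series                      # individual -> latent state
    latents: dict[str, LatentState]
    channel_models: dict[str, ChannelModel]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z": self.z})
        df.index.name = "individual_id"
        return df


def generate_cohort(config: CohortConfig) -> tuple[list[EventTable], OutcomeTable, GroundTruth]:
    """Generate a full cohort: event tables, outcome table, ground truth.

    Individual ids are ``S0001..SNNNN``.  Outcomes and the negative control
    are drawn from random streams independent of the event streams; the
    control's stream is additionally independent of ``z``.
    """
    ss = np.random.SeedSequence(config.seed)
    # one child stream per individual + one for z + one for outcomes + control
    children = ss.spawn(config.n_individuals + 3)
    z_rng = np.random.default_rng(children[-3])
    outcome_rng = np.random.default_rng(children[-2])
    control_rng = np.random.default_rng(children[-1])

    n = config.n_individuals
    ids = [f"S{i + 1:04d}" for i in range(n)]
    z = z_rng.standard_normal(n)
    models = config.resolved_channel_models()

    tables: list[EventTable] = []
    latents: dict[str, LatentState] = {}
    for i, iid in enumerate(ids):
        latent = derive_latent(iid, float(z[i]), models)
        latents[iid] = latent
        rng = np.random.default_rng(children[i])
        tables.append(generate_events_for_individual(latent, config, rng))

    data = {}
    for spec in config.outcome_specs:
        rng = control_rng if spec.control else outcome_rng
        data[spec.name] = spec.realize(z, rng)
    outcomes = OutcomeTable(pd.DataFrame(data, index=pd.Index(ids, name="individual_id")))

    truth = GroundTruth(z=pd.Series(z, index=ids), latents=latents,
                        channel_models=models, seed=config.seed)
    return tables, outcomes, truth


def ground_truth_gated_counts(events: EventTable, tree: GateNode) -> CellTypeCounts:
    """Reference gated counts for synthetic data.

    Shares the implementation with :func:`ungated.gating.apply_gating_tree`
    so the comparator model's input is truthful by construction; the
    equivalence is asserted in the test suite.
    """
    return apply_gating_tree(events, tree)
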