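# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing and binning

Events are processed per individual in a fixed order: trim → outlier
removal → subsample → bin.

- **Trim** removes the first and last `floor(0.10·n)` events by
  acquisition order. Rationale: acquisition inconsistencies concentrate at
  the ends of a run; the synthetic generator's drift model makes this
  consequential and testable.
- **Outlier floor**: any event with a fluorescence value strictly below
  −50,000 RFU is dropped whole. The floor protects a distribution-based
  featurization from a handful of extreme negative values claiming entire
  histogram sections.
- **Subsample**: a seeded simple random sample of 5,000 events
  (acquisition order preserved) equalizes representation across
  individuals whose event counts differ by orders of magnitude. When
  fewer events survive cleaning, all are kept and a shortfall flag is
  recorded — never resampling with replacement, so the sample is always a
  true subset. Outlier removal precedes subsampling so the sample holds
  exactly 5,000 *clean* events.
- **Binning**: per individual and channel, the 2.5th/97.5th percentiles
  are computed on the values actually binned, using linear interpolation
  between order statistics (the "type 7" convention — the default in
  NumPy and R, fixed here because the choice moves clip counts by ±1).
  Section 1 takes values `< p2.5`, section 102 takes values `> p97.5`,
  and `[p2.5, p97.5]` is split into 100 equal-width half-open sections
  `[a, b)` with the last closed at `p97.5`, so counts always sum to the
  number of binned events. Counts are raw (not normalized): with a fixed
  sample size they are comparable across individuals. A degenerate
  channel (all values equal) collapses to a single interior section with
  a warning rather than crashing.

## Network architectures and training

The continuous model: 23 branches (one per fluorescence channel) of dense
layers 102 → 75 → 50 → 25 → 1; ELU (α = 1) on the 75/50/25 layers, linear
on both one-unit layers; a final linear unit combines the 23 branch
scalars. 295,022 parameters. The gated model: 67 → 50 → 30 → 15 → 1, same
activation pattern; 5,411 parameters. When a synthetic gating tree has a
different leaf count, the gated hidden sizes are scaled proportionally
while preserving the strictly decreasing layer-size gradient.

Training is minibatch Adam (step 1e-3, β₁ = 0.9, β₂ = 0.999) on mean
squared error, batch size 100. MSE is used for every outcome type,
including binary ones, because evaluation is RMSE on a linear output —
binary outcomes are deliberately regressed, not classified. Inputs are
fed raw (section counts ≤ 5,000); a standardization switch exists but
defaults off.

The implementation is plain NumPy with explicit forward/backward passes.
The networks are small enough that this is fast on one CPU, and it makes
every replicate bit-reproducible under a seed — there is no thread-level
or framework-level nondeterminism to document. Gradient correctness is
pinned by a finite-difference test. A non-finite loss raises immediately
with the epoch and last finite loss.

Epoch profiles: **full scale** is 25,000 epochs (continuous) / 10,000
(gated); the **desk profile** used by default in examples, tests and the
acceptance script is 500/200. The reduced budgets were chosen as the
package's routine operating point: on desk-scale cohorts the continuous
model's validation RMSE plateaus well within 500 epochs while 25,000
epochs on 300 calibration samples adds only training time. The full-scale
profile remains available via config (`profile: full`).

Replicates: replicate *r* seeds initialization and batch shuffling with
`base_seed + r`. The 300/267 calibration/validation split is held fixed
across replicates (a per-replicate resplit would mix split variance into
what the replicate SD is meant to isolate — training randomness); the
split itself is seeded and reproducible.

## Gating

Primary (quality) gating applies, in order: a rectangular FSC-A/SSC-A
debris gate, an FSC-H/FSC-A ratio band for singlets, a viability-channel
ceiling, and a CD45 floor. It is shared by both model arms.

Gating trees are hierarchies in which each internal node splits one
channel at strictly increasing thresholds into half-open intervals —
siblings are therefore mutually exclusive and exhaustive by construction,
and leaf counts always partition the gated events. Only 1-D threshold
splits (plus the 2-D rectangle/ratio rules of primary gating) are
supported: polygon or ellipse gates would complicate the exclusivity
guarantee without adding anything testable on synthetic mixtures. The
default synthetic tree splits leaves breadth-first, cycling through
channels, with thresholds at pooled-cohort histogram valleys (peak
detection includes boundary bins so a mode packed into the first bin is
not missed; unimodal channels fall back to the median). The gated model's
input is raw leaf counts, mirroring the continuous model's raw section
counts; a proportions option exists.

## Synthetic cohorts

The generator emulates what the analysis assumes about real cytometry
cohorts, with every latent draw recorded for recovery tests.

- **Intensities**: per-channel two-component normal mixtures on the raw
  RFU scale (bimodal lineage markers: components near 500 ± 300 and
  30,000 ± 5,000; unimodal gradient markers: single component near
  8,000 ± 3,000). Mixtures, not transformed scales, because binning is
  defined on the absolute scale.
- **Latent state**: one scalar z ~ N(0,1) per individual drives channels
  in one of two modes — mixing-weight shifts (cell-type proportions, on
  the logit scale) or positive-component mean shifts (within-population
  intensity). The default cohort mixes both; the `intensity_shift`
  scenario puts *all* signal into mean shifts of well-separated bimodal
  channels, so valley-threshold counts are independent of z by
  construction. That scenario is the package's testbed for the central
  claim: information that gating cannot see.
- **Nuisance events**: debris (low scatter, barely stained), doublets
  (FSC-H/FSC-A ≈ 0.55, ~1.8× signal), dead cells (high viability stain),
  at 5%/3%/5% by default; extreme negative outliers at rate 0.001, placed
  on one random channel per affected event, magnitude −50,000 minus an
  exponential (mean 10,000) — matching the qualitative description of
  rare extreme negative values.
- **Drift**: a linear multiplicative ramp 1 ± amplitude (default 0.05)
  over event order on fluorescence channels, making the head/tail trim
  consequential.
- **Outcomes**: 20 emulated health measures (continuous, ordinal and
  binary) with cohort means matching the published sample description
  (age ≈ 67, MMSE ≈ 28, mostly low-prevalence dichotomies); binary
  outcomes threshold a probit-style latent risk at the quantile matching
  the target prevalence. "Religion" is a negative control generated from
  a random stream independent of z and of all event streams.
- **Scale**: defaults are 567 individuals × 20,000 events. Event counts
  per individual are exposed as config rather than drawn from a guessed
  distribution, since no quantitative description of real per-individual
  variability was available. Routine runs and the acceptance experiment
  use 2,000 events per individual, which keeps a full cohort under a few
  hundred MB and a 10-replicate two-arm experiment within minutes on one
  CPU.

What the generator does **not** emulate: marker co-expression structure
(channels are conditionally independent given z), compensation/spillover,
instrument-specific transforms, or time-parameter channels beyond event
order. Passing tests therefore demonstrate that the pipeline recovers
signal of the assumed form — distributional shifts driven by a scalar
latent state — not that it would predict any particular real-world
outcome.

## Evaluation

RMSE per replicate on the validation set; replicate aggregation reports
the mean and the sample (n−1) standard deviation. The success rule is the
strict inequality `rmse_mean < outcome_mean/3` and is undefined (raises)
for non-positive outcome means. The sign test is the exact one-sided
binomial tail P(K ≥ k | n, ½) computed by pmf summation, validated
against full 2ⁿ enumeration for small n; ties are dropped with a warning.
Individuals with any missing outcome are removed before splitting so
every outcome's models see the same people. The published benchmark table
is embedded (`ungated.benchmark`) as reference input for the success-rule
and sign-test machinery; the published 15-of-21 sign-test count is
recorded as published rather than recomputed, because a naive pairing of
the printed per-outcome means yields a different count and the original
pairing basis (possibly per-replicate) is not stated.

## Numerical choices and degenerate inputs

- Glorot-uniform initialization, seeded; two builds with one seed are
  bit-identical.
- Percentile convention type 7; clip membership strict (`<`, `>`); final
  interior bin closed.
- Empty event tables: allowed through gating (all-zero counts) but an
  error once a stage needs at least one event (cleaning, binning).
- Trim fraction must be < 0.5; subsample shortfalls flag rather than
  resample; all-equal channels collapse with a warning.
- Seed offsets per stage (cohort +0, preprocessing +1000, split +2000,
  continuous training +3000+r, gated +4000+r) keep streams disjoint under
  one base seed.

## Limitations

- The branched network treats channels as separate branches; joint
  multi-marker structure is only combined affinely at the informative
  layer, by design — interpretability over expressiveness.
- Desk-profile results quantify the method on synthetic cohorts; real
  cohorts bring compensation, batch and panel-drift effects that are out
  of scope here.
- FCS support covers the common list-mode float profile (3.0/3.1), not
  integer data, compressed dialects or analysis segments.
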