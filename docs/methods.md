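# Methods

`commfun` analyses combinatorial community experiments with small
bacterial communities — the motivating system is sets of four
*Pseudomonas* strains per community, one per phenotype class
(pyoverdine + protease producer `PVD_PRO`, pyoverdine-only `PVD`,
protease-only `NON_PRO`, non-producer `NON`) — and asks how much of the
variance in community functioning is attributable to *which strains are
present* (strain identity) versus *how strains affect each other*
(strain interactions). This note describes the statistical procedures,
the synthetic-data model used to validate them, and the design choices
made where several reasonable options existed.

## Experimental design model

Every community contributes all strain combinations of sizes 1–4:
4 monocultures + 6 pairs + 4 triples + 1 quadruple = 15 cultures, of
which the 11 mixtures (size ≥ 2) enter the variance decomposition.
Mixtures are inoculated substitutively: total starting density is
constant (default OD600 = 0.01), so each member's inoculum is
`total / richness`. Combination identifiers are the sorted member ids
joined with `+`, which makes every table joinable on a canonical key.
Design validation is strict by default (exactly one strain of each of
the four types per community); the balance properties of the
decomposition assume the complete design, so incomplete communities
require an explicit override.

## Supernatant interactions

The directed effect of donor *d* on receiver *r* is the growth effect

    GE = median(SN_treatment) / median(SN_control),

the receiver's median growth in medium supplemented with the donor's
sterile spent medium, relative to a saline control; GE > 1 is
stimulation, GE < 1 inhibition. Effects are classified +1 / 0 / −1 by a
two-sided Welch t-test of treatment vs control replicates at α = 0.05
(Mann–Whitney available as an alternative). When a group has fewer than
two replicates, or both groups have zero variance (noise-free synthetic
data), classification falls back to an effect-size threshold
|GE − 1| > 0.05. Reciprocal sign pairs map to six interaction types:
mutual stimulation [+/+], one-way stimulation [+/0], no effect [0/0],
contrasting [+/−], one-way inhibition [0/−], mutual inhibition [−/−].

Per combination, three summaries are computed over all
`richness × (richness − 1)` directed non-self effects among members:

* **interaction score** — mean of the sign codes, in [−1, 1];
* **mean absolute effect** — mean |GE − 1| (GE = 1 is the null line, so
  magnitude is distance from 1; mean |log GE| would be a defensible
  alternative and can be derived from the emitted effect table);
* **proportion of positive effects**.

Effects of a strain's supernatant on itself are computed and reported
but excluded from the summaries, which are defined over interactions
*between* community members. The default assay endpoint is 24 h;
48 h measurements are accepted via the `timepoint_h` argument.

## Community functioning

Productivity and total pyoverdine production are the trapezoidal
integrals of the OD600 and fluorescence time series over the observed
window (units OD600·h and RFU·h), computed on the native measurement
grid with no smoothing or blank correction — inputs are taken as
provided. Endpoint-only tables (pre-integrated values, blank
`timepoint_h`) are accepted interchangeably. Replicates are aggregated
by the median (mean optional), consistent with the use of medians in
the supernatant assay. The deviation from the monoculture expectation
for a mixture is

    DEV_trait = TV_mix − mean(TV_mono),

with TV_mono the same-condition monoculture values of the mixture's
members, using the same aggregate on both sides. Positive DEV means the
mixture functions better than the average of its parts.

## Sequential variance decomposition

For each community × condition, using the 11 mixtures (replicate-level
rows by default; per-combination aggregates optional), variance in a
trait is split into sequential (Type-I) components in the order

1. **linear richness** — strain richness as a continuous covariate;
2. **strain identity** — four presence/absence indicators;
3. **strain interactions** — one of three variants:
   richness as a categorical factor (non-linear richness, the purely
   statistical proxy), the interaction score, or the mean absolute
   effect together with the proportion of positive effects.

Each stage's SS is the increment in explained SS when its column block
is appended to the cumulative design; df is the rank increment
(presence indicators sum to richness, so the identity stage has df 3,
not 4; the categorical-richness block adds rank 1 beyond continuous
richness), and the mean square MS = SS/df is the effect-size currency.
The decomposition is exhaustive by construction: stage SS plus residual
SS equal the total SS about the mean on every input, balanced or not.
The original formulation of the method fits each stage to the previous
stage's residuals; on the balanced design this is identical to the
Type-I increments (verified against R's `anova(lm(...))` and an
explicit projection-matrix oracle), and the identity and
nonlinear-richness mean squares are invariant to the fitting order.
The cumulative Type-I form is used because it remains exhaustive and
well-defined when the design is unbalanced or when the interaction
predictors correlate with presence; `orthogonality_check` fits both
orders and reports any discrepancy instead of averaging it away.

Strain contribution coefficients are obtained by regressing the
stage-1 residuals on the four presence indicators (no intercept) and
centering; they sum to zero exactly and measure each strain's effect on
functioning relative to the community average. On a noise-free additive
community they are exactly proportional to the generator's identity
deviations (a consequence of the design's permutation symmetry).

The DEV-versus-interaction-score relationship is estimated by OLS of
`DEV_productivity` on the score with condition and richness as additive
covariates — a fixed-effects, desk-scale stand-in for the original
mixed-model analysis. Standard errors are cluster-robust by community:
DEV rows within a community share monoculture reference values, so
their errors are correlated, and null simulations show plain OLS
standard errors reject a true null about 8× too often at α = 0.01
while the clustered test holds its nominal size.

## Synthetic data generator

The generator emulates the full study: 16 communities (8 soil,
8 freshwater) × 4 strain types, both iron conditions, the complete
supernatant assay (4 treatment / 3 control replicates, 24 h endpoint)
and all 15 competition cultures (5 replicates; 6 for the quadruple).

* **Trait units.** Productivity integrals are OD600·h over 0–48 h for
  static 96-well cultures read at ~0.55 cm path length, where peak
  densities of 0.2–0.4 OD are typical: type baselines are 10 OD·h for
  all types under iron-rich conditions and 8.0 / 7.4 / 6.6 / 4.6 OD·h
  (PVD_PRO / PVD / NON_PRO / NON) under iron limitation, reproducing
  the producer–non-producer growth ordering when iron is scarce and the
  near-equality of types when it is not. Pyoverdine baselines are high
  only for producers under iron limitation (9000 / 8000 vs 900 /
  300 RFU·h) and uniformly low when iron is rich.
* **Identity.** Each strain × condition receives a deviation
  ~ N(0, `identity_sd`) added to its type baseline (pyoverdine: the
  same deviation scaled by `pyoverdine_scale` = 300, reflecting
  positive trait linkage across secreted-compound phenotypes).
* **Supernatant truth.** Directed effects have a positive sign with
  probability `positive_interaction_prob[condition]` (defaults 0.6
  iron-limited, 0.2 iron-rich: stimulation is much commoner under iron
  limitation) and half-normal magnitudes (scale 0.35 / 0.08), so
  iron-rich effects are small and mostly classified neutral.
  Self-effects are predominantly positive under iron limitation.
* **Mixture interactions.** The expected trait of a mixture is the mean
  of its members' monoculture means plus the mean over member pairs of
  a pairwise contribution `γ = interaction_sd · (κ·s + (1−κ)·z)`,
  where `s ∈ {−1, 0, +1}` is the sign of the pair's summed directed
  supernatant signs, `z ~ N(0,1)`, and `κ` is the supernatant–mixture
  coupling. Averaging (rather than summing) over pairs keeps effect
  magnitudes comparable across richness levels, matching the constant
  total inoculum of the substitutive design. At κ = 1 the mixture
  interaction effect equals `interaction_sd ×` the true interaction
  score exactly, which gives the DEV–score regression an analytic
  target; at κ = 0 supernatant signs carry no information about
  mixture deviations.
* **Noise.** An observed replicate is the expectation times
  `exp(noise_cv · N(0,1))`; multiplicative noise because OD and
  fluorescence errors scale with signal. Default `noise_cv` = 0.05, a
  typical replicate CV for growth-curve integrals.
* **Time series.** On request, logistic curves (growth rate 0.25 h⁻¹,
  midpoint 12 h; pyoverdine 0.30 h⁻¹, 16 h) are emitted on the 15-min
  grid, with the carrying capacity solved so the analytic 0–48 h
  integral equals the replicate's endpoint value — the integration
  stage therefore has an exact oracle. Endpoint-only output is the
  default; the large simulation harnesses do not need the curves.

Identical seeds produce byte-identical tables. The ground truth
(monoculture means, identity deviations, directed effects, pair
contributions, per-combination expectations) is serialized to
`truth.json` and suffices to recompute every expectation without the
RNG.

What the generator does *not* emulate: mechanistic iron/siderophore
chemistry, within-mixture strain frequencies, lag/rate differences
between strains (curves differ only in scale), plate position effects,
or measurement error that is additive at low signal. Passing recovery
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to every property of
real plate-reader data.

## Regime harness

Parameter-recovery experiments use a single-condition configuration
(`simulate.regime_config`): the iron-rich condition (shared type
baseline, so between-strain variance is exactly the identity dial) with
iron-limited-like supernatant effect magnitudes and balanced sign odds
(p = 0.5), making the supernatant predictors informative. In the
identity regime (identity_sd = 1, interaction_sd = 0, 5% noise) the
centered strain coefficients correlate with the true identity
deviations at r ≈ 0.95 across 50 communities, and the identity mean
square exceeds every interaction mean square in ≥ 95% of communities.

## Known limitations

* **Attribution order caps the visibility of interactions.** Strains
  differ in how many positive effects they give and receive, and that
  margin structure is itself a strain main effect: in the balanced
  design, a median ≈ 60% of the interaction score's richness-adjusted
  variance lies inside the span of the presence indicators. Because
  identity is fitted before the interaction term (the interaction
  predictor replaces the *last* model's richness term), the identity
  stage absorbs that shared variance. Consequently, even a generator
  with *only* interaction effects (identity_sd = 0, full coupling, no
  noise) yields MS(interaction) > MS(strain ID) in only ~55–60% of
  communities. Mean-square comparisons under this method are
  conservative about interactions by construction, which should be kept
  in mind when interpreting identity-versus-interaction contrasts.
* **Non-linear richness is blind to pair-averaged interactions.** When
  pairwise contributions enter mixtures as the average over pairs, each
  richness level's mean equals the grand mean of pair contributions, so
  the categorical-richness term captures none of this interaction
  variance. It detects richness-structured non-additivity only.
* The inferential layer of the original analysis (GLS/LMM variance
  structures, AIC model selection, post-hoc contrasts with FDR
  correction) is out of scope; cross-community statements here rest on
  simulation-based checks, not on those test statistics.
* Classification of weak effects depends on replicate number and noise;
  with the default 4-vs-3 replicates at 5% CV, effects below roughly
  8% of control growth are usually classified neutral.
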