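# commfun

**Strain identity versus strain interactions in the functioning of small
bacterial communities.**

Microbial communities drive ecosystem services, but what determines how
well a community functions? Two broad forces compete for the answer:
*strain identity* — which strains (with which intrinsic traits) are
present — and *strain interactions* — how strains help or harm each
other, for instance through secreted iron-scavenging pyoverdines that
some strains produce and others exploit. `commfun` implements, as a
tested and reusable pipeline, the combinatorial-assembly analysis used
to separate the two: communities of four *Pseudomonas*-like strains
(one per phenotype class: `PVD_PRO`, `PVD`, `NON_PRO`, `NON`) are grown
in monoculture and in every 2-, 3- and 4-strain mixture under
iron-limited and iron-rich conditions, secreted-compound interactions
are measured with supernatant-feeding assays, and a sequential
linear-model decomposition partitions the variance in community
functioning between identity and interactions.

The core quantities:

* **Growth effect** of donor *d* on receiver *r*:
  `GE = median(SN_treatment) / median(SN_control)`; GE > 1 stimulation,
  GE < 1 inhibition. Sign classification (+1/0/−1) by Welch test;
  reciprocal signs give six pairwise interaction types, and per strain
  combination the **interaction score** (mean sign code), **mean
  absolute effect** (mean |GE − 1|) and **proportion of positive
  effects** summarize the interaction milieu.
* **Community functioning**: 0–48 h trapezoidal integrals of OD600
  (productivity, OD·h) and pyoverdine fluorescence (RFU·h), and the
  deviation from the monoculture expectation
  `DEV = TV_mix − mean(TV_mono)`.
* **Sequential decomposition** per community × condition over the 11
  mixtures: Type-I sums of squares for (i) linear richness
  (continuous), (ii) strain identity (presence indicators, df 3),
  (iii) strain interactions — non-linear richness (categorical), the
  interaction score, or mean absolute effect + proportion positive.
  Mean squares (SS/df) are compared across predictors; per-strain
  contribution coefficients (centered, sum-to-zero) measure each
  strain's effect relative to the community average.

A fully ground-truthed synthetic study generator (strain-type baseline
phenotypes, per-strain identity deviations, sign-linked pairwise
interaction contributions, multiplicative replicate noise, optional
logistic time series with analytic integrals) makes every stage
testable without external data.

## Worked example

```bash
commfun run --config examples/demo.yaml
```

simulates a 4-community study (seed 7) and runs the full analysis into
`demo_out/`. The run prints a manifest; the headline outputs are
`decomposition.csv`, `coefficients.csv`, `summaries.csv`, and
`mean_square_summary.csv`, which for productivity reads:

```
   condition     response            predictor  median_ms
iron_limited productivity            strain_id  10.974108
iron_limited productivity    interaction_score   2.624272
iron_limited productivity combined_supernatant   1.488167
iron_limited productivity   nonlinear_richness   0.036619
iron_limited productivity      linear_richness   0.121541
```

Read: in these four simulated communities under iron limitation, strain
identity explains far more per-degree-of-freedom variance in
productivity (median MS ≈ 11 OD²·h²) than any interaction measure, and
the supernatant-based interaction measures in turn carry more signal
than the purely statistical non-linear richness proxy. The manifest
also reports the deviation–score regression, e.g.

```
dev_regression: slope 0.909 ± 0.097 (t = 9.41, n = 88)
```

a positive relationship between deviations from expected productivity
and the interaction score: mixtures whose members stimulate each other
through secreted compounds overperform their monoculture expectation
(the demo generator couples mixture interactions fully to supernatant
signs, hence the strong slope).

The same stages are available as separate subcommands
(`commfun simulate | interactions | traits | decompose | report`) and
as library functions (`commfun.supernatant`, `commfun.functioning`,
`commfun.partition`, `commfun.simulate`, `commfun.workflows`).

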