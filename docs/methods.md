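# Methods

## Scope and data model

The package re-implements, as a seeded and fully testable pipeline, the
standard desk workflow for nominating a regulatory driver motif from
two-group expression cohorts: DE screening → interaction filtering →
feed-forward-loop (FFL) network → degree-centrality ranking → survival
analysis → over-representation analysis. The original workflow consumes
live resources (GEO series, a ChEA-style TF–target database, a
miRWalk-style miRNA–target database, KM-plotter / MethSurv cohorts);
here every input is either a user-supplied plain-text table in the same
shape, or a synthetic stand-in with planted ground truth. No network
access is ever required.

## Synthetic generators: what they emulate

Every generator is a pure function of its parameters and an integer
seed, so any reported number is reproducible from the config alone.

- **Expression** (`generate_expression`): values are
  `base_i + shift + N(0, sd)` on the log2 scale, with per-feature
  baselines `N(7, 1.5²)` mimicking microarray log2 intensities. A
  fraction `frac_de` of features is mean-shifted by ±`effect` in the
  case group, split evenly between up and down so both directions of
  the DE bookkeeping are exercised. Defaults: 30+30 samples,
  `frac_de = 0.2`, `effect = 0.75`, `sd = 0.4`. The effect default sits
  at the centre of the 0.5–1.0 log2FC calling band; `sd = 0.4` is a
  typical within-group spread for array data and makes the band
  retain a truly shifted feature with high probability at n = 30 per
  group (s.e. of the fold-change estimate ≈ 0.1). The generator does
  **not** model probe effects, background correction, batch structure
  or correlated features, so passing tests demonstrate correctness of
  the screening logic, not robustness to array artifacts.
- **Interaction tables** (`generate_regulatory_tables`): independent
  Bernoulli edges per pair type (TF→gene, miRNA⊣TF, miRNA⊣gene) with
  probability `edge_prob`. Each background edge receives
  filter-*passing* attributes with probability `pass_prob` (p-value
  uniform below 0.05 / score uniform above 0.95 with exclusive-3′UTR
  binding) and failing ones otherwise (p above threshold, or score
  below, or a non-exclusive binding-region set) — so every branch of
  the filters sees traffic. A planted motif's three defining edges are
  always emitted passing, and each member receives `extra_degree`
  additional passing edges so its degree exceeds the background
  expectation; the miRNA's extras are drawn from the combined TF+gene
  namespace. `target_role` is derived from the target's namespace so a
  single miRWalk-style table yields both miRNA–TF and miRNA–mRNA pairs.
- **Survival** (`generate_survival`): event times are exponential with
  rate `baseline_rate · exp(log_hr · z)` (z the standardized covariate),
  censoring independent exponential(`censor_rate`); the recorded time is
  the minimum. Defaults `baseline_rate = 0.02`/month (median survival
  ≈ 35 months) and `censor_rate = 0.01` give roughly two-thirds observed
  events, a realistic cohort mix. Proportional hazards hold exactly by
  construction; the generator does not model time-varying effects.
- **Methylation** (`generate_methylation`): i.i.d. Beta(α, β) beta
  values; defaults α = 2, β = 5 give the left-skewed bulk typical of
  promoter CpGs. No spatial CpG correlation is modelled.
- **Gene sets** (`generate_gene_sets`): uniform draws from the gene
  universe; optionally the first sets draw a fraction of members from
  the true-DE list so the enrichment stage has a detectable signal.

## Differential expression

The screen is a per-feature two-sample t-test (Welch–Satterthwaite by
default; a pooled-variance option exists) with fold change defined as
mean(case) − mean(control) in log2 units. The DE call combines
`p < p_thresh` (raw p by default; BH-adjusted optionally) with a
fold-change rule. The default rule is the *band* `0.5 ≤ |log2FC| ≤ 1.0`,
taken literally from the workflow this package operationalizes; because
a band that excludes large effects is unusual, the conventional
`min` rule (`|log2FC| ≥ lo`) is a first-class alternative
(`fc_rule="min:0.5"`), and whether the band applies to log2FC or raw FC
being ambiguous in the source workflow, the package fixes it to log2FC.
Degenerate features (both groups constant and equal) are assigned
t = 0, p = 1; constant-but-unequal groups get |t| = ∞, p = 0 and a
clamped −log10 p in the volcano table.

## Interaction filtering and calibration

Thresholds are strict inequalities (`p < 0.05`, `score > 0.95`), and
"exclusively 3′ UTR" is region-set equality `{3UTR}`, not membership.
TFs are *not* required to be DE themselves (they enter by regulating DE
genes); `require_de_tfs=True` switches the stricter reading on.
Calibration iterates three restrictions to a fixed point: miRNA edges
are kept only for *common* miRNAs (≥ 1 retained edge to an mRNA and
≥ 1 to a TF), miRNA→TF edges only for TFs present in the TF–gene table,
and TF→gene edges only when both endpoints are targeted by ≥ 1 common
miRNA. These conditions are necessary but not sufficient for an edge to
sit in a triangle (the miRNAs hitting the TF and the gene may differ),
so `ffl_support=True` optionally adds triangle-support pruning — the
strictly stronger fixed point under which every surviving edge belongs
to ≥ 1 enumerable FFL. The weaker fixed point is the default because it
matches the edge-rich networks this workflow reports in practice. A
`single_pass` mode applies one restriction round for comparison.

## Network and motif ranking

Node identity is the (role, id) pair, so an identifier appearing as
both TF and mRNA yields two distinct nodes and role counts stay
additive. Degree centrality is in-degree + out-degree over all edge
types on the full assembled network (matching the raw degree a graph
viewer reports), unnormalized by default; `normalized=True` divides by
(n − 1). The ranking rule — not uniquely determined by workflows that
just say "degree centrality identified the top motif" — is defined here
as the **sum** of the three member centralities, with lexicographic
tie-breaking on (tf, gene, mirna); sum is symmetric in the members and
reduces sensibly when motifs share a hub. A `max`-member variant is
behind a flag. Enumeration iterates each miRNA's TF-targets × the
TF's genes intersected with the miRNA's gene-targets, and is verified
against a brute-force triple loop.

## Survival analysis

The median split uses the covariate median over the entire cohort with
ties assigned to the low group (the split convention is not fixed by
KM-plotter-style tools; ties-low is the deterministic choice). KM
curves use the product-limit estimator (via lifelines), with samples
censored at an event time counted at risk at that time. The log-rank
statistic is computed from the observed/expected/hypergeometric-variance
table; the hazard ratio is the log-rank O/E approximation
`(O_h/E_h)/(O_l/E_l)` rather than a Cox fit — the claims this pipeline
supports are direction and significance, not HR magnitude, and the O/E
form needs no iterative estimation (lifelines' `logrank_test` serves as
an independent cross-check in the tests). "Invert HR below 1" reports
the reciprocal with an `inverted` flag so adverse associations read
uniformly as HR > 1. The per-feature scan skips constant covariates
with a log entry and sorts by p.

## Enrichment

One-sided hypergeometric upper tail `P[X ≥ overlap]` per set after
intersecting sets with the universe, BH adjustment across tested sets,
sorted by p, truncated to the significant top-k. The universe defaults
to all features tested in the DE screen — a choice, since enrichment
backends rarely document their background. The rank-based combined
scores of hosted enrichment services are deliberately not reproduced.

## Problem sizes and numerical conventions

The test suite and acceptance script run at desk scale: 100-seed
recovery simulations on 30 TF / 100 gene / 50 miRNA namespaces with
background passing-edge probability 0.02 and 30 extra edges per planted
member; 2000-replicate null calibrations for the DE screen (2000
features, 20 vs 20) and the log-rank test (n = 60 per replicate); exact
oracle comparisons on universes ≤ 30 (ORA) and graphs ≤ 12 nodes per
role (FFL enumeration). The published-scale bookkeeping check samples
exact unique-edge counts (9,051 / 16,824 / 90,520) uniformly without
replacement from the corresponding pair spaces. Quantile normalization
resolves ties by average-rank interpolation into the mean-sorted
reference. All stage seeds are derived from the single config seed via
`numpy` `SeedSequence`, and manifests contain no timestamps, making
reruns byte-identical.

## Known limitations

- No empirical-Bayes variance moderation in the DE screen; small-n
  cohorts will be noisier than limma-style pipelines.
- The O/E hazard ratio is biased away from 1 relative to a Cox HR when
  censoring differs between groups.
- Synthetic data are i.i.d. within feature: no batch effects,
  feature–feature correlation, or platform artifacts, so recovery rates
  measured here are upper bounds on real-data performance.
- The band fold-change rule discards strong effects by design; use
  `min:` when that is not intended.
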