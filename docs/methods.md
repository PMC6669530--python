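# Methods

`mixtox` implements the statistical analysis of a two-agent factorial
ecotoxicology study — a genotoxic organic compound (agent A, e.g.
benzo[a]pyrene) crossed with a nanomaterial (agent B, e.g. aqueous C60
aggregates), with mixture groups pairing each A dose with one fixed B dose
— together with a label-free spectral-count proteomics arm. This note
records the models, the defaults and why, and what the synthetic-data
validation does and does not establish.

## Interaction Factor

For group means C (control), G_A, G_B and G_AB (mixture) the Interaction
Factor is

    IF = G_AB − G_A − G_B + C,

the departure of the observed mixture response from additivity of the two
single-agent effects on the response scale. Errors propagate by the
Pythagorean rule for independent groups:

    SEM_IF  = sqrt(SEM_AB² + SEM_A² + SEM_B² + SEM_C²)
    A       = (G_A − C) + (G_B − C),   SEM_add = sqrt(SEM_A² + SEM_B² + SEM_C²)

Assumptions: groups are independent; the endpoint is analyzed on the scale
on which additivity is meant (raw response units by default — the reported
endpoint scale — not the log scale used for ANOVA normalization); SEMs are
estimated with the n−1 SD.

**Significance rule.** The mixture interval `IF ± z·SEM_IF/√2` is compared
with the additive null interval `0 ± z·SEM_add/√2`; strict non-overlap is
declared significant and the label then follows sign(IF) (antagonistic /
synergistic), otherwise "additive". The √2 scaling is the usual correction
that makes interval-overlap testing approximate an α-level two-sample
comparison rather than the very conservative raw-interval version. Two
caveats are intentional and documented:

- `z = 1.959964` (normal quantile) rather than a t quantile — there is no
  single defensible df for a four-group composite; the choice is exposed via
  `alpha`.
- The rule is *approximate and conservative*: SEM_add shares three of
  SEM_IF's four components, so their sum double-counts error. Simulation
  (2000 additive runs, n = 10/group, SD = 5) gives a significant-call rate
  of ≈ 0.01–0.05 at α = 0.05, and detection of a −2·SD antagonistic shift
  of ≈ 0.70 (a plain z-test on SEM_IF alone would give ≈ 0.89). We keep the
  overlap rule because it is the procedure the reported tables define.
- Touching interval endpoints are "not significant"; a relative tolerance
  of 1e−9 absorbs float round-off at the exact boundary. If every SEM is
  exactly zero the intervals degenerate to points and significance reduces
  to IF ≠ 0.

## Endpoint decision tree

Continuous endpoints (e.g. % tail DNA from comet assays, 8-oxodGuo levels)
follow a gatekept univariate analysis:

1. **Lilliefors normality per group**, Monte Carlo p-value: the KS distance
   to a normal with estimated mean/SD is compared with `n_mc` (default
   10 000; 2000 in the pipeline driver) simulated same-n normal samples with
   parameters re-estimated per resample, using the add-one estimator
   (k+1)/(n_mc+1). This is exact at small n, unlike table interpolation;
   simulation shows a rejection rate of ≈ 0.05 for normal data. Groups with
   n < 4 or zero variance are not testable and are skipped with a warning.
2. **Bartlett homogeneity** across groups (χ² on k−1 df).
3. **Branching**: all gates pass → raw-scale one-way ANOVA; normality fails
   and all values are positive → natural-log transform and retest (ln-ANOVA
   if rescued); otherwise → Kruskal–Wallis with tie correction. Bartlett
   failure with normality intact also routes nonparametric — homogeneity is
   an ANOVA assumption and the conservative fallback costs little. Gate
   α = 0.05 throughout.
4. **Post-hoc**: Tukey HSD on the studentized-range distribution (numerical
   integration via scipy), summarized as a compact letter display by the
   insert-and-absorb algorithm: start with one letter covering all groups,
   split every letter-set containing both members of a significant pair,
   absorb subsets, assign letters by each set's smallest member. Groups
   sharing a letter are not significantly different; non-transitive patterns
   yield multi-letter codes rather than an error.

Note that with ~10 groups each gated at α = 0.05, perfectly normal data
still fail at least one gate in roughly a third of experiments; the
nonparametric fallback is therefore common and harmless.

## Spectral-count proteomics

The workflow starts from a peptide × sample matrix of spectral counts with
a peptide→protein map and a condition/biological-replicate design (three
pooled biological replicates per condition by default). Stage order is
fixed; reordering is a pipeline error, not a variant.

1. **Identification filter** — proteins with < 3 distinct peptides are
   dropped (false-positive control), with a per-protein audit table.
2. **Aggregation** — protein value = sum of observed peptide counts ÷
   number of observed peptides in that cell; a protein cell is missing only
   when all its peptide cells are. The per-cell peptide tally is retained
   so the raw sums can be reconstructed exactly (value × tally).
3. **Presence filter** — keep proteins observed (non-missing, nonzero) in
   ≥ 3 biological replicates of *at least one* condition. The per-condition
   reading (rather than global) keeps condition-specific proteins, which
   are exactly the interesting ones in a unique-DEP comparison.
4. **Variance stabilization** — per-sample scale calibration by median
   ratio to the row-median reference profile, then the generalized log
   `arcsinh(y/c)` with `c` the global median of calibrated values. The
   transform is strictly monotone within a sample and leaves missing cells
   untouched; simulation with multiplicative-plus-additive noise confirms
   the per-protein SD–mean correlation shrinks. This scale is used for
   imputation distances and reporting only.
5. **Mixed imputation** — missing cells are classified per
   protein × condition: observed in some replicates of the condition →
   treated as randomly missing, imputed by KNN (k = 10 nearest proteins by
   Euclidean distance over co-observed samples, normalized per shared
   sample; neighbors must be observed in the target sample; k shrinks with
   a warning when neighbors run out); entirely missing within a condition →
   treated as left-censored, imputed by QRILC: per sample a normal is
   fitted by least-squares regression of the order statistics on
   standard-normal quantiles, and draws are taken from the left tail
   truncated at min(fitted q-quantile, empirical q-quantile of the
   observed values), q = 0.01 by default. The min makes the truncation
   contract hold on both the fitted and the empirical scale. Observed cells
   are never altered; every imputed cell carries a provenance flag.
6. **Differential expression** — per protein, a quasi-Poisson log-link GLM
   of the *reconstructed summed counts* on condition with a
   log(sample-total) offset. For a two-group contrast the grouped MLE is
   closed-form (rate_g = Σcounts_g / Σtotals_g), so the fit is vectorized
   across the proteome. The dispersion is estimated from the residual
   deviance on n−2 df and squeezed toward the proteome-wide median with
   `prior_df = 4` pseudo-df; the condition effect is a deviance F test on
   (1, n−2+prior_df) df. The squeeze matters: unmoderated per-protein
   dispersions on 4 residual df make the far tail anticonservative (false
   discoveries slip under BH at q < 0.01), while a hard Poisson floor is
   overconservative; borrowing strength across proteins gives a null
   p < 0.05 rate of ≈ 0.05 and realized FDP ≈ 0.01 at q < 0.01 in
   negative-binomial simulations (dispersion 0.1, 3 vs 3). Counts are
   tested, not glog values — the two scales are incompatible. Missing cells
   enter as zero (a missing spectral count is a non-observation). Two
   significance tiers are reported: *candidate* (p < 0.05) and *confirmed*
   (BH q < 0.01).
7. **Quantification and overlaps** — spectral index SI_N = value / sample
   total (counts-based; the classical intensity-based index is out of
   scope and this surrogate is stated as such), and Venn-partition
   cardinalities plus pairwise Jaccard percentages for candidate sets
   across doses.

## Term enrichment

Candidate sets are tested against flat term→protein annotations
(GMT files; any ontology-graph propagation is assumed done upstream and is
deliberately out of scope). Per term, the upper-tail hypergeometric
p = P(X ≥ k) with (N, K, n) = (universe, annotated, candidates). The
universe is the tested population — all proteins surviving the presence
filter — not the annotation's own union; an enrichment background must
match the selection population. Terms with K < 3 are skipped (untestable
tails). Two corrections mirror the two conventions of GO/pathway tooling:

- **FWER** by min-p permutation: random candidate sets of the same size are
  drawn uniformly without replacement (default 1000, seeded); the adjusted
  p of a term is the add-one fraction of permutations whose minimum raw p
  over all terms is ≤ the term's raw p. Monotone in raw p by construction;
  weak FWER control confirmed by simulation.
- **BH q-values** over all tested terms.

## Synthetic data

The generators define the validation conditions:

- **Endpoint**: control mean 8, SD 5 (comet-type % tail DNA variability),
  n = 10 per group, graded effects (4–10 units across A doses, 1–3 across B
  doses), and a configurable mixture interaction shift (0 additive,
  negative antagonistic, positive synergistic) on top of the additive
  expectation. Noise is normal on the raw scale by default; a lognormal
  family (group mean = median, SD on the log scale) exercises the ln
  branch. Truth records (expected group means) are emitted separately from
  the data so pipelines cannot read them by accident.
- **Proteome**: protein baselines lognormal (median 8 counts, log-SD 1),
  peptides per protein shifted-geometric (p = 0.35, capped at 12) so a
  realistic mass of proteins sits at 1–2 peptides and exercises the
  3-peptide rule; counts are gamma–Poisson (negative binomial,
  Var = μ + 0.1·μ²) per cell; a configurable fraction of proteins carries a
  ±log2FC fold change in all non-control conditions. A latent abundance
  matrix with a small per-run wobble (log-SD 0.1) accompanies the counts:
  intensity-dependent censoring (MNAR) thresholds per-sample quantiles of
  this latent scale — keeping the threshold well-defined under tied counts
  and letting censoring vary across replicates — while counts themselves
  are drawn from the clean mean so that dispersion 0 is exactly Poisson.
  MCAR dropout follows censoring; the expected missing fraction is
  q + r·(1−q).
- **Annotation**: random term sets of configurable size, plus an optional
  planted term annotating candidates at 80% versus 10% background.

What passing tests on these data do *not* show: real spectral counts have
correlated peptides within a protein, batch structure, and
replicate-pooling variance (three animals pooled per biological replicate),
none of which are modeled; the generator's missingness is exactly
MNAR+MCAR, whereas real MAR mechanisms are messier. Recovery rates here are
best-case figures for data meeting the model's assumptions.

## Reproducibility and problem sizes

Every random operation derives its stream from a single global seed via
`blake2b(seed:stage)` substreams, so toggling one pipeline stage never
shifts another's randomness; identical (config, inputs) give byte-identical
outputs, recorded in a manifest with input checksums. The validation suite
and the acceptance script use: 2000 additive simulations for calibration,
500 seeds per shift for antagonism recovery, 20 seeds × 1000 proteins for
DE error control, 10–20 seeds for imputation masking, 100 seeds for planted
enrichment, 2000 × n_mc=400 for Lilliefors level — sizes chosen to put
Monte Carlo standard errors well inside the asserted margins.

## Known limitations

- The IF significance rule is the interval-overlap construction defined by
  the reporting convention it reproduces; it is conservative (see above)
  and its α is approximate.
- The DE model is quasi-Poisson with moderated dispersion, not a full
  negative-binomial likelihood; with 3 replicates per condition its power
  at q < 0.01 is modest and that is a property of the design, not a bug.
- VSN here is a scale-calibration + glog reimplementation, not the full
  maximum-likelihood affine fit of the reference method.
- Enrichment takes annotations as flat, pre-propagated sets.
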