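# mixtox

Statistics for two-agent mixture ecotoxicology: Interaction Factor analysis
of factorial exposure studies, and a label-free spectral-count proteomics
pipeline, with synthetic-data generators that make every stage testable.

## The problem

Co-exposure studies — e.g. a mussel digestive-gland experiment crossing a
genotoxic PAH (benzo[a]pyrene) with a carbon nanomaterial (aqueous C60) —
ask whether a mixture's effect is the *sum* of its parts. `mixtox` answers
this at two levels:

**Endpoint level.** For a factorial design with control mean C,
single-agent means G_A and G_B and mixture mean G_AB, the Interaction
Factor

    IF = G_AB − G_A − G_B + C,    SEM_IF = √(SEM²_AB + SEM²_A + SEM²_B + SEM²_C)

measures the departure from additivity: IF < 0 antagonism, IF ≈ 0
additivity, IF > 0 synergism. The mixture interval `IF ± z·SEM_IF/√2` is
tested for overlap against the predicted-additive interval
`0 ± z·SEM_add/√2` (SEM_add = √(SEM²_A + SEM²_B + SEM²_C)); non-overlap at
α = 0.05 flags a significant interaction. Endpoint tables additionally get
the standard gatekept univariate treatment: Monte Carlo Lilliefors and
Bartlett gates, optional ln transform, one-way ANOVA with Tukey HSD and a
compact letter display, or Kruskal–Wallis when normality cannot be rescued.

**Proteome level.** Peptide spectral counts go through the standard
label-free workflow: 3-peptide identification filter → scaled aggregation
to proteins → replicate-presence filter → variance-stabilizing (glog)
normalization → mixed KNN + QRILC imputation of the MCAR/MNAR missingness →
per-protein quasi-Poisson GLM with library-size offsets and moderated
dispersion (candidate tier p < 0.05, confirmed tier BH q < 0.01) → spectral
index quantification, Venn overlaps across doses, and hypergeometric term
enrichment with permutation FWER and BH control.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Simulate a factorial comet-assay experiment with a built-in antagonistic
interaction (mixture means depressed by 12 units, ≈ 2.4 group SDs) and run
the Interaction Factor analysis:

```bash
mixtox simulate-endpoint --seed 4 --interaction-shift -12 --out ep.tsv
mixtox interaction --table ep.tsv --out itab.tsv
```

```
BaP_5+C60_1: IF = -14.97 ± 5.12 * (antagonistic)
BaP_50+C60_1: IF = -12.57 ± 4.69 * (antagonistic)
BaP_100+C60_1: IF = -13.12 ± 3.90 * (antagonistic)
```

Each row is one mixture group: the Interaction Factor, its half confidence
interval (95% CL/√2), a `*` when the mixture interval fails to overlap the
predicted-additive interval, and the resulting call. All three mixtures are
correctly recovered as significantly antagonistic — the planted shift (−12)
lies within each interval.

The same library functions are importable directly:

```python
from mixtox import GroupStats, analyze_mixture

res = analyze_mixture(GroupStats(5, 1), GroupStats(10, 1),
                      GroupStats(12, 1), GroupStats(14, 1))
res.if_value, res.sem_if, res.classification   # (-3.0, 2.0, 'additive')
```

The full pipeline (endpoint statistics + proteomics + enrichment) runs from
a YAML config:

```bash
mixtox run --config demo.yaml
```

```
mixtox run summary
==================
endpoint branch: nonparametric
  BaP_5+C60_1: IF = -16.25 ± 4.36 * -> antagonistic
  BaP_50+C60_1: IF = -14.41 ± 4.73 * -> antagonistic
  BaP_100+C60_1: IF = -12.84 ± 4.77 * -> antagonistic
proteomics treated: 50 candidate (p<0.05), 16 confirmed (q<0.01) of 126 tested
enrichment treated: 0 terms at q < 0.05
```

(the demo config plants 10% differentially expressed proteins at |log2FC| = 3
and no enriched term, hence the last line). Every run writes its tables,
a manifest with seeds and input checksums, and this summary to the output
directory; identical configs reproduce byte-identical outputs.

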