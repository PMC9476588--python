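# Methods

## Pathway model

Pathways are declared in a versioned YAML document
(`src/nitrocycle/data/pathways.yaml`) as ordered reaction steps with
OR-of-AND gene logic: each step lists alternative gene groups, a group being
the subunit genes of one enzyme variant. This single primitive expresses the
two structures the inference needs — complexes (dinitrogenase requires
*nifD* AND *nifK*) and alternatives (the Fe/Mo, Fe/V and Fe/Fe nitrogenase
subtypes, or the homologous urease cluster variants *URE*, *ureAB*,
*ureA*+*ureB*+*ureC*). Gene symbols are matched case-insensitively with
whitespace stripped; first-seen spellings are preserved for display.

The packaged registry covers biological nitrogen fixation (two steps:
dinitrogenase reductase *nifH*/*vnfH*; dinitrogenase
*nifD*+*nifK* / *vnfD*+*vnfK*+*vnfG* / *anfG*), urea hydrolysis (one
essential urease step), ammonium assimilation (GDH or GS–GOGAT, plus
aspartate transamination), and the ten essential-amino-acid (EAA)
biosynthesis routes. The EAA block spans 115 distinct genes across the ten
routes. Step granularity and gene composition follow KEGG module structure
for gut-relevant bacteria; where organisms bypass a step (direct
sulfhydrylation vs. transsulfuration in methionine synthesis, the
dehydrogenase shortcut in the diaminopimelate route), the bypass genes are
listed as alternatives of the steps they cover, so route-level logic stays
expressible in the per-step AND/OR form. All steps default to
`essential: true`: absence of any enzyme is treated as pathway-breaking,
which is the interpretation used for the missing *argF* in arginine
biosynthesis.

## Completeness, blockers, categories

A step is satisfied when some alternative group is fully covered by the
in-scope taxa. The default pooling is **pooled** (community
complementation: each gene of a group may come from a different core
taxon), because the scientific question is asked of the core community
collectively; **single_taxon** mode is available when within-genome
co-occurrence is required. Completeness is the exact rational
satisfied/total (Python `Fraction`; no float thresholds). Blockers are
unsatisfied essential steps; their reported gene gaps are the missing genes
per alternative group, sorted lexicographically for reproducibility.

Categories: `complete` (all steps), `almost_complete` (no essential blocker
and ≤ *tolerance* missing steps; tolerance defaults to 1 and is a config
knob, since "almost complete" has no canonical quantitative definition),
otherwise `incomplete`.

Transcriptional blockers are steps satisfied on the DNA layer but not the
RNA layer for the same stage; the report carries the DNA-supporting taxa
and the RNA gene gaps. Whether expression should be required in the *same*
taxon as the genomic copy is genuinely ambiguous for community data, so both
pooling modes apply here too; pooled is the default for the same reason as
above.

## Contributions

A taxon's contribution to a pathway is involved-steps / total-steps.
`any_gene` (default) credits a taxon that carries any gene appearing in a
step's alternatives — partial complex subunits count, which matches how
per-gene annotation bars credit taxa; `full_step` requires the taxon alone
to satisfy the step and is therefore never larger. Proportions are exact
fractions and depend only on presence, never on abundance magnitude.

## Annotation input and core-taxon selection

Input is long-form TSV (order, genus, species, gene, layer, stage,
abundance). Layer/stage vocabularies are closed with synonyms mapped at read
time ("G"→DNA, "T"→RNA, "larvae"→larva, …). Duplicate keys are aggregated
by summing abundance (logged). Abundances are not renormalised — only
ordering and positivity matter downstream. Presence is abundance strictly
greater than a threshold, default 0 (any detected annotation counts as
"mapped"); the threshold is exposed for noisier inputs.

Core taxa are the union, over each (layer, stage) in scope, of the top-k
taxa by summed abundance at the chosen rank; defaults rank=order, k=5,
layers={DNA, RNA}, stages={larva, adult}. Ties at rank k include all tied
taxa rather than breaking arbitrarily.

## Isotope and expression statistics

Tracer arithmetic uses the standard ¹⁵N conventions with the reference
ratio 0.003676 as a named, overridable constant; natural abundance 0.3663
atom% is consistent with it (0.3663/(100−0.3663) = 0.003676). Group
comparison is classic one-way fixed-effects ANOVA (scipy) followed by Tukey
HSD (scipy's studentized-range implementation) on the untransformed
response; a log-response can be applied upstream for heavy enrichment.
No multiple-testing correction is applied across tissues — tissues are
reported as independent comparisons, a known limitation.

The compact letter display assigns one letter per maximal clique of the
non-significance graph (edges join pairs with Tukey p ≥ α; Bron–Kerbosch
enumeration, fine for the handful of groups in a feeding trial). This
guarantees: significantly different groups never share a letter, and
non-significantly different pairs always share one. Transitivity conflicts
produce extra letters, never false merges. Letters are ordered by the
highest group mean in each clique, descending, so output is deterministic.

Relative expression is 2^−(Ct_target − Ct_reference); condition contrasts
use two-sided t-tests, Welch by default (variance homogeneity across pH
conditions is not assumed; a pooled-variance switch reproduces the
classical test). Degenerate zero-variance equal-mean inputs are reported as
p = 1 rather than NaN.

## Synthetic data

`simulate_community` plants a taxon × gene Bernoulli assignment matrix
(default 12 taxa, density 0.6) with an expressed subset (rate 0.8) and
log-normal per-stage abundances (σ = 1.5), emulating the heavy-tailed
order-level profiles of real gut tables. `simulate_annotation_table`
renders DNA rows from the assignment and RNA rows from the expression
matrix, flipping cells with independent Bernoulli dropout/spurious noise —
the simplest corruption adequate to stress blocker detection. With zero
noise every downstream statistic equals its planted closed form exactly.

`simulate_observed_pattern` is a fixed fixture encoding the qualitative
fly-gut result pattern: the full nitrogenase complement (*anfG*, *nifD*,
*nifK*, *nifH*) in the Enterobacterales metagenome with *nifH* alone on the
transcript layer, the urease cluster on both layers across core orders,
*argF* absent everywhere, and all other registry genes present. Order
weights spread each order's relative abundance across its genes so
order-level totals reproduce the intended community profile
(Enterobacterales dominant; Orbales leading the adult metatranscriptome).

The tracer generator draws tissue atom% as
`natural + f_eff · (diet − natural) + N(0, sd)` with the diet label at 5.17
atom%, where f_eff is the assimilated fraction f for the untreated
heavy-urea arm, f·(1−suppression) under antibiotics, and 0 on light urea.
Defaults f = 0.3, suppression = 0.6, sd = 0.1 atom%, n = 5 per arm — effect
sizes chosen as a realistic strong-incorporation regime, since the true
per-tissue magnitudes are not recoverable from published figures alone. The
qPCR generator draws Ct differences around planted per-condition shifts
(relative expression recovers 2^−shift in expectation).

What the generators do **not** emulate: read-level error, compositionality
of relative abundances, phylogenetic correlation of gene carriage, or
abundance-dependent detection. Passing tests therefore demonstrate the
engines' correctness against planted truth, not robustness to every
artefact of real annotation pipelines.

## Numerical and design choices

- Exact rational completeness/contribution values avoid float-comparison
  flakiness; floats are derived views for export.
- All generators are pure functions of (parameters, seed) using numpy's
  `default_rng`; identical seeds give byte-identical TSV exports.
- Monte-Carlo problem sizes: oracle equivalence on 1,000 random instances
  (≤ 6 genes/step, ≤ 6 taxa, exhaustive enumeration as the oracle); dropout
  recovery over 200 replicates of a ten-step benchmark pathway; null
  calibrations at 2,000 replicates. These sizes give stable rates while
  keeping the default suite quick to run.
- A nitrogenase subtype absent from a dataset (e.g., no Fe/V genes at all)
  is simply an uncovered alternative, not an error.
- Reports embed a config digest and registry version so outputs are
  reproducible from config + inputs alone.

## Known limitations

Presence/absence only — expression magnitude is never interpreted as
enzyme activity. Pathway definitions are a static curated fixture, not a
live KEGG query; organisms with unusual routes may need a custom registry
document. The per-tissue ANOVA treats tissues independently (no factorial
tissue × treatment model), and ELISA-style activity values are treated as
opaque inputs to the two-condition test.
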