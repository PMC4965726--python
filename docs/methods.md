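# Methods

## Prediction model

`scafpred` treats scaffolding as a structural property of an undirected
protein-protein interaction (PPI) graph plus three side resources: per-
protein domain architectures (ordered domain-family instances, optionally
with residue coordinates), a set of unordered interacting domain-family
pairs (DDI), and a catalog of protein complexes.

For a candidate scaffold *s*, a domain instance *r* of *s* "mediates" the
edge *s–p* when family(*r*) forms a DDI pair with any family carried by
*p* (homotypic pairs count). Criterion 2 asks for a partner pair
(*p₁, p₂*) with mediating regions *r₁ ≠ r₂*; criterion 3 asks for a
complex containing {*s, p₁, p₂*} where both partners are also direct
interactors of *s*. The classifier is purely existential: adding a DDI
pair or a complex can promote a protein (none → III/II → I) but never
demote it, and the engine's output is checked against an exhaustive
(scaffold, partner, partner, region-assignment) enumerator in the test
suite.

Assumptions worth stating:

* the PPI graph is unweighted and undirected; confidence scores and
  directionality are out of scope;
* self-interactions are stored but never counted as partners — a scaffold
  must recruit two *other* proteins, and the literature on homodimeric
  scaffolding is too thin to justify an exception;
* a protein absent from the domain table has an empty architecture. It can
  still be Type III: domain and DDI resources are known to be incomplete,
  and complex evidence should not be held hostage to them;
* partner-partner interaction is *not* required (the classical definition
  of a scaffold demands partners that interact with each other; the
  criteria implemented here deliberately do not, to admit non-classical
  scaffolds).

## Configuration points and their defaults

* `region_semantics` (default `instance`): whether "different domain
  regions" means different domain *instances* (two copies of one family
  are two physical binding surfaces) or different *families*. The
  family-level reading matches a pipeline that only knows family content;
  the instance-level reading is the physically faithful default. Both are
  implemented and oracle-tested.
* `joint_witness` (default `True`): Type I demands one partner pair
  satisfying criteria 2 and 3 *simultaneously*. This is the stricter and
  biologically coherent reading — the pair that is co-recruited on
  distinct regions is also seen together in a complex. The independent
  reading (`False`: each criterion satisfied by some pair) is available as
  a flag.
* `require_partner_domain_known` (default `True`): strictly, a partner
  with no domain data cannot contribute criterion-2 evidence. The lenient
  mode (`False`) lets such a partner bind any scaffold region whose family
  occurs in the DDI network at all; it exists for exploring sensitivity to
  missing domain annotation and is never used in the defaults.
* Witnesses are stored per partner *pair*, not per region assignment; one
  deterministic representative assignment is kept (regions ordered by
  lowest copy index, then family; the lexicographically smallest complex
  id). This bounds output size on dense neighborhoods; larger assemblies
  can be reconstructed downstream from the per-pair witnesses.
* Identifier handling is opaque and case-sensitive; optional isoform
  suffix stripping (`P12345-2` → `P12345`) is a parser flag, off by
  default.

## Evaluation and statistics

The confusion table is computed inside the gold universe only (predictions
outside both gold lists are ignored); a rate whose denominator is zero is
reported as absent, never as 0. Percentages are formatted with
round-half-up at one decimal.

Association tests use the uncorrected Pearson chi-square at df = 1
(`scipy.stats.chi2_contingency`, Yates correction available behind a flag
but off by default, as the uncorrected statistic is what 2×2 tables of
this size conventionally report), with risk ratio (a/(a+b))/(c/(c+d)) and
odds ratio ad/bc; rows are group membership, columns trait status. With a
zero off-diagonal cell the ratios are reported absent while the statistic
is still computed. A closed-form identity, n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
serves as a second oracle in the tests.

Enrichment is the hypergeometric upper tail P[X ≥ k] (identical to
one-sided Fisher, which is offered as an alternative engine); terms with
zero foreground hits are skipped. Multiple-testing correction is
Bonferroni or Benjamini-Hochberg via `statsmodels`; the BH step-up
recurrence is pinned by a hand-computed example in the tests. The default
background is every protein in the loaded annotation map, overridable with
an explicit universe. Both corrections are provided because both are in
routine use for this kind of annotation screening.

Partner similarity counts a scaffold as "matched" when it shares ≥ 1
annotation term with ≥ 1 partner in scope. The default scope is the
witness partners — the proteins the model says the scaffold recruits;
`all_partners` widens to every interactor and can only increase the
counts.

## Synthetic data generator

The generator emulates the structure the predictor keys on, not real
biology: each planted Type I motif is a scaffold with two distinct domain
families, two single-domain partners DDI-linked to *different* scaffold
families, both edges, and a triad complex; Type II omits the complex;
Type III keeps the complex but gives the scaffold a single domain instance
(so distinct-region recruitment is impossible by construction); hub decoys
have one domain and `hub_degree` partners all DDI-linked through it.
Domain families are drawn from a disjoint namespace per motif, so motifs
cannot cross-talk through the DDI set. Background proteins carry families
that occur in no DDI pair and are wired Erdős–Rényi-style (default edge
probability 0.02 over pairs touching a background protein — sparse, so
chance motifs are effectively impossible; a consistency pass nevertheless
re-labels any non-scaffold protein that genuinely satisfies the criteria).
`ddi_dropout` and `complex_dropout` delete planted evidence to emulate
incomplete resources: dropping complexes moves Type I toward Type II,
dropping DDI pairs moves it toward Type III. Annotations give every
protein at least one term, and scaffold-partner term agreement is planted
per scaffold at `annotation_match_rate` (default 0.8, in the range of the
agreement levels reported for curated localization data).

Default dataset size — 5/7/3 planted scaffolds, 4 hub decoys (degree 4),
50 background proteins — keeps each dataset a ~110-protein graph: large
enough that background wiring is non-trivial, small enough that the
brute-force oracle can verify every instance. What passing tests show is
that the engine implements the criteria exactly; they do not show that the
criteria find true scaffolds in a real interactome, where domain and
complex coverage, edge noise and degree distributions are far from this
idealization.

## Numerical and degenerate-input choices

* All file readers are deterministic in the file bytes; malformed lines
  are logged and skipped, fatal only when *no* line parses.
* A 2×2 table with an all-zero grand total is unrepresentable; chi-square
  additionally requires all four marginals positive.
* p-values are validated into (0, 1] before adjustment.
* The generator is driven by one `random.Random(seed)`; identical seed and
  config give byte-identical output files (all writers sort their rows).

## Known limitations

* Predictions are unscored (binary); no reliability ranking, ROC/PR.
* Recruitment of more than two partners is represented only through
  multiple witness pairs, not as a first-class assembly object.
* The GO hierarchy is not traversed; localization terms are consumed
  already rolled up to compartments via a pre-built mapping.
* Gold-standard list construction (literature curation) is upstream of
  this package; the evaluation consumes plain accession lists.
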