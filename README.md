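# scafpred

Scaffold proteins organize signaling and metabolic reactions by physically
assembling two or more partner proteins into one functional unit. Unlike
hub proteins — whose many partners *compete* for the same binding surface —
a scaffold holds distinct partners *simultaneously*, on distinct binding
regions. `scafpred` predicts scaffold-protein candidates from a protein
interactome and characterizes them, for systems-biology users working with
protein-protein interaction (PPI), domain, and complex resources.

## Method

A protein *s* is a scaffold candidate when it satisfies criterion 1 plus
criterion 2 and/or 3:

1. **Multi-partner interaction** — *s* has direct PPI edges to at least two
   other proteins (self-interactions never count).
2. **Distinct-region recruitment** — there are partners *p₁, p₂* and domain
   instances *r₁ ≠ r₂* on *s* such that family(*r₁*) forms a known
   domain-domain interaction (DDI) with a family of *p₁*, and family(*r₂*)
   with a family of *p₂*. Requiring *different* regions filters out hubs,
   whose partners all bind one region competitively.
3. **Complex co-membership** — some annotated protein complex contains
   *s*, *p₁* and *p₂* together (both partners still interacting with *s*).

Candidates are classified **Type I** (criteria 2 and 3; by default the same
partner pair must satisfy both), **Type II** (criterion 2 only) or
**Type III** (criterion 3 only). Each prediction carries *witness pairs*:
the recruited partners with the mediating scaffold regions and/or the
shared complex.

Around the predictor sits the evaluation layer: confusion-matrix metrics
against gold-standard positive/negative lists (precision, sensitivity,
specificity, ...), hypergeometric term enrichment with Bonferroni or
Benjamini-Hochberg correction, scaffold-partner annotation agreement per
type class, and 2×2 association statistics (Pearson chi-square without
continuity correction, risk ratio *(a/(a+b))/(c/(c+d))*, odds ratio
*ad/bc*) for disease-gene and drug-target analyses.

A seeded synthetic-data generator plants Type I/II/III motifs and hub
decoys with full ground truth, so every stage can be exercised end to end
without external databases.

## Worked example

```sh
scafpred simulate --seed 42 --outdir fixtures
scafpred predict --ppi fixtures/ppi.tsv --domains fixtures/domains.tsv \
    --ddi fixtures/ddi.tsv --complexes fixtures/complexes.gmt -o predictions.tsv
scafpred evaluate --predictions predictions.tsv \
    --gold-pos fixtures/gold_positive.txt --gold-neg fixtures/gold_negative.txt \
    --report report.json
scafpred similarity --predictions predictions.tsv \
    --annotations fixtures/localization.gmt -o table.tsv
```

prints

```
wrote 9 files to fixtures (I=5 II=7 III=3 hubs=4)
15 scaffold candidates (I=5 II=7 III=3)
TP=15 FP=0 FN=0 TN=54 precision=100.0% sensitivity=100.0% specificity=100.0%
Type I: 5 total, 5 known (100.0%), 5 matched (100.0%)
Type II: 7 total, 7 known (100.0%), 5 matched (71.4%)
Type III: 3 total, 3 known (100.0%), 2 matched (66.7%)
```

The simulated dataset plants 5 Type I, 7 Type II and 3 Type III scaffolds
plus 4 hub decoys among 50 background proteins; the noise-free run recovers
exactly the planted candidates (15 true positives, no false positives — the
hubs land among the 54 true negatives). The similarity table reports, per
type class, how many scaffolds carry localization annotation ("known") and
how many share a term with a recruited partner ("matched"; planted
agreement rate 0.8). The first prediction rows:

```
#scaffold  type_class  n_witnesses  p1       p2       region1     region2     complex_id
T1S0000    I           1            T1A0000  T1B0000  F1S0000A.1  F1S0000B.1  CPX10000
```

Association statistics on plain accession lists:

```sh
scafpred associate --group scaffolds.txt --trait disease_genes.txt \
    --universe proteome.txt --report assoc.json
```

For example, a group of 616 scaffolds of which 188 are disease genes, in a
20233-protein universe with 4950 disease genes, gives chi-square 12.6
(p ≈ 4e-4), risk ratio 1.26 and odds ratio 1.37: disease genes are
significantly over-represented among the scaffolds.

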