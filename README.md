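# gseaconcord

Concordance analysis of two continuous proliferation markers against bulk
transcriptomes, built for the lung neuroendocrine tumor (NET) setting where
tumor grading rests on the mitotic count while the Ki-67 labelling index is
a candidate complementary criterion. The scientific question the package
operationalizes: do the two markers track the same transcriptional programs
(in which case adding the second to a grading scheme is redundant), or do
they capture different biology?

## What it computes

Given a genes × samples matrix of log2(TPM+1) expression, a per-sample
phenotype table (mitotic rate per 2 mm², Ki-67 %, histological subtype) and
a GMT gene set collection, the pipeline runs — for the whole cohort and per
subtype:

1. **Marker concordance** — Spearman ρ between the two markers.
2. **Per-gene correlation profiles** — Spearman ρ of every gene's
   expression with each marker, plus a strength ranking (descending |ρ|).
3. **Rank-shift analysis** — for a focal gene set (e.g. cell-cycle genes),
   Δrank = |rank_A − rank_B| and Δρ = |ρ_A − ρ_B| per gene.
4. **Correlation-ranked GSEA** — genes ranked by signed ρ; each set S of
   size k in a universe of N genes is scored with the weighted
   Kolmogorov–Smirnov running sum

       RS(i) = Σ_{j≤i, j∈S} |r_j|^p / N_R  −  #{j≤i, j∉S} / (N − k),
       N_R = Σ_{j∈S} |r_j|^p,

   the enrichment score ES being the running-sum value of maximum |·|
   (default weight p = 1). Significance comes from a permutation null
   (default: 10000 random same-size gene subsets), sign-matched add-one
   p-values, and Benjamini–Hochberg FDR across the retained sets.
5. **Pathway concordance** — significant pathways (q < 0.10) partitioned
   into common and marker-specific groups, split by ES sign.
6. **Leading-edge overlap** — per marker, the union of leading-edge genes
   over commonly enriched pathways, intersected within and across sample
   groups.

A seeded synthetic-cohort generator (`gseaconcord.simulate`) emulates the
study design — 28 samples (20 carcinoid + 8 LCNEC), correlated marker
latents with an overall rank correlation of 0.83, planted
shared/marker-specific pathway signals — and ships a ground-truth manifest
so detection can be scored.

## Worked example

```python
import gseaconcord as gc

ds = gc.generate_dataset(gc.SimulationConfig(effect_size=1.5, seed=42))
model = gc.ProliferationConcordance(
    ds.expression, ds.phenotypes, ds.gene_sets,
    params=gc.GseaParams(n_permutations=1000, seed=0),
)
results = model.fit()
print(results.summary())
results.save("out/")          # TSV tables + run manifest
```

prints

```
Proliferation-marker concordance analysis
=========================================================
markers: mitotic_rate (A) vs ki67 (B)
genes: 2000   gene sets: 100
GSEA: p=1, 1000 gene-permutations, FDR < 0.1

group          n  rho(A,B)  enr A  enr B  common  spec A  spec B   LE∩
----------------------------------------------------------------------
all           28     0.847     15     15      15       0       0   739
carcinoid     20     0.617     13     19      12       1       7   439
LCNEC          8     0.429     23     26      14       9      12   212
```

Reading the table: across all 28 samples the two markers correlate at
ρ = 0.85 and every enriched pathway is shared (`common` = both markers'
significant lists intersected by name; `spec A/B` = pathways significant
for only one marker; `LE∩` = leading-edge genes common to both markers over
the shared pathways). Within subtypes the marker correlation drops and
marker-specific pathways appear — the pattern the concordance report is
designed to surface. The cohort here is synthetic, with 15 planted
proliferation-linked sets among 100; the 15 pathways recovered for both
markers in the `all` analysis are exactly those.

The same workflow is scriptable from the shell:

```bash
gseaconcord simulate --seed 1 -o cohort/
gseaconcord run --expression cohort/expression.tsv \
    --phenotypes cohort/phenotypes.tsv --gmt cohort/gene_sets.gmt \
    -o out/ --permutations 10000 --seed 1
gseaconcord gsea ... --marker ki67 -o ki67.tsv   # single-marker run
gseaconcord concord --table-a mi.tsv --table-b ki67.tsv
```

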