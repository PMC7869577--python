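# Methods

## The analysis

The pipeline asks whether two continuous proliferation markers measured on
the same tumors — here the mitotic count per 2 mm² and the Ki-67 labelling
index — are concordant at the transcriptome level. It answers in three
layers: (i) the marker–marker rank correlation; (ii) per-gene Spearman
correlation profiles against each marker, with a rank-shift table over a
focal gene set quantifying how differently the two markers order those
genes; (iii) gene set enrichment on the correlation-ranked gene lists,
compared between markers as common vs marker-specific pathways and as
overlapping leading-edge gene sets.

Spearman correlation is used throughout because both markers are bounded,
skewed quantities whose relationship with expression is expected to be
monotone but not linear; rank correlation is also invariant to the
log2(TPM+1) transform applied to expression, which the test suite asserts.

### Enrichment score

Genes valid for ranking (non-constant expression across the analyzed
samples) are sorted by signed ρ, descending, ties broken by gene id. For a
set S with k = |S ∩ universe| of N ranked genes, the running sum after
position i is

    RS(i) = Σ_{j≤i, j∈S} |r_j|^p / N_R  −  #{j≤i, j∉S} / (N − k)

with N_R = Σ_{j∈S} |r_j|^p. ES is RS at the position of maximum |RS|
(earliest position on exact ties); the leading edge is the member genes at
or before the peak (ES > 0) or at or after it (ES < 0). The default weight
exponent is p = 1 (hit increments proportional to |ρ|); p = 0 gives the
unweighted two-sample KS-type statistic and is what the exhaustive test
oracles exercise alongside p = 1. If every member statistic is exactly
zero under p > 0, the set falls back to p = 0 with a warning rather than
dividing by zero.

The production scorer evaluates only the candidate positions where a
running-sum extreme can occur (at a hit, or just before one), in closed
form chosen to be bitwise-identical to the full per-position evaluation;
the test suite verifies exact equality against an independently coded
exhaustive oracle on randomized instances.

### Permutation null, p-values, FDR

Two null models are provided. **Gene mode** (default): each permutation
draws a uniformly random gene subset of the same size and scores it on the
fixed ranked list; sets of equal size share one pooled null of
`n_permutations` draws. This matches the scale of a 1499-pathway collection
and is cheap enough for 10000 permutations. **Sample mode**: marker values
are permuted across samples and the entire profile → ranking → ES chain is
recomputed per permutation; this preserves inter-gene expression
correlation and is the stricter null for small cohorts, at ~N_perm times
the cost of the full analysis.

Nominal p-values use a sign-matched add-one estimator: among null samples
with the same sign as the observed ES (zeros count for both signs),
p = (1 + #{|null| ≥ |ES|}) / (1 + #same-sign), guaranteeing p ∈ (0, 1] and
matching standard permutation-test practice. A normalized ES
(ES / mean |null ES| of matching sign) is reported as auxiliary output
only; significance thresholds operate on the FDR of the nominal p-values.

FDR control is Benjamini–Hochberg step-up, implemented directly
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1) and cross-checked in tests
against both a quadratic-time brute-force scan and
`statsmodels.stats.multitest`. Adjustment is performed within each
(sample-group, marker) run — i.e. across the retained pathways of that one
analysis — and pathway significance uses the strict inequality q < 0.10 by
default.

### Concordance and leading edges

"Common" pathways between two markers are intersected **by name,
regardless of ES sign**; sign agreement over the common set is reported as
an auxiliary count. This choice is deliberate: with correlated markers the
same pathway occasionally enriches from opposite ends of the two rankings,
and folding sign into the intersection would silently change the common
counts. All set-cardinality identities (n_enriched = n_pos + n_neg,
n_specific = n_enriched − n_common, |A ∪ B| = |A| + |B| − |A ∩ B|) hold by
construction and are property-tested.

Leading-edge comparison pools, per marker, the leading-edge genes of all
commonly enriched pathways into one union set, then reports intersection
and marker-exclusive counts per sample group, plus pairwise intersections
of the per-group pooled sets across groups.

### Rank-shift analysis

Correlation *strength* ranking uses descending |ρ| with lexicographic tie
breaks; Δρ is the absolute difference |ρ_A − ρ_B|. Signed ρ values are
retained in every output so users can re-rank under a signed convention.
Genes with constant expression are excluded from ranking (flagged, not
assigned ρ = 0, which would distort rank shifts).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale by default: 28 samples (20 carcinoid + 8 LCNEC), 2000
genes (scalable; real cohorts run ~19,000 protein-coding genes), 100 gene
sets of 15–80 genes with 5 shared, 5 mitotic-specific and 5 Ki-67-specific
planted sets.

Per sample, a latent proliferation component u ~ N(0, 1) is shifted by
`subtype_shift` (default 4.36) for LCNEC samples; marker latents are
a = u + ε_a and b = sign(ρ)·u + ε_b with equal, independent noise. The
noise variance is solved deterministically (Gauss–Hermite quadrature plus
Brent root-finding, no sampling) so the **population Spearman** of (a, b)
under the two-component mixture equals `target_marker_rho` (default 0.83
— the rank-correlation scale on which marker concordance is reported).
With these defaults the within-subtype correlation lands near 0.55,
reproducing the overall-strong / within-subtype-moderate structure the
analysis is designed around; the default subtype shift was solved jointly
with that constraint, not fitted to data.

Observed markers go through strictly monotone links, so
Spearman(mitotic rate, Ki-67) equals Spearman(a, b) exactly:

* mitotic rate = 130·logistic(−3.44 + 0.81·a) — exponential at the low
  (carcinoid) end and saturating so counts stay within a plausible 0–130
  mitoses per 2 mm² band (carcinoid means land near a few mitoses, LCNEC
  means in the tens), matching published subgroup summaries as soft
  calibration targets only;
* Ki-67 = 100·logistic(−2.44 + 0.98·b) percent.

Planted-set genes load with slope `effect_size` (default 1.0, in
expression-SD per latent-SD units) on the standardized u / a / b for
shared / a-only / b-only status, plus N(0, noise_sd²) noise
(noise_sd = 1); background genes are baseline + noise, baselines uniform
on [1, 8]. Planted sets occupy disjoint gene blocks so every gene has one
ground-truth status; null sets sample from the unplanted background. The
whole matrix is shifted by a single global constant to be non-negative
(log2(TPM+1)-like); constant shifts change no correlation. One RNG stream
with a fixed draw order makes a dataset a pure function of its config.

What the generator does **not** emulate: count-level sequencing noise,
batch effects, gene–gene correlation beyond the planted latent structure,
heavy-tailed expression marginals, and any real NET biology beyond the
correlation/enrichment skeleton. Passing recovery tests therefore show the
machinery detects the planted structure at the stated effect sizes — not
that equivalent power holds on real cohorts, where inter-gene correlation
inflates the gene-permutation null in particular (sample mode exists for
that reason).

## Numerical and design choices

* **Determinism**: every stochastic step is seeded; the orchestrating model
  derives one sub-seed per (group, marker) run from the top-level seed.
  Identical config + seed reproduces output trees byte for byte (tested);
  floats are written with 12 significant digits.
* **Tie-breaks**: average ranks inside Spearman; lexicographic gene id for
  ranking ties; earliest position for running-sum peak ties.
* **Group analyses** reuse the full gene universe; genes constant within a
  subgroup are dropped (flagged) for that group only. Groups with fewer
  than 3 samples are skipped with a warning rather than erroring the run —
  subtype groups at LCNEC-like sizes are expected and legitimate.
* **Set-size filters** default to min 1 / no max, mirroring analyses run
  against a full canonical-pathway collection; both are configurable.
* **WHO grading** (`grade_by_who`) encodes the mitotic-count rule
  (typical < 2 without necrosis; atypical 2–10 or necrosis; high grade
  > 10) and, under the modified scheme, flags rates in (10, 20] for
  pathology review instead of reclassifying: reclassification requires
  morphology/IHC evidence a count alone cannot supply.
* **Hot-spot vs slide-average Ki-67**: the phenotype table carries a single
  `ki67` column; which measurement convention feeds it is the user's
  choice and does not alter any algorithm.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at reduced scale (hundreds of genes, tens of
sets, ≤ 1000 permutations) chosen so the whole suite completes in well
under a minute while still exercising every code path; the planted-recovery
check runs 20 replicates at 2000 genes / 100 sets / 1000 permutations with
100 samples and effect size 2, the power point at which shared-set
detection is expected to exceed 80% for both markers. The acceptance
script uses 5 such replicates plus a 200-null-set calibration run; these
sizes are the package's own reporting choices and are trivially scalable
upward through the config objects.

## Known limitations

* Gene-mode permutation assumes exchangeable genes; correlated gene blocks
  make it anti-conservative on real data (use sample mode for small
  cohorts when wall-time allows).
* The BH q-values inherit the discreteness of permutation p-values; with
  few permutations the q distribution is coarse.
* Pooled nulls per set size ignore the identity of set members; two
  same-size sets share a null even if their gene weights differ under
  p = 1. This is the standard trade-off for gene-mode speed.
* The generator's planted sets are disjoint; real pathways overlap
  heavily, which induces correlated enrichment statistics the recovery
  rates here do not reflect.
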