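# Methods

This note documents the statistical procedures `polyqnet` implements, the
design choices made where several reasonable options existed, what the
synthetic data generator does and does not emulate, and the problem sizes
the test suite and acceptance script run at.

## Data model

Expression is handled per donor as a probes × samples matrix of log-scale
intensities with aligned probe and sample annotations. Samples carry a
donor id, an anatomical structure label and an MNI millimetre coordinate.
Genes are keyed by an opaque `gene_id`; the nine polyQ genes are matched
case-sensitively by `gene_symbol`. Rows with unparseable values are dropped
at load time with a logged count: per-donor Pearson correlations require
complete vectors, and imputing microarray intensities would manufacture
co-expression, so dropping the probe row for that donor is the conservative
choice.

## Probe collapse

Genes measured by several probes are reduced to one probe, used for every
donor:

- one probe: kept;
- two probes: the higher mean per-donor sample variance (unbiased, n−1);
- three or more: the highest connectivity — per donor the sum of the
  probe's Pearson correlations with all probes of *other* genes, then
  averaged over donors.

Choices within this rule: connectivity sums **signed** correlations (the
rule is stated as a plain sum; an absolute-value mode exists as
`connectivity_absolute`), ranges over other genes' probes only (sibling
probes carry redundant signal; `connectivity_scope="all_probes"` switches
this), and is computed over all of a donor's samples because collapse
precedes any regional restriction. Ties select the lexicographically
smallest probe id, which makes selection independent of input order.
Zero-variance probes get r = 0 against everything.

A consequence of the additive-noise data model worth knowing: for 2-probe
genes the max-variance rule favours the *noisier* probe (its total variance
is signal + noise), whereas the connectivity rule for 3+-probe genes
favours the *least* noisy probe. Both follow directly from the stated rule;
the property tests assert the connectivity case.

## Region assignment

A sample is inside the region of interest iff its coordinate, mapped
through the inverse of the mask affine and rounded to the nearest voxel
half-away-from-zero, lands on an in-bounds voxel equal to 1. The mask is
binary, so no interpolation is performed; coordinates outside the volume
are simply "outside" (atlas samples span the whole brain, masks cover a
sub-volume). Donors contribute to a region's analysis only with at least
`min_region_samples = 3` samples there (Pearson r is undefined below 3
points); excluded donors are logged and the consensus denominator adjusted.

## Consensus differential expression

Each donor is tested separately: two one-tailed Mann–Whitney U tests of
inside vs outside samples at `de_alpha = 0.025` per tail. The exact null
distribution is used when the combined group size is ≤ 12 and tie-free;
otherwise the normal approximation with midrank tie correction and
continuity correction. A gene is differentially expressed when at least
`min_brains = 5` of the 6 donors are significant in the **same** tail;
opposing tails never combine, because the output partitions genes into up-
and downregulated sets. An optional per-donor Bonferroni mode
(`bonferroni_de`) divides the per-tail alpha by the gene count; the raw
per-tail rule is the default. No FDR across genes is applied — the 5-of-6
same-tail consensus is itself a far stricter filter than the per-test
alpha (the null probability of 5-of-6 one-sided hits at 0.025 is ≈ 1e-7).

## Consensus co-expression

Per region, the gene × gene Pearson matrix is computed per donor over that
region's samples and averaged entry-wise with a plain arithmetic mean —
the consensus is defined as an average of correlations, not of z-scores; a
Fisher-z averaging mode exists behind `fisher_z_consensus` for users who
prefer the bias-corrected pooling. Genes flat on a subset get r = 0 rather
than being dropped, keeping matrix dimensions constant across donors.
Partnership uses a **strict** inequality at `coexpr_threshold = 0.5`; a
consensus r of exactly 0.5 is not a partner. The seed-gene network
contains the nine polyQ genes and their partners, with polyQ–partner and
polyQ–polyQ edges only (no partner–partner edges), exported as GEXF and
GraphML with `is_polyq`, `partner_of`, `gene_symbol` and regional
mean-expression node attributes (mean over a region's samples per donor,
then over donors).

## Relationship tiers and family overlaps

For each of the 36 unordered polyQ pairs per region:

1. **direct** — consensus r with the strict threshold flag;
2. **shared** — partner-set overlap tested one-tailed against the
   hypergeometric upper tail with the post-collapse gene universe as the
   population. The two tested genes are removed from both partner sets and
   from the universe (a gene cannot be its own partner); this exclusion is
   switchable (`exclude_pair_from_partner_sets`). The 36 raw p-values are
   compared to `fisher_alpha = 0.05` without multiplicity adjustment by
   default (a BH option exists) — the flags mirror a reported raw-p
   convention;
3. **functional** — the count of enriched annotation term ids the two
   partner sets share, flagged at `min_shared_terms = 10`.

Family overlaps are plain set intersections of a partner set with a named
gene family from the annotation collection (`FAMILY_*` terms in the
synthetic GMT).

## Enrichment

Over-representation uses the hypergeometric upper tail per term, terms
intersected with the background universe first, Benjamini–Hochberg across
all tested terms of the collection, and the pass rule
`adjusted p < 0.05 AND overlap ≥ 2`. This deliberately replaces
service-based annotation scoring (EASE-style penalised Fisher scores,
term clustering): absolute p-values therefore differ from such services,
but every downstream quantity consumes only the *set* of passing terms,
which needs a consistent, reproducible definition rather than a particular
scoring heuristic. Annotation collections are caller-supplied GMT files.

## Synthetic data generator

The generator emulates the statistical shape of a six-donor spatial
expression atlas:

- **Donors and regions.** Six donors with the published per-donor sample
  counts for the mask region (280/183/99/139/125/147, total 973) and seven
  anatomical structures, plus a rest-of-brain filler sized so the grand
  total is 3,702 samples and each donor's total falls in the atlas's
  363–946 range. Counts are reproduced exactly in the annotation, and mask
  region samples are placed at jittered mask-voxel centres (jitter < half
  a voxel, so assignment recovers the planted counts exactly).
- **Correlation blocks.** A block of genes at correlation ρ shares a
  latent factor: gene value = √ρ·factor + √(1−ρ)·noise, giving an exact
  population within-block correlation. Default blocks: 40 genes at ρ = 0.7
  containing ATN1, ATXN2 and HTT, and 30 genes at ρ = 0.6 containing
  ATXN1 — the planted analogue of a strongly connected polyQ trio plus a
  weaker second module.
- **Regional shifts.** DE genes get a mean shift of δ noise-SDs inside the
  mask region in every donor (default 60 up and 120 down at δ = 1, the
  published 711:2101 up:down imbalance scaled to a 1,000-gene universe).
  Shifted genes are drawn outside the correlation blocks so the two kinds
  of planted structure do not confound each other.
- **Probes.** Each gene carries 1–4 probes (P = 0.50/0.25/0.15/0.10),
  probe value = gene value + N(0, σ_p) with σ_p ~ U(0.1, 0.5) fixed per
  probe. The range is chosen so probe-level technical noise is small
  relative to biological variation: attenuation of a gene-gene correlation
  is 1/√(1+σ²) per gene, so the worst-case planted ρ = 0.7 pair still
  averages ≈ 0.56 — above the 0.5 partner threshold — while probe
  selection remains non-degenerate.
- **Gene count.** Default 1,000 genes. This is a deliberate desk-scale
  stand-in for a ~20,000-gene atlas: consensus matrices are quadratic in
  gene count, and every planted property (block recovery, null rates, DE
  recovery) is scale-free in the gene dimension.

What the generator does **not** emulate: microarray intensity
distributions and batch effects, spatial autocorrelation of expression
between neighbouring samples, region-specific co-expression (planted
blocks are global, so block recovery tests the consensus machinery, not
regional specificity), donor heterogeneity in correlation strength, and
hemispheric structure. Passing tests therefore demonstrate that the
*machinery* recovers known structure under clean location-shift and
latent-factor alternatives — not that real-atlas headline numbers are
reproduced, which would require the full atlas and the original MRI mask.

## Numerical choices

- Half-away-from-zero voxel rounding; declared, not inferred from any
  particular imaging convention.
- Mann–Whitney exact/asymptotic crossover at combined n = 12 (`mw_exact_cap`).
- Consensus matrices are symmetrised ((M + Mᵀ)/2) and their diagonal fixed
  to 1 after averaging to absorb floating-point asymmetry.
- All thresholds are strict where stated strict (r > 0.5), and inclusive
  where stated inclusive (≥ 10 shared terms, ≥ 2 genes per term).
- TSV outputs are sorted on their first column and floats printed with
  `%.10g`, making reruns byte-identical; GEXF/GraphML carry a
  writer-inserted date and are excluded from byte-level determinism
  checks.
- Hypothesis property tests run derandomised; every stochastic fixture is
  explicitly seeded.

## Problem sizes used by the test suite and acceptance script

Block recovery runs at 2 × 20 block genes in a 500-gene universe, 6 donors
× 100 samples, single low-noise probes (σ_p ∈ [0.05, 0.15]) so that the
measured quantity is consensus-threshold recovery rather than probe
attenuation. Shift recovery runs at 2,200 genes (100 up + 100 down planted,
2,000 null), 6 donors × (50 inside + 150 outside). The end-to-end pipeline
runs at the full default conditions (1,000 genes, 3,702 samples, nine
regions). These sizes keep the whole suite in the tens of seconds while
leaving Monte-Carlo margins wide (e.g. the consensus SE of a planted
ρ = 0.7 entry at these sizes is ≈ 0.02, an order of magnitude below the
0.2 gap to the partner threshold).

## Known limitations

- The consensus average weights donors equally regardless of their sample
  counts; this mirrors the definition implemented, but donors with few
  regional samples contribute noisier matrices (mitigated by the
  3-sample floor, visible in the recorded donor roster).
- Enrichment p-values are not comparable to service-based annotation tools
  (see above); only passing-term *sets* are meant to be consumed.
- The 2-probe variance rule's behaviour under additive probe noise (see
  Probe collapse) means collapse quality on 2-probe genes depends on the
  real data's noise structure, not on anything the package can verify.
- No covariate adjustment, no FDR across genes in DE, no partial
  correlations or module detection — the implemented statistics are the
  plain consensus definitions.
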