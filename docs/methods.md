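# Methods

## Model and procedure

`clonalqc` treats CH calling as a filtering problem over a long-format
cohort table of per-sample variant records (one row per sample × tissue ×
allele). Filtering is deterministic given the table and a `FilterConfig`;
the permutation analysis wraps the filter in a resampling loop to choose
thresholds that make the call set stable under subsampling of the cohort.

### Filter tiers and comparator semantics

Tiers run population → technical → functional → individual. Every criterion
is evaluated for every blood record — removal in an early tier does not
short-circuit later tiers — so each record carries a complete, auditable
list of reason codes, and the surviving records are exactly those with an
empty list.

Comparator boundaries are fixed as follows (the mixture of strict and
non-strict comparisons is deliberate and matches common usage):

| parameter | pass condition | default |
|---|---|---|
| `vaf_min` / `vaf_max` | `vaf_min ≤ VAF ≤ vaf_max` (boundaries pass) | 0.02 / 0.35 |
| `dp_min` | `DP > dp_min` (strict) | 20 |
| `alt_ad_min` | `Alt_AD ≥` | 5 |
| `saf_min`, `sar_min` | `SAF ≥`, `SAR ≥` | 3, 3 |
| `sor_max` | `SOR ≤` | 3.0 |
| `tlod_min` | `TLOD ≥` | 6.3 |
| `prevalence_max` | removed iff prevalence `>` (equality passes) | 0.10 |
| `gnomad_max` | removed iff gnomAD AF `>` | 0.001 |
| `paired_alpha` | kept iff one-sided p `<` | 0.05 |

`vaf_max = 0.35` removes germline heterozygotes while tolerating binomial
depth noise around 0.5. `alt_ad_min`, `saf_min`/`sar_min` and `sor_max`
defaults sit inside the inflection ranges the permutation analysis itself
finds on deep cohorts (SAF/SAR around 3–5, SOR around 2–3); `tlod_min = 6.3`
is the consuming caller's conventional emission threshold. All are tunable
and all five scan dimensions are exposed to the permutation analysis.

A **missing metric passes its criterion** (with a logged count): the package
accepts VCFs from heterogeneous callers and platforms, and absence of a
strand table or TLOD must not silently discard a cohort.

Cohort prevalence is computed over blood samples only, at two levels:
allele (carriers of the exact `(chrom, pos, ref, alt)` key) and locus
(distinct samples carrying *any* alternate allele at `(chrom, pos)`; samples,
not alleles, are counted). The denominator is the full roster passed in —
including samples that contributed zero records — so subset runs
automatically use subset prevalence.

The functional tier removes synonymous variants, exonic effects outside the
kept set, repeat-region variants (when a BED mask was supplied at parse
time), and germline-database hits. A bare dbSNP id with no gnomAD frequency
counts as germline evidence, but COSMIC membership rescues it: known somatic
cancer mutations are legitimately present in dbSNP.

### Paired (individual) tier

For a blood record with a paired non-blood sample, the 2×2 table
`[blood alt, blood ref; paired alt, paired ref]` is tested one-sided for
blood alt-fraction enrichment. The test is the hypergeometric tail
(equivalently one-sided Fisher), a documented implementation choice.
Non-enriched records are removed and reason-coded by VAF direction —
`PAIR_TUMOR` when the paired VAF is higher (the cfDNA-contamination
pattern), `PAIR_GERMLINE` otherwise; the split is purely for reporting, as
no quantitative boundary between the two failure modes is defined. A
variant absent from the paired VCF is tested against alt = 0 at the paired
sample's median depth: absence from a VCF is evidence of absence only
relative to coverage, and the median is the least-assumption stand-in
(imputations are logged). Samples without any paired data fall back to
single-sample logic, logged.

### Permutation analysis

For each permutation the cohort is partitioned uniformly at random into
k = round(1/proportion) disjoint subsets of size ⌊N/k⌋ or ⌈N/k⌉; the
pipeline runs independently per subset and the union of subset calls is
compared to the full-cohort call set. Consistency is
`|full ∩ pooled| / |full|` (defined as 1 when the full set is empty). This
"partition" semantics makes the full-cohort denominator well-defined at
every proportion; the alternative single-subset reading (one subset per
permutation, denominator restricted to subset samples) is available behind
`PermutationPlan(single_subset=True)`.

Default scan grids: VAF 0–0.1 step 0.005; prevalence 0–0.15 step 0.01;
DP 0–50 step 5; SOR 0.5–6 step 0.5; SAF/SAR 0–10 step 1 (SAF and SAR are
set jointly). Proportions default to 1/2 … 1/10 with 100 permutations each.

Randomness is driven by a `SeedSequence` keyed on (seed, metric, proportion
index, permutation index) — *not* the grid value — so the same partitions
are reused across the grid (common random numbers): curves differ only
through the scanned parameter, not through sampling noise. Per-grid-value
standard deviations across permutations are recorded alongside the means.

Two scan engines produce identical output. The default vectorised engine
evaluates, per partition, a records × grid boolean call matrix: non-scanned
flags are computed once, the scanned criterion is an outer comparison, and
per-subset prevalence reduces to bincounts over factorised keys (each blood
record belongs to exactly one subset, so the pooled call set is a row-wise
union). The `per-subset` engine literally reruns `run_chipfilter` on every
subset and is kept as the reference implementation; their equality is
asserted in the test suite for single, paired and prevalence scans.

**Inflection detection** is formalised since curves are otherwise read by
eye: *plateau* (default) returns the smallest grid value whose mean
consistency is within ε = 0.02 (relative) of the curve maximum; *curvature*
returns the interior grid value maximising the negative second central
difference. Ties go to the smallest value; when only the final grid point
qualifies the result is flagged "no saturation". Fewer than 3 grid points
is an error.

When a curated truth set is supplied, precision and recall of the
full-cohort calls are reported per grid value (empty-set conventions:
precision of an empty call set is 1, recall against an empty truth is 1).

## Synthetic cohorts

The generator emulates the data regimes the method targets: WES (~150×
mean depth) and ultra-deep error-corrected panels (~5000×), with per-site
negative-binomial depth (variance m + 0.3 m², reflecting capture
variability), binomial read sampling given the latent VAF, and a panel laid
out over CH driver genes (DNMT3A, TET2, ASXL1, TP53, JAK2, PPM1D, SF3B1,
SRSF2). Four record classes:

- **ch**: Poisson(2) events per sample, VAF ~ U(0.02, 0.2), balanced
  strands, driver annotations, no germline-database entries (10% of draws
  are synonymous and are removed by design, exercising the functional tier);
- **germline**: VAF 0.5 heterozygotes with gnomAD AF ~ U(0.01, 0.5) and
  dbSNP ids;
- **artifact**: 15 recurrent loci with VAF ~ U(0.004, 0.015) — below the CH
  floor, so the two classes are separable by a VAF cutoff, which is the
  point of the fixture (`enforce_separability=False` allows overlap for
  hard-mode tests) — strand skew 0.65 inflating SOR, and per-locus cohort
  occurrence probabilities drawn from U(0.05, 0.12). The occurrence band
  deliberately straddles the 0.10 prevalence cutoff from below: a locus
  whose full-cohort prevalence is near but under the cutoff is kept in the
  full call set yet stochastically crosses the cutoff inside small subsets,
  which is precisely the partition-sensitive fluctuation the consistency
  statistic detects (a locus always above the cutoff never enters the
  full-cohort calls and is invisible to a full-cohort-anchored statistic);
- **contamination** (paired mode): tumor VAF ~ U(0.2, 0.6) with blood VAF ~
  U(0.001, 0.01), plus paired-sample records for ch (trace tumor VAF) and
  germline (tumor VAF 0.5) classes.

TLOD is synthesised as 1.8·Alt_AD plus unit Gaussian noise — monotone in
read support, sufficient to exercise the threshold, with no claim of caller
fidelity. Zero-alt-read draws are not emitted (a caller would not report
them), so realised class counts fall slightly below their nominal rates at
WES depth.

What the generator does **not** model: sequence-context error profiles,
indels beyond representation, mapping artifacts, contamination between
unrelated samples, and annotation errors. Passing tests therefore
demonstrate the pipeline's contracts (comparator correctness, tier order,
determinism, subset-consistency mechanics), not calling performance on real
reads.

## Problem sizes and numerical choices

The test suite and acceptance script run at n = 100 samples (60 for the
paired cohort), 20–50 permutations per proportion, and subset proportions
{1/2, 1/5, 1/10}; these sizes give stable inflections on the synthetic
cohorts while keeping the default grid scans in the seconds range via the
vectorised engine. Permutation recovery of the planted VAF separability
point is asserted at the acceptance level on the ultra-deep regime: at ~150×
a VAF-0.015 artifact carries ~2 alternate reads and fails the count
thresholds (`alt_ad_min`, `saf/sar_min`) regardless of the VAF cutoff, so
the low-VAF end of the scan is only informative where depth supports it —
the same reason the corresponding real-data analyses use deep panels to
probe cutoffs below 0.02.

Other numerical details: ties in duplicate-record collapsing keep the first
encountered (logged); prevalence uses exact fractions against strict `>`;
median paired depth is rounded half-even; consistency standard deviations
use ddof = 1 (0 when n_perm = 1); curve TSVs and manifests avoid volatile
fields (wall-clock time is logged to stderr, not written) so reruns are
byte-identical.

## Known limitations

- The exact test and the germline/tumor split in the paired tier are
  package choices; other implementations of the same idea may classify
  borderline records differently.
- Locus-level prevalence counts carrier samples, not distinct alternate
  alleles; highly multi-allelic sites are treated conservatively.
- Indel representations are taken as given (left-alignment assumed done
  upstream); no normalisation or liftover is attempted.
- The functional tier trusts upstream annotation; no live database lookup.
- Joint optimisation of several thresholds is out of scope: metrics are
  scanned one at a time against a fixed base configuration.
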