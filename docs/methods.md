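# Methods

This note documents the statistical model behind `xregen`, the default
parameters and why they were chosen, the synthetic-data generator used
for validation, and the package's known limitations.

## Problem setting

Regeneration time courses from distantly related animals cannot be
compared gene by gene: the species lack reference genome annotation,
and their protein sequences are too diverged for reliable direct
orthology assignment. `xregen` therefore compares them through a shared
intermediary — a curated reference-protein database (human-dominated,
eukaryote-wide). Every transcriptome is aligned against that database;
two genes from different species are treated as corresponding when they
hit the same reference entries. All downstream analysis (differential
expression, temporal classes, signature intersections) is carried out
per species and then joined on that correspondence.

## Annotation

Alignment hits are first filtered:

* **taxon allow-list** — hits to non-eukaryotic subjects are discarded
  outright; transcriptome assemblies of aquatic animals routinely
  contain microbial contamination whose best database matches are
  bacterial proteins.
* **permissive significance cutoff 1e-2** (inclusive `<=`) — removes
  spurious alignments while keeping distant homology, which is the norm
  between these species and human proteins.

Transcripts may optionally be clustered into genes (greedy
longest-first clustering at 80% sequence identity, k-mer containment
with word size 8, mirroring standard redundancy-removal practice for de
novo assemblies); otherwise every transcript is its own gene. Hits of a
gene's member transcripts are aggregated per subject accession by the
mean bit score and mean significance over the members that hit it; a
member hitting the same subject multiple times contributes only its
single best hit, so duplicated hit rows cannot shift the averages.

Two annotations are derived per gene:

* **best match** — the subject with the highest mean bit score; ties
  broken by lower mean significance, then lexicographic accession, so
  annotation is deterministic.
* **list match** — all subjects with mean significance `<= 1e-15`
  (strict-homology cutoff), kept as a set. The list view retains
  one-to-many homology that a single best match discards.

## Cross-species co-annotation

* **best-match mode** — genes from different species are linked when
  their best-match accessions are identical. Per accession the set of
  carrier species is recorded; counting accessions per exact carrier
  set yields disjoint Venn regions that sum to the union.
* **list-match mode** — genes are linked when their list-match sets
  overlap by more than 80% of the smaller list
  (`|A ∩ B| / min(|A|, |B|) > 0.8`, strictly; an overlap of exactly
  4-of-5 does not link). The min denominator makes the criterion
  insensitive to one species having systematically longer lists.
  Links may be many-to-many; ambiguity is preserved, not resolved.
  An inverted index over accessions keeps construction near-linear in
  total list size.

## Differential expression without replicates

Each post-amputation time point is compared against the 0 h baseline.
With one library per time point, dispersion cannot be estimated per
gene, so a conditional exact test is used with a fixed dispersion:

* Counts are modelled as negative binomial with variance
  `mu + phi * mu^2`; the default `phi = 0.1` is typical of bulk RNA
  time courses (a moment-based estimator, `estimate_dispersion`, is
  provided for data-driven choices).
* Conditioning on the total `s = a + b` of a gene's two counts, the
  expected split is proportional to the two library sizes (total-count
  normalization with geometric-mean scaling by default). The two-sided
  p-value sums the probabilities of all splits no more likely than the
  observed one (method of small p-values). At `phi = 0` the reference
  distribution reduces to the binomial.
* `log2FC = log2((c_t/f_t + 0.5) / (c_0/f_0 + 0.5))` with
  library-size factors `f` and a 0.5 pseudocount to stabilize zeros.
* Genes enter testing only if expressed: strictly more than 20 counts
  at some time point, or RPKM above 1 when gene lengths are available.
  The thresholds are strict (`[5, 15, 19]` is filtered out; `[0, 0,
  21]` is kept).
* p-values are Benjamini–Hochberg adjusted per time point, and a gene
  is DE at a time point when `|log2FC| > 2` (strictly — exactly 2.0 is
  not DE) and adjusted `p < 0.05`. For the hydra-like species, whose
  much shallower libraries compress observable fold changes, the
  fold-change threshold is relaxed to 0.5 via per-species config.

The exact test and the BH adjustment are validated against independent
oracles: an exact rational-arithmetic enumeration of the conditional
split distribution (`fractions.Fraction`, agreement within 1e-10 over
all totals up to 50 at dispersions 0, 0.05, 0.1, 0.5) and a brute-force
step-up rule (exact agreement on 1000 random vectors). On simulated
null genes the raw type-I error at alpha 0.05 is ~0.046.

### What the FDR bound applies to

BH is applied per time point, so the controlled quantity is the false
discovery rate among per-time-point DE *calls*. On synthetic data with
planted effects, that per-call FDR is ~0.08 (bounded at 0.1 in the
acceptance tests). The *union* definition of a DE gene — DE at at least
one time point — compounds the per-time tests: with six or so tested
time points per gene, the fraction of unplanted genes among union-DE
genes rises to ~0.2. That inflation is a property of union calling, not
of the test; the acceptance script reports it as the unasserted
diagnostic `de_gene_union_fdr`. Analyses needing gene-level FDR control
should adjust across the full gene-by-time matrix instead.

Total-count normalization also carries a composition bias: when
planted DE is mass-asymmetric, library totals absorb part of the
signal, shifting log2FC by up to ~0.2–0.4. A median-of-ratios
alternative (`normalize_libsizes(..., method="median_ratio")`) is
exposed for such data; the default remains total-count.

## Temporal patterns

Time grids are heterogeneous (half-hour to two-day spacing in the
hydra-like and planarian-like species, multi-day in the sea-cucumber-
like one, whose full regeneration takes about two weeks), so profiles
are compared on an affine rescaling of each grid to `[0, 1]`. Phases
are assigned by index: early = first two non-baseline points (first
one only when fewer than three exist, as in sparse day-scale designs),
late = last two (minus any index already claimed as early, which keeps
the two sets disjoint when only three non-baseline points exist),
recovery = last point. Per-species overrides are config options.

Each gene DE at `>= 1` time point is classified:

* **EU / ED** — DE with consistent positive/negative sign at an early
  index and `|log2FC| <= 0.5` at the recovery index (a transient pulse
  that has returned to baseline);
* **LU / LD** — consistent sign at every DE time point, DE persisting
  into the late phase, not recovered;
* **OTHER** — sign-mixed or matching neither class.

EU/ED are checked before LU/LD so a recovered early pulse is never
absorbed into the sustained classes, and classification is exactly
antisymmetric: negating a trajectory maps EU↔ED and LU↔LD. Note that
the recovery tolerance interacts with count noise: at dispersion 0.1
and baseline mean 100 the log2FC noise sd (~0.5–0.7) exceeds the 0.5
tolerance often enough that a substantial fraction of genuinely
transient genes land in OTHER; `recovery_tol` is exposed for deeper
libraries. Profiles of DE genes are additionally clustered
(1 − Pearson correlation, average linkage, cut at k = 4 by default)
for visual grouping; constant profiles, whose correlation is
undefined, are assigned to the nearest cluster mean and flagged.

## Signatures

Published regeneration/wound-healing gene lists are intersected with
the per-species results in a presence/DE matrix: per signature member
and species the cell records absent, present (best- or list-match) or
DE. Consensus signatures are built from multi-dataset support
(defaults: `>= 2` of 4 murine datasets and `>= 3` of 8 human
datasets), shared-membership sets use case-normalized identifiers, and
a reciprocal-best-hit utility (coverage `>= 0.4`, identity `>= 0.6`)
supports direct pairwise orthology where assemblies permit it.

## Synthetic data and validation

Real inputs for this analysis are multi-gigabyte assemblies and
alignment runs; the package instead validates against a seeded
generator with planted, exactly scorable truth:

* a reference universe with deterministic taxon proportions (largest-
  remainder apportionment: 50% human / 15% mouse / 30% other eukaryote
  / 5% bacteria by default);
* hit tables with planted ortholog groups — one shared human top
  accession per group plus a shared, between-group-disjoint strict hit
  list (mean size 15) — Poisson decoy hits below the planted score,
  and a bacterial fraction to exercise the taxon filter;
* NB count time courses on three realistic grids with planted EU/ED/
  LU/LD fold-change pulses (effect 3 log2 units, 50 genes per pattern
  by default) and a subset of ortholog genes DE in every species;
* signature lists with exact pairwise/three-way overlap structure and
  per-dataset DE lists with known consensus membership.

Every generator is bit-reproducible: sub-stages derive their RNG from
the configured seed plus a fixed offset, and the truth table is written
alongside the fixture. Acceptance checks (see
`tests/test_acceptance.py` and `scripts/acceptance.py`) cover oracle
agreement, null calibration, planted recovery (DE sensitivity `>= 0.9`
per gene, per-call FDR `<= 0.1` pooled over species, pattern accuracy
`>= 0.9`, exact recovery of all planted ortholog groups in both
co-annotation modes on noise-free fixtures), boundary strictness, and
byte-level reproducibility of full pipeline reruns. Typical problem
sizes in those runs are 2000 genes × 3 species with 100 planted
ortholog groups; a complete pipeline run at that size takes a few
seconds on one CPU.

## Numerical choices

* Exact-test pmfs are computed in log space and shifted by their
  maximum before exponentiating; the "no more likely than observed"
  comparison uses a relative tolerance of 1e-9 so float rounding cannot
  split tied splits.
* BH is implemented directly (reverse cumulative minimum over ranked
  `p * m / rank`), validated against a brute-force oracle.
* All report tables are written sorted with fixed float formatting and
  `\n` line endings; the manifest records the config digest and seed
  but no timestamps, making reruns byte-identical.

## Limitations

* Shared-hit correspondence is not orthology: paralogs hitting the same
  human protein are conflated by design.
* The fixed-dispersion exact test trades per-gene dispersion estimation
  (impossible without replicates) for calibration under an assumed
  `phi`; severely misspecified dispersion distorts type-I error.
* Union-over-time DE calling inflates gene-level FDR (see above).
* Pattern classes depend on index-based phase assignment; irregular
  grids may need per-species overrides.
* The synthetic generator plants idealized signals (shared top hits,
  step-shaped pulses); it validates correctness and calibration, not
  performance on real assemblies.
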