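# Methods

This note records the statistical model, the simulator's assumptions, the
numerical choices, and the known limitations of `rohscan`.

## The model

Litter-size records (Total Number Born, TNB; Number Born Alive, NBA) are
repeated measurements on sows.  For one trait,

    y = f d + X b + T h + Z u + W p + e

* **b** — parity fixed effects at 5 classes (1st, 2nd, 3rd, 4th, 5th and
  beyond).  The first class absorbs the intercept (drop-first dummy coding),
  so every other parity solution is a contrast against first parity;
  estimable contrasts are invariant to this choice.
* **f, d** — per-sow heterozygosity percentage (heterozygous SNPs × 100 /
  total post-QC SNPs) and its slope in piglets per percent.  Under
  directional dominance, autozygosity depresses litter size, so the
  one-sided alternative for d is *positive* (more heterozygosity, larger
  litters).
* **h** ~ N(0, I σ²ₕ) — herd–year–season contemporary groups, treated as
  random (about 100 levels for ~2,000 records).
* **u** ~ N(0, H σ²ₐ) — additive genetic values with the single-step
  relationship matrix combining pedigree and genomic information (below).
* **p** ~ N(0, I σ²ₚ) — permanent environment of the sow, carrying the
  covariance among her repeated litters beyond additive genetics.
* **e** ~ N(0, I σ²ₑ).

The per-segment scan refits this model (without the heterozygosity
covariate; see *Design choices*) plus one fixed 0/1 carrier effect per
catalog ROH segment, with variance components *fixed* at their pre-scan
REML estimates.  The carrier effect is tested one-sided for a *negative*
value.

## ROH detection and the shared-segment catalog

A run is a maximal stretch of strictly homozygous genotypes within one
chromosome of one sow, spanning at least `min_snps` markers.  The default
is 16 — "more than 15 SNPs" read strictly — and is configurable.  No
heterozygous calls are tolerated inside a run (`max_het=0`); genotyping-
error tolerance was considered and left out because the mode-imputed,
call-rate-filtered input already constrains error rates, and a tolerant
definition would need an error model the data cannot identify.

Candidate shared segments are the *distinct intervals among individual
runs*; a sow carries a segment iff one of her own runs covers it fully,
and segments with carrier frequency in [5%, 95%] are kept.  This
run-derived enumeration (rather than fixed sliding windows) reproduces the
characteristic catalog-to-run count ratio of unfavourable-haplotype scans
and is isolated in `build_catalog` so an alternative enumeration can be
swapped in.

Genome coverage per sow divides the union length of her runs by the mapped
autosome length (last minus first marker position per chromosome, summed),
which is reproducible from the marker map alone; run lengths are reported
as `end_bp - start_bp`.

## Relationship structures

* **A** — numerator relationship matrix by the tabular recurrence; unknown
  parents are unrelated, non-inbred founders (no unknown-parent groups).
* **G** — VanRaden method 1 with observed-frequency centering,
  `G = Zc Zc' / (2 Σ p(1-p))`, monomorphic markers dropped.  For
  invertibility G is blended as `0.95 G + 0.05 A22` by default
  (configurable); no additional compatibility scaling of G toward A22 is
  applied by default, keeping the recipe simple and reproducible — a flag
  would be the place to add it if a dataset needs it.
* **H⁻¹ = A⁻¹ + [0 0; 0 G_blend⁻¹ − A22⁻¹]** on the genotyped block, the
  standard single-step construction.  A⁻¹ is assembled from the
  parent–offspring rules with inbreeding-adjusted Mendelian sampling
  variances.

All matrices are dense.  The package targets pedigrees of a few hundred to
a few thousand individuals, where one dense Cholesky factorization of the
~1,000–2,000 mixed-model equations costs well under a second; sparse
machinery would add complexity without benefit at this scale.

## AI-REML

Variance components are estimated by average-information REML on the mixed
model equations: exact first derivatives from the inverse coefficient
matrix, the AI matrix from the data-part quadratic forms `½ fᵢ' P fⱼ`, and
Newton updates with two expectation–maximization warm-up iterations for
stability.  Steps that would leave the parameter space or decrease the
restricted likelihood are halved; components heading to zero are pinned at
a floor of 10⁻⁶ × phenotypic variance, flagged as boundary estimates, and
removed from the active update set.  Convergence requires a scaled update
norm below 10⁻⁸ (default).  Sampling variances come from the inverse AI
matrix at convergence.  Starting values split the phenotypic variance
equally across the four components.

The one-sided tests use the standard normal reference by default — with
~2,000 records the residual degrees of freedom make Student-t corrections
invisible at two significant figures; a `df` option switches to Student-t.

## Scan mechanics

The base system (parity, herd–year–season, additive, permanent
environment) is factorized once per trait.  Each segment adds a single
carrier column, solved by the Schur-complement bordering identity, so the
per-segment cost is one triangular solve; correctness against full refits
is asserted in the tests to 10⁻⁸.  Segments whose carrier status is
constant among phenotyped sows, or whose carrier column is numerically
confounded with the base design, are skipped with a logged reason.
BH-FDR q-values are reported alongside raw one-sided p-values; merged
regions join overlapping or bookended significant segments per chromosome.

## The simulator

The generator emulates a closed nucleus herd:

* **Pedigree** — 24 founders and 5 generations of 132 offspring (litters
  of 5, sexes alternating within sibships), with each mating a full-sib
  pair with probability 0.9 (`partial_fullsib` scheme).  These defaults
  were calibrated once so the ~330 phenotyped sows (all non-founder
  females) carry mean pedigree inbreeding near 0.3 and mean ROH genome
  coverage of roughly 27–31%, matching the upper range reported for closed
  Iberian pig lines; `random` and `circular` schemes are available for
  low-inbreeding contrasts.
* **Genotypes** — 18 autosomes × 120 evenly spaced SNPs on 130 Mb
  chromosomes; founder allele frequencies uniform on [0.15, 0.5];
  gene dropping with Poisson(1.3) crossovers per chromosome per meiosis at
  uniform positions, no interference.  The marker count (~2,160) is a
  deliberate scale-down of a 60K chip: ROH landscapes scale with marker
  spacing, so run-size distributions are realistic in *marker* units while
  whole-study analyses stay fast enough for replicated testing.
* **Phenotypes** — records follow exactly the fitted model: parity effects
  near 6.2 piglets, heterozygosity slope 0.055 piglets/%, herd–year–season
  levels assigned uniformly at random (the true assignment process of
  commercial herds is unknown; uniform assignment likely understates
  environmental confounding), breeding values dropped down the pedigree
  with inbreeding-adjusted Mendelian sampling variances, and variance
  components defaulting to σ²ₐ=0.145, σ²ₚ=0.366, σ²ₕ=0.170, σ²ₑ=2.901
  (squared piglets).  NBA is TNB minus a Poisson(0.27) loss, so NBA ≤ TNB
  holds by construction.  Records are simulated continuously and rounded
  to non-negative integers for output; rounding adds ≈1/12 squared piglet
  to the realized residual variance, so *parameter-recovery validation runs
  on the continuous scale* (`round_phenotypes=False`) where the generating
  components are exact.
* **Planted segments** — a configurable fraction of *founder haplotypes*
  is overwritten with one shared allele pattern across each planted
  interval, so carriers (sows homozygous across the interval) arise through
  ordinary inheritance and Mendelian consistency is never violated.  The
  founder-haplotype frequency is solved from the target carrier frequency
  via `F q + (1-F) q² = target` using the realized mean inbreeding F.
  Realized carrier frequencies drift around the target (±0.1 is common
  with 24 founders).  Defaults plant −0.6 and −0.9 piglet effects,
  mirroring the magnitudes such scans report.

What the simulator does *not* emulate: linkage-disequilibrium decay from a
realistic ancestral population (founders are in linkage equilibrium, so
background ROH sharing is entirely pedigree-driven), selection, mutation,
genotyping error, multi-herd structure, and heterogeneous marker spacing.
Consequently, passing tests demonstrate the estimators and the scan are
correct and calibrated *under the stated model*, not that the model
captures every feature of commercial sow data.

## Validation design

* **Oracle equivalence** — the run detector, A matrix, mixed-model solver
  and H⁻¹ are each checked against independent naive implementations
  (brute-force interval scan, kinship recursion, dense GLS, dense block
  assembly) on 100+ random instances.
* **Parameter recovery** — 20 replicates at study scale, generated from
  the default components and estimated with the *matched* pedigree
  relationship structure, must recover every component within two
  empirical standard errors.  (The ssGBLUP path replaces A with a
  genomic-pedigree blend; using it on pedigree-simulated breeding values
  mixes estimator bias with deliberate model mismatch, so the recovery
  check isolates the estimator.)
* **Null calibration** — segments within one replicate share the realized
  genetic background, so their significance indicators are strongly
  positively correlated and a segment-count binomial band would be far too
  narrow.  The replicate is the exchangeable unit: over 40 independent
  null genomes the mean significant fraction must lie within a 99%
  empirical-standard-error band of 0.05.  Marginal calibration is exact
  under the model because carrier indicators are functions of the
  genotypes, which are independent of the trait's random effects.
* **Power** — a planted −0.8-piglet segment at ~30% carrier frequency must
  be the top-ranked hit in at least 18 of 20 study-scale replicates.
* **Smoke** — the fixture pipeline must run end to end deterministically
  (byte-identical reruns) with cross-file counts and id sets consistent.

## Design choices on open points

* The per-segment scan models *exclude* the genome-wide heterozygosity
  covariate by default and *retain* herd–year–season.  Rationale: the
  second-stage models of such scans fix the previously estimated variance
  components — which include σ²ₕ — while the covariate is a genome-wide
  summary whose inclusion would partially absorb each segment's own
  contribution.  Both are flags (`scan_het_covariate`, `scan_hys`), and
  the manifest records the setting used.  A consequence worth knowing:
  with the covariate omitted, carrier effects absorb part of the
  genome-wide trend (carriers are more homozygous overall), which biases
  scan estimates of planted effects away from zero; the acceptance script
  therefore reports the planted-effect estimate from a model that includes
  the covariate.
* Parity uses five classes {1, 2, 3, 4, ≥5}; the class map is explicit in
  the phenotype table rather than inferred.
* Individuals are filtered before markers in QC (each threshold is
  strict: a call rate must exceed it), and the order plus removal counts
  are written to the dataset's provenance so results are auditable.
* Mode imputation (ties toward the lower dosage) stands in for pedigree-
  haplotype imputation.  Imputation quality is not what this package
  studies; the scan only needs complete data, and post-QC missingness is
  under 5%.  Pre-imputed data can be supplied to bypass the step.
* The text PLINK dialect cannot represent a marker whose counted allele
  never occurs (no allele reference in .ped), so such markers read back
  dosage-reflected; heterozygosity, ROH calls and G are invariant to the
  reflection, and the binary dialect round-trips exactly.

## Problem sizes

Replicated analyses (tests and the acceptance script) run the full study
scale of ~330 sows × 6 records on ~2,160 markers for recovery and power
checks, and a reduced 128-sow × 8-chromosome configuration for the
40-replicate calibration study; these sizes keep a complete validation run
in the low minutes on one CPU while leaving every stage at realistic
dimensionality.

## Known limitations

* Dense linear algebra bounds practical pedigrees to ~10⁴ individuals.
* Mode imputation ignores family information; with >5% missingness it
  would visibly attenuate ROHs.
* The catalog treats exact duplicate intervals only; near-duplicate
  segments with identical carrier sets produce identical test results by
  construction and are all reported.
* No dominance or epistatic components; single-trait REML only; no
  genomic prediction accuracy reporting.
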