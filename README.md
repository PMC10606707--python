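# rohscan

Genome scan for inbreeding depression of litter size in pigs, mapped through
runs of homozygosity (ROH).

Inbreeding depression is strongest in fitness traits such as litter size,
and its genetic basis is unevenly distributed along the genome.  `rohscan`
implements the complete analysis used to localise that variation in
SNP-chip-genotyped sow populations:

1. **QC and heterozygosity.** PLINK text/binary genotypes are filtered
   (individual and SNP call rates > 95%, autosomes only), residual missing
   calls are mode-imputed, and each sow's heterozygosity percentage
   (heterozygous SNPs × 100 / total SNPs) is computed.
2. **ROH catalog.** Maximal homozygous runs spanning more than 15 SNPs are
   detected per sow; the distinct run intervals form candidate shared
   segments, a sow *carries* a segment when one of her own runs covers it
   entirely, and segments carried by 5–95% of sows enter the catalog.
3. **Repeatability animal model.** For each trait (Total Number Born,
   Number Born Alive) the model

   `y = f d + X b + T h + Z u + W p + e`

   is fitted, with parity fixed effects **b**, heterozygosity covariate
   **f** with slope *d* (piglets per percent heterozygosity; a positive *d*
   is the genome-wide signature of inbreeding depression), random
   herd–year–season **h** ~ N(0, Iσ²ₕ), additive genetic **u** ~ N(0, Hσ²ₐ)
   with the single-step (ssGBLUP) relationship matrix H combining pedigree
   and VanRaden genomic relationships, permanent environment **p** ~
   N(0, Iσ²ₚ), and residual **e**.  Variance components come from
   average-information REML; the slope gets a one-sided test for *d* > 0.
4. **Per-segment scan.** With variance components fixed, every catalog
   segment is refitted with a carrier/non-carrier fixed effect (a bordered
   update of one base factorization, so thousands of mixed-model equations
   solve in seconds) and tested one-sided for a *negative* effect —
   homozygosity depressing litter size.  Benjamini–Hochberg FDR values and
   merged significant regions are reported alongside.

Because sow datasets of this kind are not public, the package includes a
first-class simulator (`rohscan.simulate`) that generates pedigrees with
tunable close-relative mating, gene-dropped SNP genotypes whose autozygosity
shows up as ROHs, and litter-size records drawn from exactly the model
above — including planted unfavourable segments with known carrier effects —
so every stage is testable end to end.

## Worked example

```python
from rohscan import (SimConfig, simulate, detect_runs, build_catalog,
                     summarize_catalog, h_inverse, ModelSpec, ai_reml,
                     fit_het_covariate, scan, heterozygosity_percent)

out = simulate(SimConfig(seed=1))          # ~330 sows, 18 autosomes, 6 records each
runs = detect_runs(out.genotypes, min_snps=16)
catalog = build_catalog(runs, out.genotypes, 0.05, 0.95)
s = summarize_catalog(runs, out.genotypes)
print(f"{s['n_runs']} runs, coverage {s['coverage_mean']:.1f}%, "
      f"{len(catalog)} shared segments")

hinv = h_inverse(out.pedigree, out.genotypes, out.genotypes.samples)
het = dict(zip(out.genotypes.samples, heterozygosity_percent(out.genotypes)))
spec = ModelSpec(trait="tnb", het_covariate=True)
vc = ai_reml(out.phenotypes, spec, hinv, het=het)
d = fit_het_covariate(out.phenotypes, spec, hinv, vc, het)
print(f"d = {d.estimate:.4f} ± {d.se:.4f} (one-sided p = {d.p_one_sided:.3g})")

hits = scan(catalog, out.phenotypes, ModelSpec(trait="tnb"), hinv, vc)
print(hits.nsmallest(3, "p")[["chromosome", "start_bp", "end_bp",
                              "effect", "se", "p"]])
```

prints (the default configuration plants unfavourable segments of −0.6 and
−0.9 piglets on chromosomes 5 and 8):

```
5593 runs, coverage 28.3%, 2926 shared segments
d = 0.0883 ± 0.0082 (one-sided p = 3.52e-27)
  chromosome  start_bp    end_bp    effect        se             p
8   36528926  55867769 -0.981258  0.136051  2.747999e-13
8   37603306  58016529 -0.981329  0.138422  6.733967e-13
8   36528926  58016529 -0.974920  0.139429  1.352807e-12
```

The scan's strongest hits sit on the planted chromosome-8 segment with an
effect near the planted −0.9 piglets (the estimate also absorbs part of the
genome-wide heterozygosity trend, since the per-segment models omit the
covariate by default), and the positive slope *d* says each extra percent
of heterozygosity adds about 0.09 piglets per litter in this population.

A command-line interface wraps the same pipeline:

```sh
rohscan simulate --seed 1 --out-dir fixture/
rohscan run-all analysis.cfg        # flat key:value config; see `rohscan --help`
```

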