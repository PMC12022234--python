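# nivgeno

Quality-controlled consensus genotyping and population-diversity
indicators for **noninvasive genetic monitoring** with microsatellite
panels.

Long-term monitoring of elusive carnivores such as the gray wolf (*Canis
lupus*) relies on scat, urine and hair collected in the field. DNA from
such material is degraded and dilute, so every genotype is exposed to
amplification failure, allelic dropout (AD: one allele of a heterozygote
fails to amplify) and false alleles (FA: artifactual peaks). `nivgeno`
implements the standardized workflow used by national wolf-monitoring
programmes to turn raw replicate genotypes into reliable individual
records:

1. **Species / mitotype screen** — mitochondrial control-region consensus
   sequences matched offline against a curated haplotype panel (e.g. the
   Italo-Alpine w22 mitotype); only wolf-specific haplotypes proceed.
2. **Multitube consensus** — four PCR replicates per noninvasive sample
   (two for tissue) are combined per locus; unconfirmed single-replicate
   alleles are screened out, and more than two supported alleles flag the
   sample as contaminated.
3. **Quality index (QI)** — each replicate × locus scores 1 (matches the
   consensus), 0.5 (allelic dropout) or 0 (missing/other); the per-sample
   mean over loci defines sample quality, and only uncontaminated samples
   with QI > 0.5 are retained.
4. **Individual identification** — samples sharing ≥ 12 complete loci
   with ≤ 3 allele mismatches are attributed to one animal. The tolerance
   follows a binomial error model: with per-locus dropout rate *p* among
   high-quality samples, P(≥ 1 mismatch over *n* loci) = 1 − (1 − *p*)ⁿ
   (0.587 at *n* = 12, *p* = 0.071). Discriminatory power is quantified by
   the probability of identity among siblings,
   PI_sibs = 0.25 + 0.5·Σp² + 0.5·(Σp²)² − 0.25·Σp⁴ per locus,
   multiplied across loci (and over every locus-subset size via
   elementary symmetric polynomials).
5. **Staged error rates** — AD per successful PCR at heterozygous
   reference loci (replicates vs sample consensus; all samples and the
   high-quality subset) and residual AD/FA rates (sample consensus vs
   individual consensus of recaptured animals).
6. **Diversity indicators** — Na, Ho, Nei's unbiased He, F_IS = 1 − Ho/He,
   Hardy–Weinberg permutation tests (1000 allele permutations), a
   maximum-likelihood (EM) null-allele frequency estimator, and a
   sex-ratio z-test from the amelogenin marker.

A fully seeded **simulator** draws diploid genotypes under
Hardy–Weinberg equilibrium, capture–recapture sampling structure and the
complete error taxonomy (failure, dropout, false alleles, contamination),
with a per-event truth log, so every estimator in the pipeline can be
validated against ground truth without any external data.

## Worked example

```python
from nivgeno import SimConfig, simulate_dataset, run_dataset_pipeline
from nivgeno.popgen_stats import diversity_report, pi_sibs_panel

cfg = SimConfig(n_individuals=100, seed=42)
records, metas, truth = simulate_dataset(cfg)
samples, retained, individuals, errors = run_dataset_pipeline(records, cfg.panel)

print(f"samples genotyped   : {len(samples)}")
print(f"retained (QI > 0.5) : {len(retained)}")
print(f"individuals         : {len(individuals)}")
print(f"mean AD per locus   : {errors.mean('ad'):.1%}")
table, totals = diversity_report(individuals, cfg.panel, n_perm=1000, seed=42)
print(f"mean Ho / He        : {totals['Ho']:.3f} / {totals['He']:.3f}")
print(f"PI_sibs (22 loci)   : {pi_sibs_panel(table['pi_sibs']):.2e}")
```

prints

```
samples genotyped   : 220
retained (QI > 0.5) : 131
individuals         : 73
mean AD per locus   : 12.7%
mean Ho / He        : 0.470 / 0.478
PI_sibs (22 loci)   : 7.48e-06
```

220 field samples of 100 simulated wolves pass the funnel: 131 survive the
quality filter, and clustering recovers 73 animals among the retained
samples. The initial dropout rate (12.7% of successful PCRs at
heterozygous loci) is typical of scat-grade DNA, while the 22-locus panel
leaves a ~10⁻⁵ chance that even full siblings share a genotype.

The same workflow is scriptable from the shell:

```bash
nivgeno simulate --seed 42 --n-individuals 100 --out replicates.tsv
nivgeno run replicates.tsv --outdir out/ --seed 42
```

writing per-stage tables (`sample_consensus.tsv`, `individuals.tsv`,
`error_rates.tsv`, `diversity.tsv`, a Genepop export) and a
`manifest.json` with the seed, configuration hash and the
sample-accounting funnel.

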