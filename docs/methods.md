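# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the design decisions taken where the underlying field
protocol leaves room for interpretation.

## Data model

A genotype call at one locus is an unordered pair of integer allele
labels (fragment sizes in base pairs) or one of three non-called states:
missing, contaminated, disputed (analyst disagreement). All three
non-called states behave as missing in every comparison; in particular,
*missing data count as similarity* when matching samples, because a
failed amplification carries no evidence for or against identity. Allele
mismatches between two calls are counted per allele under the best
pairing of the two pairs (0, 1 or 2 per locus).

The default marker panel is the 22-autosomal-microsatellite + amelogenin
set used for European gray wolf monitoring (amelogenin is heterozygous in
male canids, homozygous in females). The sex marker is excluded from
matching, quality and diversity computations and used only for sex
assignment.

## Species and mitotype screen

Control-region consensus sequences (~605 bp) are assigned to the closest
reference haplotype by Hamming distance over the shared aligned length,
with `N` as a wildcard. Defaults: `max_mismatch = 2` (a curated panel of
known haplotypes leaves no room for distant hits), `min_length = 500` bp
(shorter Sanger consensus is considered insufficient to identify the
species). Equidistant references yield an unidentified verdict rather
than an arbitrary choice. Haplotypes shared between dog and wolf yield a
*Canis* sp. verdict and are excluded downstream, since a free-ranging dog
cannot be ruled out. Indel-containing alignment is out of scope: the
panel is assumed to be trimmed to a common coordinate frame.

## Multitube consensus and contamination

Per locus, the candidate alleles of a sample are those observed across
its called replicates. Two screening rules are applied:

* **Unconfirmed-allele screening.** An allele observed in exactly one
  replicate, when ≥ 3 replicates were informative for that locus, is
  discarded. This is the in-silico counterpart of the trained analyst who
  removes artifact peaks during electropherogram scoring. The threshold
  is justified by the error-rate regime of noninvasive data: with
  per-allele dropout d ≈ 0.07 and per-cell false-allele probability
  f ≈ 0.01, a single-replicate allele is roughly 30× more likely to be an
  artifact (probability ≈ f) than a real allele that dropped out of every
  other informative replicate (probability ≈ d³). Below 3 informative
  replicates the rule is not applied — there is too little opportunity to
  confirm a real allele.
* **Contamination.** More than two distinct surviving alleles — within a
  single replicate or pooled across replicates — cannot come from one
  diploid animal; the sample is flagged contaminated and excluded from
  matching and diversity stages. Both the within-replicate and the pooled
  trigger are active because a genuine DNA mixture can surface either way.

After screening, one allele makes a homozygote, two a heterozygote, and a
single amplification suffices for each retained allele (no ≥ 2-replicate
confirmation of the genotype itself).

## Quality index and retention

Each replicate × locus scores 1 when it reproduces the consensus
genotype, 0.5 when it shows an allelic dropout against a heterozygous
consensus, 0 otherwise — including a replicate carrying a corrected false
allele against a homozygous consensus, which is a disagreement, not a
dropout. The per-sample QI averages locus scores over **all** autosomal
panel loci (a locus that never amplified contributes 0 per replicate), so
pervasive failure drives QI toward 0. Samples are retained when QI is
strictly above 0.5 and no contamination was flagged. PCR success per
locus is the fraction of attempted amplifications (replicate × locus
cells) that produced a called genotype; since a locus score is at most
1{called}, mean QI never exceeds mean PCR success on the same records.

## Individual identification

Matching rule (defaults): two genotypes belong to one animal when they
share ≥ 12 autosomal loci with no missing data and show ≤ 3 allele
mismatches over the shared loci. The mismatch tolerance follows a
binomial model B(n, p) of per-locus dropout among high-quality samples:
at n = 12 and p = 0.071 the probability of at least one mismatch between
two samples of the same animal is 1 − (1 − p)¹² = 0.587, and ≤ 3
mismatches cover 99.2% of comparisons (98.65% of the disagreeing ones),
so a 3-mismatch tolerance accepts essentially all genuine recaptures.

Clustering is a deterministic greedy agglomeration: samples ordered by
descending QI (ties by sample id) join the existing individual with the
fewest mismatches (ties: most shared loci, then lowest individual id)
whose consensus satisfies the rule, else found a new individual. The
field protocol does not prescribe an algorithm; determinism and
order-invariance were the design criteria, and a post-hoc audit verifies
every member still satisfies the rule against the final individual
consensus (violations would indicate intransitive triads).

The individual consensus per locus is the union of member alleles —
residual dropout being far likelier than a residual false allele, an
allele seen in only one member is normally real — with the same
single-replicate screening as above (an allele backed by one replicate of
one member, against ≥ 3 informative replicates, is discarded), and a
majority-genotype fallback (ties toward the higher-QI member) if more
than two well-supported alleles remain. Without the screening step a
residual false allele would be absorbed into the individual consensus and
residual FA rates would be structurally zero.

Sample date and location are never used to split or merge automatically;
a reviewer report flags same-day member samples farther apart than a
configurable distance (default 50 km) for manual inspection.

## Staged error rates

All rates are events per successful amplification at the locus,
following the replicate-comparison estimators standard for multitube
data:

* **AD** — replicates vs their sample consensus, heterozygous-consensus
  loci only, over all uncontaminated samples; an observation homozygous
  for exactly one reference allele is a dropout event.
* **AD_high** — the same restricted to retained (QI > 0.5) samples.
* **AD_res / FA_res** — sample consensus vs individual consensus over
  recaptured individuals (≥ 2 member samples). An observation carrying
  any allele absent from the reference is a false-allele event — including
  a homozygote for a foreign allele and a heterozygote sharing only one
  allele with a heterozygous reference (one FA event, not a dropout).

Zero-denominator loci propagate as explicitly not-estimable (never a
silent 0), and panel means average estimable loci only. Every numerator
event is logged with sample/locus/replicate coordinates for audit. The
expected ordering AD ≥ AD_high ≥ AD_res emerges when quality filtering
and consensus correction are effective; it is a statistical tendency, not
an identity.

The null-allele frequency estimator complements these rates on the
individual dataset: an EM algorithm maximizes the multinomial likelihood
of called genotypes under HWE with one unamplifiable allele of frequency
r — a heterozygous null carrier presents as an apparent homozygote, a
null homozygote never amplifies, and the likelihood conditions on
amplification. Convergence: relative log-likelihood change < 1e-8, at
most 10,000 iterations; non-convergence is flagged on the estimate. At
least ~20 called genotypes are needed for a stable estimate (a warning is
issued below that).

## Diversity statistics

Per locus: Na (observed alleles), Ho (heterozygous fraction of called
genotypes), He as Nei's unbiased gene diversity (1 − Σp²)·2n/(2n − 1)
(the correction is negligible at monitoring-scale n, and exactness tests
use large simulated samples), F_IS = 1 − Ho/He. The panel F_IS is
1 − mean(Ho)/mean(He) with unweighted locus means and a
bootstrap-over-loci 95% CI; loci suspected of null alleles can be
excluded and the aggregates re-run. The HWE test permutes the pooled
alleles into new genotype pairs (allele frequencies, hence He, are
invariant, so only Ho moves); the two-sided p-value uses the add-one
estimator (1 + #{|F*| ≥ |F|})/(n_perm + 1), which cannot return 0, with
1000 permutations by default. Per-locus p-values are reported raw (an
optional Bonferroni column is a presentation choice, not a default).

PI_sibs per locus is 0.25 + 0.5·S₂ + 0.5·S₂² − 0.25·S₄ (Sₖ = Σpᵢᵏ), the
sibling-pair genotype-identity probability that conservatively bounds the
panel's discriminatory power. Multi-locus values multiply across loci;
subset statistics over all C(n, k) locus combinations use the elementary
symmetric polynomial recurrence for the mean (no subset enumeration) and
sorted products for min/max — enumeration-checked in the tests up to
n = 12.

The sex-ratio test is a standard one-proportion z against 0.5 with normal
approximation, two-sided.

## Simulator

The generator draws, in order: per-locus allele frequency vectors
(symmetric Dirichlet over ladders of dinucleotide-spaced sizes, allele
counts templated on the default panel's observed diversity); diploid
genotypes under HWE (two i.i.d. alleles per locus; amelogenin set by a
configurable male share, default 0.55); a capture-recapture sample count
per individual (singleton probability 0.607, otherwise 2 + Poisson(2.03)
truncated at 35, so recaptured animals average ≈ 4 samples); sample types
(≈ 84% scat; tissue/blood amplified in duplicate, others in
quadruplicate); and per-cell errors — failure, per-allele dropout d,
false-allele injection f (substituting one surviving allele of a
two-allele call, or added to a single-allele call, drawn uniformly from
the locus ladder excluding true alleles), plus sample-level contamination
that pools a second individual's alleles.

Defaults emulate degraded-sample monitoring conditions: base failure 0.20
per cell, d = 0.07, f = 0.01, contamination 0.02 per sample, and a
three-class quality mixture (8% completely failed samples; 25% poor
samples with failure ×3.5 and dropout ×2.5, noninvasive only; the rest
good; invasive samples always good with attenuated error rates). Under
these defaults a simulated run reproduces the qualitative regime of field
programmes — roughly 60–65% PCR success, two-thirds retention at
QI > 0.5, a bimodal QI distribution, and the staged ordering
AD ≥ AD_high ≥ AD_res with FA_res below 1%. The Dirichlet concentration
0.2 produces the skewed allele-frequency spectra (mean He ≈ 0.5) of a
population founded by few colonizers.

Every injected event is logged with exact coordinates
(sample/replicate/locus/allele), and replaying the log against the truth
genotypes regenerates the emitted replicate table byte-for-byte — the
reconciliation is enforced by a test. Because dropout is per allele, a
heterozygote drops to an apparent homozygote with probability 2d(1 − d)
per replicate; recovery tests therefore compare estimators with empirical
truth-log event frequencies measured on the estimators' own comparison
frames (same denominators, numerators classified against the true
genotypes), which verifies that the estimators count exactly the injected
events rather than re-deriving d in closed form.

Parameter-recovery experiments use a homogeneous configuration — uniform
good quality, small failure rate (0.05), no contamination, all samples
noninvasive with 4 replicates, d = 0.07, f = 0.01, 50 individuals — so
the consensus reference is reliable and the comparison isolates the
estimators themselves. With 100 replicate datasets the Monte-Carlo
standard errors of the mean AD and FA estimates are ≈ 4×10⁻⁴ and
≈ 5×10⁻⁵.

What the simulator does **not** emulate: relatedness among individuals
(all are unrelated, so PI_sibs-based power statements are conservative),
null alleles (the EM estimator is validated by its own dedicated
generator in the tests), spatial structure of sampling, analyst-specific
scoring behavior, and year-to-year population turnover. Passing tests
demonstrate correctness of the estimators under the stated error model,
not robustness to model misspecification in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on simulated datasets of
50–300 individuals (hundreds of samples, tens of thousands of
replicate-locus cells), 1000 HWE permutations, 1000-locus calibration
batches and 100-dataset recovery experiments — sizes at which the
statistical assertions have comfortable power while a full run stays in
the minutes range on one core. All randomness flows from explicit seeds
(numpy `default_rng`); the pipeline orchestrator records the seed and a
configuration hash in its run manifest, and identical (config, seed)
yield identical artifacts. Dates are parsed as ISO-8601 only, for
deterministic capture histories. Genepop export uses 3-digit allele
coding (microsatellite sizes here are < 1000 bp) with `000000` for
missing genotypes.

## Known limitations

* The greedy clustering, although audited, is not a global optimizer; in
  pathological near-threshold configurations a different (still
  rule-satisfying) partition could exist.
* The AD estimator conditions on the consensus being correct; with very
  few informative replicates per sample (heavy failure) the consensus
  itself degrades and residual rates are under-detected — visible in the
  gap between AD_high and AD_res under the default quality mixture.
* The null-allele model attributes all homozygote excess to one null
  allele; population substructure or inbreeding will inflate the
  estimate.
* The mitotype screen assumes length-comparable, indel-free reference
  sequences.
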