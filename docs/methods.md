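# Methods

## Genotype-likelihood model

All three callers share one observation model.  At a site with reference
allele R, the likelihood of a diploid genotype g = {a₁, a₂} given a sample's
reads is the product over reads of ½[P(b|a₁) + P(b|a₂)], where a base b is
emitted from template allele a with probability 1 − e if b = a and e/3
otherwise, and e is the PHRED-derived error probability of that base.  Two
numerical safeguards: e is capped at 0.75, so a quality-0 base never carries
an improper error probability of 1, and all products are accumulated in
natural-log space and renormalized per sample so the best genotype sits at
log-likelihood 0 (safe to depths of hundreds).  The model assigns raw base
qualities at face value; alignment-level recalibration of qualities is out
of scope, and the e/3 misread convention is the standard consensus-caller
choice.  Genotype quality is GQ = −10·log₁₀(1 − posterior), capped at 100,
so GQ ≥ 20 is equivalent to posterior ≥ 0.99.

## Individual-based calling (IBC)

The prior anchors on the reference with per-bp heterozygosity θ = 0.001 and
is uniform across transitions and transversions (so Ts/Tv remains an
unbiased quality readout).  Two parameterizations are implemented.  The
*independent* mode draws the two alleles independently (hom-alt prior
(θ/3)²); it cannot call a homozygous alternate genotype below roughly 18x
even from clean reads, which is inconsistent with how this caller family
behaves at 24x.  The default *dependent* mode uses P(het R/X) = θ/3,
P(X/X) = θ/6 and keeps the alt–alt pair prior at 2(θ/3)² so tri-allelic
genotypes remain callable.  The most likely genotype is emitted when its
posterior reaches 0.99 (ties broken by fixed alphabetical genotype order);
otherwise the genotype is missing.  Note that at depth 0 the posterior
equals the prior (≈ 0.9985 for hom-ref), so zero-coverage cells are *called*
reference-homozygous — this is why the downstream depth < 7 genotype filter
exists.  The union call set keeps every site where at least one non-missing
call carries a non-reference allele; site allele lists are the union of
called alternates (count-ordered), supporting tri- and tetra-allelic sites.

## Population-based calling (PBC)

Upon any non-reference evidence, the alternate allele is the non-reference
base with the highest quality-weighted read count (weights 1 − e, ties by
base order); the model is explicitly biallelic.  The polymorphism prior is
Watterson's segregation probability θ·Σ_{i=1}^{n−1} 1/i over the n sampled
chromosomes, capped at 0.5 to stay a proper prior at large n.  The
alternate-allele frequency maximizes the cohort likelihood under
Hardy–Weinberg by EM on the three-component mixture; because the mixture
can be multimodal for very small cohorts, EM restarts from {f₀, 0.05, 0.5,
0.95} (f₀ = quality-weighted non-reference read fraction) and the highest
final likelihood wins, with the result clipped to [1/2n, 1 − 1/2n].  The
estimate is validated against a 10⁻⁴-step grid search in the tests.  A site
is emitted when the posterior probability of polymorphism exceeds 0.5
(site quality > 3); real selection happens downstream by ranking, so this
threshold is deliberately permissive.  Genotypes combine the per-sample
likelihood with the HWE prior at f̂ and use the same 0.99 threshold; at
rare sites this prior calls zero-coverage cells reference-homozygous
((1−f̂)² ≥ 0.99 whenever f̂ ≤ 0.005), which is the mechanism behind PBC's
low missingness.  Replicate pairs can be split across two call runs via the
sample-subset option so that replicates never inform each other's calls.

## LD-aware refinement (LDC)

A Li–Stephens haplotype-copying HMM refines PBC calls without adding or
removing sites.  The hidden state is the ordered pair of template
haplotypes being copied, from a panel of K haplotypes drawn uniformly
(without replacement, fresh per sample per iteration) from the other
samples' current haplotypes.  Transitions switch each haplotype
independently with per-interval probability 1 − exp(−r·d_kb): a single
region-wide crossover rate r per kb, so that dense in-target markers and
sparse flanking markers are handled on a common genetic-distance scale.
Emissions mix the per-marker likelihood triplet over a per-marker copying
error ε_m: sequence markers use the read likelihoods, unmasked scaffold
markers a chip-genotype likelihood with chip error 0.002 (chip error must
be nonzero: chip genotyping is itself imperfect), and masked or missing
markers are flat.  Refinement runs per target region (the target interval
plus its ≤500 kb scaffold flanks), keeping distant regions independent, as
one would run this caller per gene.

Each iteration visits samples in random order, computes exact
forward–backward marginals over the K² states (validated against full path
enumeration in the tests), samples a haplotype pair from the posterior
(forward-filter backward-sample, then per-allele sampling), and
re-estimates r and ε from the sampled switch and mismatch counts —
stochastic EM in the MaCH tradition, rather than accumulating expected
counts, because the sampled-path counts are already available and their
noise is immaterial after a few iterations.  The copying-error rate is
estimated *per marker*: rare variants genuinely mismatch almost any
template, and a single global ε would let them degrade emission confidence
at well-imputable markers.

**Consensus.**  After a burn-in, per-iteration marginal posterior triplets
are combined per genotype cell by their *median* (renormalized), not their
mean.  At desk-scale panel sizes the mean is fragile: an iteration whose
random K-haplotype panel happens to contain no haplotype matching a
sample's background produces diffuse marginals, and even a few such
iterations push the best:second posterior ratio of a well-determined
genotype below the 99:1 filter.  The median rejects these minority
iterations while preserving genuine uncertainty (a genotype that is soft in
most iterations stays soft).  Dosage is the expected alternate count of the
consensus triplet; per-site imputation quality is
R̂² = Var(dosage)/(2f̄(1−f̄)) clipped to [0, 1], with monomorphic dosage
vectors scored 0.  With a single-sample cohort there is no panel and the
input HWE posteriors are returned unchanged.

Defaults follow the standard setting (30 iterations, K = 200 reference
haplotypes, burn-in 10).  The comparison trials and the acceptance run use
a scaled-down budget (12 and 10 iterations, K = 20, burn-in 3–4), chosen
as the package's desk-scale working point; the panel size and the
generator's founder count are a joint constraint (K/F ≳ 3), since a panel
that cannot represent every founder background re-introduces exactly the
contamination the median consensus guards against.

## QC ladder

Per-site features — quality-weighted allele-balance deviation among het
carriers, mean depth, mean GQ, call rate, signed heterozygote-excess z
(observed minus expected hets under HWE at the sample frequency, over its
binomial SD), and site quality — feed a standardized linear SVM trained on
labelled good/bad sites (in synthetic runs, truth variants vs. injected
artifacts).  Alignment-level features (strand bias, indel proximity) do not
exist in pileup-only data and are excluded.  Sites are ranked by signed
margin; a fixed-size top-K set is selected among positive scores (ties by
genomic order; fewer-than-K positives truncate with a warning).  LD call
sets drop sites with R̂² < 0.7 before ranking.  Genotype hard filters apply
after site selection: IBC GQ < 20 or depth < 7; PBC GQ < 20; LDC posterior
ratio < 99:1.  Filters only add missing marks or remove sites — never alter
a called genotype.

## Evaluation statistics

Ts/Tv counts A↔G and C↔T substitutions against the rest, one substitution
per alternate allele at multi-allelic sites, and is flagged undefined with
zero transversions.  The heterozygote mismatch rate h_e is the number of
genotypes het in one set and homozygous in the other divided by the total
hets of both sets, over cells non-missing in both; it is symmetric.
Replicate concordance restricts h_e to sites where at least one member of a
pair is het.  The additional-het audit counts cells het and non-missing
under a more complex caller but missing under a simpler one, and reports
their mismatch rate against truth.  Chip no-calls are treated as missing.
Fisher's exact test is two-sided by minimum-likelihood summation (tables no
more probable than the observed one, with a 1 + 10⁻⁷ tolerance factor),
cross-checked in the tests against explicit hypergeometric enumeration.
The down-sampling experiment rebuilds nested sub-cohorts by sequential
addition, re-runs PBC per subset, and scores a reference singleton as
recovered when its carrier is in the subset, the site is emitted, and the
carrier genotype is called het; the emitted-only fraction is reported
alongside, since requiring the genotype call is the stricter reading.

## Synthetic cohorts

The generator emulates the statistical structure the comparison needs, not
reads at the alignment level:

* **Spectrum.**  Alternate-allele counts follow P(i) ∝ i^(−α) on 1..2n−1.
  α = 1 is the stationary neutral spectrum (the default of the drawing
  primitive); the cohort generator defaults to α = 2, because human exon
  cohorts show a strong rare-variant excess (well over half of discovered
  SNVs are singletons) that the neutral spectrum cannot produce — under
  1/i the singleton share of segregating sites is 1/H_{2n−1} ≈ 13% at
  n = 500.
* **LD.**  Variants at frequency ≥ 0.02 and all chip markers live on F = 6
  founder haplotypes; sample haplotypes are founder mosaics switching at
  0.01/kb, so markers within a 4 kb target are tightly linked, flanking
  markers decay over ~100 kb, and separate targets (1.2 Mb apart) are
  independent.  Rarer variants are placed directly on sample chromosomes
  that share one founder background at the site — a recent mutation is a
  single event, identical by descent among its carriers.
* **Coverage.**  Depth is Poisson with mean 24 · a_sample · b_site, with
  unit-mean gamma factors (shape 10 per sample, shape 2 per site): capture
  efficiency varies far more across positions than library size across
  samples, producing per-cell depths from 0 to several times the mean.
  Base qualities draw from {20, 25, 30, 35} with mean error ≈ 0.2%.
* **Replicates.**  80 pairs scaled by cohort size (minimum 2): duplicate
  read columns with identical truth genotypes and independent reads.
* **Chip scaffold.**  Genotypes at flanking markers (~1 per 16 kb of flank)
  and at common (f ≥ 0.05) on-target markers, perturbed at error rate
  0.002 once per individual (replicate columns share the perturbed chip).
* **Artifacts.**  5% extra non-variant sites where 30% of samples show a
  35% non-reference read fraction — the heterozygote-excess failure mode
  that site ranking must learn, at a severity that leaves some low-depth
  artifacts genuinely hard.
* **Known sites.**  True variants at frequency ≥ 0.01, emulating a public
  variant archive.

Everything derives from one integer seed.  What the generator does *not*
model: indels, strand and mapping artifacts, base-quality miscalibration,
sequence-context mutation-rate heterogeneity (so true tri-allelic sites do
not arise; multi-allelic calling is exercised on constructed genotypes and
on error-driven second alternates), and capture chemistry beyond the gamma
factors.  Passing tests therefore demonstrate the statistical machinery
under the stated generative model, not robustness to alignment-level
artifacts in real data.

## Problem sizes

The qualitative comparison trials run 300 samples × 2,000 target sites
(plus 5% artifact sites and 480 flanking markers) at 24x, ten seeds, with
the scaled-down HMM budget above; the parameter-recovery check runs 200
samples × 1,000 sites at fixed frequencies {0.005, 0.05, 0.5}; oracle
equivalences (naive-product likelihoods, grid-search frequencies, path-
enumeration HMM marginals) run on instances small enough for the oracle to
be exact.  One full trial takes about 75 s on a single CPU.

## Known limitations

* The comparison scale (n = 300) preserves every qualitative contrast of
  the full-cohort setting except one: the individual-based caller's
  advantage on low-coverage singletons requires the population HWE prior at
  the singleton frequency (≈1/n) to be *weaker* than the individual prior
  θ/3, i.e. cohorts of several thousand samples.  At n = 300 the population
  caller's singleton prior is an order of magnitude stronger, and it calls
  a superset of the individual caller's low-depth singletons; the
  down-sampling trend (recovery non-increasing in n) shows the same
  mechanism from the other side.
* Site ranking substitutes a documented six-feature linear classifier for
  production SVMs trained on richer alignment-level features.
* The pileup reader supports the common text dialect only (no BAM/CRAM).
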