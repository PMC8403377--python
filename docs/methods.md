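# Methods

`lpsprs` asks a single design question on fully synthetic data: for
polygenic-risk-score (PRS) work, how does low-pass whole-genome sequencing
(LPS, ~0.5–5× mean depth) followed by genotype imputation compare with a
genotyping array, and how much of LPS's behavior depends on imputing from
genotype *likelihoods* rather than from fixed genotype *calls*? This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments can and cannot say about real data.

## Synthetic data model

**Population pool and reference panel.** Variation lives in a population
pool of phased haplotypes over M biallelic SNPs in a single region (default
300 haplotypes, M = 300, 1 Mb). Per-site population frequencies are drawn
from a density ∝ 1/p truncated to [max(maf_min, 1/2K), 0.5] — the
neutral-theory excess of rare alleles — so the rare (< 0.5%), low (0.5–5%)
and common (≥ 5%) frequency strata used throughout are all populated.
Variation is carried at two levels, a crude but targeted stand-in for
coalescent haplotype sharing:

* *founder-borne* sites: carrier counts of stochastically rounded p·F are
  assigned among min(20, K) founders, and every pool haplotype is a copying
  mosaic of the founders (junction probability 0.001 per interval), so
  low-frequency and common alleles ride shared haplotype backgrounds;
* *private* sites: alleles too rare for any founder get round(p·K) carriers
  placed on individual haplotypes — young alleles on single backgrounds.

The reference panel the HMM copies from is a random subsample of the pool
(default 150 of 300 haplotypes). That subsampling is the load-bearing piece
of realism: private rare alleles are frequently absent from the panel even
though targets carry them — the dominant mechanism behind poor rare-variant
imputation in practice — while founder-borne common variation survives
subsampling and stays imputable. The drawn frequency is kept as
`population_af` and plays the role of an external allele-frequency reference
(the analogue of a large public frequency database) when stratifying
accuracy by AF; realized panel AF (quantized at 1/K, and zero for
subsampled-away alleles) could not populate the rare bin.

**Target cohorts.** Diploid targets are generated by the Li–Stephens copying
process over the *population pool*: each target haplotype copies pool
haplotypes with switch probability 1 − exp(−c·d) per interval
(c = 10⁻⁶/bp by default, about one switch per Mb, matching the imputation
HMM's default) and per-allele copying error 5×10⁻⁴. Relative to the
reference panel the targets are near — but not exactly within — the copying
model class: common structure is shared through the founders, while panel
subsampling withholds part of the pool's haplotype diversity. Imputation
accuracy must still rise with sequencing depth on this data.

**Genetic architecture and phenotypes.** `n_causal` SNPs (default 15)
receive Gaussian effects on the standardized genotype scale, rescaled so the
genetic variance equals h² (default 0.2). Causal sites are sampled with
probability ∝ p(1−p): association power scales with heterozygosity, so
published risk SNPs are predominantly common, as in real disease panels.
Published weights add Gaussian noise (sd 0.05) to the true betas; published
P-values come from a Wald-test normal approximation at an effective GWAS
sample size of 30,000 (a free parameter of the generator — real weight
tables rarely state one — chosen so that genome-wide-significant thresholds
separate causal from null SNPs without being trivial). Binary phenotypes
follow a liability-threshold model: liability = genetic value + N(0, 1−h²),
case iff liability > Φ⁻¹(1−prevalence), prevalence 0.01. The study cohort
samples 87 cases and 101 controls from a pool of 15,000. h² = 0 is allowed
and gives the null architecture used for calibration checks.

**Sequencing reads.** The read model is site-level: per (individual, site)
the depth is Poisson(mean depth) — optionally gamma-Poisson with variance
mean(1 + φ·mean) to emulate non-uniform coverage — and each read reports the
alternate allele with probability (g/2)(1−ε) + (1−g/2)ε, ε = 10⁻³. Low-pass
data are produced by binomial thinning of a deep (30×) source, which
preserves Poisson depth at the target mean and leaves allele composition
unbiased. There are no read lengths, mapping errors or unmappable regions;
consequently coverage saturates at 1 (not at the ~87% mappable-genome
ceiling real pipelines show), and printed coverage fractions follow
1 − e^(−depth).

**Array route.** A fraction of sites (default 0.16) is designated "array
typed", sampled ∝ p(1−p) to mimic array design bias toward common variants;
typed genotypes equal the truth flipped to another value with probability
10⁻³, and everything else is untyped. The 0.16 default makes the typed count
≈ 0.4× the sites covered at 0.5× sequencing, the relative yield the analysis
contrasts.

## Imputation model

The hidden state is an *ordered pair* of panel haplotypes; transitions
factorize per haplotype (switch probability 1 − exp(−s·d), landing uniformly
on the panel, default s = 10⁻⁶/bp ≈ one switch per region); the copied
allele is miscopied with probability μ = 1/K unless configured. Posteriors
are computed by exact forward–backward over the K² pair states in scaled
probability space (per-site normalization), with per-site work reduced by
two structural facts: the emission takes only three values (it depends only
on the copied genotype h_i + h_j), and posterior mass per copied genotype is
obtained from haplotype-indicator contractions rather than per-state sums.
This exact recursion is a deliberate methodological stand-in for the Gibbs
samplers and pre-phasing pipelines used at biobank scale: at desk scale the
exact posterior is computable and is the quantity those samplers
approximate. There is no chunking/ligation, no iterative phasing refinement
and no PBWT compression.

Two emission modes share everything else, so performance differences are
attributable to the emissions alone:

* **GL mode** — emission = Σ_g′ P(g′ | copied genotype, μ) · L(g′), with
  L the binomial read likelihoods L(g) = Binom(n_alt; n, p_g). Sites without
  reads emit uniformly.
* **Hard-call mode** — L concentrates 1 − θ on the fixed argmax call
  (θ = 0.01), uniform at missing calls (depth below 1 read).

Outputs are posterior genotype probabilities GP, dosage DS = GP(1) + 2·GP(2)
and a per-site MaCH-style INFO score r̂² = Var(DS)/(2p̂(1−p̂)), p̂ = mean
(DS)/2, defined as 0 at p̂ ∈ {0,1} and clipped to [0,1]. Sites with INFO
strictly below 0.3 are filtered before the headline concordance metrics, in
both modes (real pipelines state this filter only for the call-based route;
applying it to both is this package's documented default, with
`info_threshold` exposed).

Numerics: float64 by default; the pipeline runs production arms in float32
(dosage differences vs float64 are ≲ 10⁻⁶, far below any metric's
resolution). Scaled-probability normalization keeps every site's state
distribution at unit mass; hard-call and best-guess argmax ties break toward
the smaller genotype (reference-majority convention). Batch size over
individuals is chosen from a memory cap (default 110 MB of forward storage).

## Metrics

* Pearson R² between true genotypes and imputed dosages (pooled over
  individuals × sites, or per SNP).
* Non-reference discordance rate (NDR): among pairs where truth or best
  guess carries an alternate allele, the fraction discordant. The exact
  denominator convention of tool-internal NDR implementations is not
  standardized; this definition is the package's stated contract.
* FPR (truth hom-ref, imputed carries alt) and FNR (truth carries alt,
  imputed hom-ref).
* Aggregate R² per AF bin, reported **both** as pooled R² and as
  mean ± SD of per-SNP R² — the term is used both ways in the field, so both
  are emitted with explicit labels.
* Fraction-more-accurate: among SNPs imputed on both platforms with
  max R² > 0.8, the fraction where platform A's per-SNP R² strictly exceeds
  B's (ties count in the denominator only).
* Coverage: covered fraction (share of sites with ≥ 1 read) and the Gini
  coefficient of 10-kb-window read counts via the trapezoidal Lorenz area
  (windows sorted ascending, empty windows included — dropping them would
  understate nonuniformity at very low depth). Windowed counts sum site
  depths, not read starts (site-level read model).
* PRS = Σ_k w_k X_k with X counted on the effect allele (dosage flipped to
  2 − DS when the effect allele is the reference allele); scores are
  mean-centered. Imputed data are scored on dosages, not best-guess
  genotypes. Missing subset SNPs are skipped and logged (a mean-imputation
  alternative is deliberately not the default).
* P+T: greedy LD clumping (visit by ascending P, drop SNPs with genotype
  r² ≥ 0.5 against a kept SNP, ties by position), then a P-threshold scan
  over 5×10⁻²…10⁻²⁰ keeping the threshold with the best AUC; thresholds
  retaining zero SNPs are recorded as null rows, not errors.
* AUC is the Mann–Whitney statistic (ties half-weight) with a stratified
  bootstrap percentile 95% CI (2,000 resamples, seeded) — a bootstrap rather
  than an asymptotic interval because it is distribution-free and direct to
  verify by simulation.

## Experiment layout

`run_experiment` mirrors a two-cohort design: a deep-sequenced evaluation
cohort (default 50 individuals at 30×, thinned to 0.5/1/2/5×) drives
coverage and concordance for GL mode, hard-call mode and the array route;
a separate 87-case/101-control cohort drives P+T and unadjusted PRS models,
AUC with CIs, case/control score distributions and cross-platform score
correlations (computed on the fixed significant-SNP unadjusted model so the
same SNP set underlies both platforms). One global seed fans out to named
per-stage seeds via a SeedSequence table; outputs are TSV/JSON with a
manifest recording the config, its hash and all stage seeds, and identical
configs reproduce byte-identical outputs.

The acceptance script runs this default experiment; the test suite runs the
same generator conditions at smaller problem sizes chosen for runtime
(e.g. 8–40 individuals, K = 100–150, M = 200–300 for the imputation
contrasts; 10⁵ sites for coverage analytics; tiny 2–3-site panels for exact
path-enumeration checks). The AF-stratified acceptance check is computed on
all imputed dosages *without* the INFO filter: filtering first would keep
only the well-imputed survivors of the rare bin and mask exactly the
rare-variant behavior under study.

## What passing does and does not show

Passing tests show the pipeline's internal consistency and the qualitative
structure of the LPS-vs-array question under a generator that favors the
copying model: targets really are mosaics of the population the panel was
sampled from, reads really are conditionally binomial, and the AF reference
is exact. They do not
demonstrate performance on real genomes — no mapping artifacts, no panel
misspecification (real targets are not mosaics of any panel), no indels or
multi-allelic sites, no population structure, a single small region rather
than a genome, and a panel orders of magnitude smaller than production
panels. Absolute metric levels (R², NDR, Gini, AUC) therefore differ from
published values on real cohorts; the package's claims are the *relations*:
GL-mode dominates hard-call mode at low depth, accuracy rises from rare to
common bins and with depth, LPS beats the array at rare frequencies, and
platform score correlations are high at moderate depth.

## Known limitations

* The K² state space is exact but quadratic; production-size panels require
  the sampling/compression machinery this package intentionally omits.
* NDR/FPR/FNR use best-guess genotypes; probabilistic versions are not
  implemented.
* The Wald-test effective sample size behind published P-values is a free
  generator parameter, not estimated from anything.
* Bayesian PRS weighting schemes are out of scope; the report schema only
  reserves labels for them.
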