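"""Synthetic reference panels, target cohorts, GWAS weights and phenotypes.

The generator produces the statistical structure the downstream analysis
assumes: a phased biallelic-SNP haplotype panel with linkage disequilibrium
and an excess of rare alleles, diploid targets whose haplotypes are mosaics
of the panel (the regime a haplotype-copying imputation model is built for),
per-SNP effect sizes with noisy "published" weights, and binary phenotypes
from a liability-threshold model.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HaplotypePanel",
    "DiploidGenotypes",
    "GWASWeights",
    "PhenotypeSet",
    "simulate_panel",
    "simulate_cohort",
    "assign_effects",
    "simulate_phenotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes over ordered biallelic SNPs.

    ``alleles`` has one row per haplotype and one column per site, entries in
    {0, 1} (0 = reference allele). Positions are 1-based physical coordinates,
    strictly increasing. ``population_af`` is the generative population
    frequency each site was drawn at — the stand-in for an external
    allele-frequency reference; the panel's realized AF is its finite-sample
    version.
    """

    positions: np.ndarray
    alleles: np.ndarray
    site_ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    population_af: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != self.positions.size:
            raise ValueError("alleles must be (n_haplotypes, n_sites)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0/1")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if len(set(self.site_ids)) != self.site_ids.size:
            raise ValueError("duplicate site_ids")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def allele_frequencies(self) -> np.ndarray:
        """Panel alternate-allele frequency per site."""
        return self.alleles.mean(axis=0)


@dataclass
class DiploidGenotypes:
    """Diploid genotypes (alt-allele counts in {0,1,2}), individuals x sites.

    Columns align with the generating panel's sites. When produced by
    :func:`simulate_cohort` the underlying phased haplotypes are kept.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    site_ids: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be in {0,1,2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_frequencies(self) -> np.ndarray:
        """Empirical cohort alt-allele frequency per site."""
        return self.genotypes.mean(axis=0) / 2.0

    def subset(self, individuals: np.ndarray) -> "DiploidGenotypes":
        haps = None
        if self.haplotypes is not None:
            idx = np.repeat(np.asarray(individuals) * 2, 2)
            idx[1::2] += 1
            haps = self.haplotypes[idx]
        return DiploidGenotypes(
            self.genotypes[individuals], self.positions, self.site_ids, haps
        )


@dataclass
class GWASWeights:
    """Per-SNP published weights plus the simulation ground truth.

    ``effect_allele`` is the ref/alt orientation of the published weight;
    ``weight`` is the per-copy effect of the effect allele on the
    standardized-genotype scale. ``true_beta`` is the causal effect on the
    standardized alt-allele dosage (the generative truth, not observable in a
    real study).
    """

    site_id: np.ndarray
    effect_allele: np.ndarray  # 'ref' or 'alt'
    weight: np.ndarray
    p_value: np.ndarray
    is_causal: np.ndarray
    true_beta: np.ndarray

    def __post_init__(self) -> None:
        if not ((self.p_value > 0) & (self.p_value <= 1)).all():
            raise ValueError("p_value must be in (0, 1]")

    @property
    def n_snps(self) -> int:
        return self.site_id.size

    @property
    def alt_weight(self) -> np.ndarray:
        """Published weight re-oriented to the alternate allele."""
        return np.where(self.effect_allele == "alt", self.weight, -self.weight)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "effect_allele": self.effect_allele,
                "weight": self.weight,
                "p_value": self.p_value,
                "is_causal": self.is_causal,
                "true_beta": self.true_beta,
            }
        )


@dataclass
class PhenotypeSet:
    """Liability-threshold case/control labels over a simulated pool.

    ``labels``/``liability`` cover the whole pool; ``case_indices`` and
    ``control_indices`` are the sampled study cohort, and ``selected`` is
    their concatenation (cases first) — the individuals carried forward into
    sequencing and scoring.
    """

    labels: np.ndarray
    liability: np.ndarray
    case_indices: np.ndarray
    control_indices: np.ndarray
    h2: float
    prevalence: float

    @property
    def selected(self) -> np.ndarray:
        return np.concatenate([self.case_indices, self.control_indices])

    @property
    def selected_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(self.case_indices.size, dtype=np.int8),
             np.zeros(self.control_indices.size, dtype=np.int8)]
        )


def _mosaic_indices(rng, n_rows, n_sites, n_sources, switch_prob):
    """Source-row index per (row, site) for a copying mosaic.

    switch_prob may be a scalar or a per-interval vector of length n_sites-1.
    """
    draws = rng.integers(0, n_sources, size=(n_rows, n_sites))
    u = rng.random(size=(n_rows, n_sites))
    switch = np.empty((n_rows, n_sites), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = u[:, 1:] < switch_prob
    # forward-fill the source drawn at the most recent switch
    last = np.where(switch, np.arange(n_sites), 0)
    last = np.maximum.accumulate(last, axis=1)
    return np.take_along_axis(draws, last, axis=1)


def simulate_panel(
    n_haplotypes: int,
    n_sites: int,
    region_length: int = 1_000_000,
    maf_min: float = 0.0,
    seed: int = 0,
    n_founders: int | None = None,
    mosaic_switch_prob: float = 0.001,
) -> HaplotypePanel:
    """Simulate a phased reference panel with LD and a 1/p frequency spectrum.

    Site frequencies are drawn from a density proportional to 1/p truncated to
    [max(maf_min, 1/(2K)), 0.5] — the neutral-theory excess of rare alleles
    that populates the rare/low/common AF strata downstream. Variation is
    carried at two levels, mirroring how real haplotype sharing works:

    * founder-borne sites — carriers among the ``min(20, n_haplotypes)``
      founders are assigned as the stochastically rounded count ``p * F``, and
      every haplotype is a copying mosaic of the founders, so these (mostly
      low/common) alleles ride on shared haplotype backgrounds;
    * private sites — sites too rare for any founder (``round(p * F) = 0``)
      receive ``max(1, round(p * K))`` carriers placed on individual
      haplotypes. These young alleles sit on single haplotypes, which is why
      they survive subsampling poorly (see :func:`subsample_panel`) and are
      the hard case for imputation.

    Sites always stay polymorphic, and when ``maf_min > 0`` the realized AF is
    confined to [maf_min, 1 - maf_min] by flipping majority-allele entries.
    The drawn frequencies are returned as ``population_af``.
    """
    if n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if maf_min > 0 and maf_min < 1.0 / n_haplotypes:
        raise ValueError(
            f"maf_min={maf_min} cannot be represented with {n_haplotypes} "
            f"haplotypes (minimum nonzero frequency is 1/{n_haplotypes})"
        )
    rng = np.random.default_rng(seed)

    lo = max(maf_min, 1.0 / (2 * n_haplotypes))
    u = rng.random(n_sites)
    freqs = lo * (0.5 / lo) ** u  # inverse CDF of f(p) ∝ 1/p on [lo, 0.5]

    positions = np.sort(rng.choice(region_length, size=n_sites, replace=False)) + 1

    n_f = min(20, n_haplotypes) if n_founders is None else min(n_founders, n_haplotypes)
    # stochastic rounding of p * F keeps the founder AF unbiased
    scaled = freqs * n_f
    f_count = np.floor(scaled).astype(int)
    f_count += rng.random(n_sites) < (scaled - f_count)
    founders = np.zeros((n_f, n_sites), dtype=np.uint8)
    for m in np.flatnonzero(f_count > 0):
        founders[rng.choice(n_f, size=min(f_count[m], n_f), replace=False), m] = 1
    if n_haplotypes > n_f:
        idx = _mosaic_indices(rng, n_haplotypes - n_f, n_sites, n_f, mosaic_switch_prob)
        rest = np.take_along_axis(founders, idx, axis=0)
        alleles = np.vstack([founders, rest])
    else:
        alleles = founders

    H = n_haplotypes
    min_count = max(1, int(np.ceil(maf_min * H))) if maf_min > 0 else 1
    counts = alleles.sum(axis=0).astype(int)
    # private-variation path: sites no founder carries get round(p * K)
    # carriers on individual haplotypes
    target = np.where(
        counts == 0,
        np.maximum(np.rint(freqs * H).astype(int), min_count),
        np.clip(counts, min_count, H - min_count),
    )
    for m in np.flatnonzero(counts != target):
        c, t = counts[m], target[m]
        if c < t:
            rows = np.flatnonzero(alleles[:, m] == 0)
            alleles[rng.choice(rows, size=t - c, replace=False), m] = 1
        else:
            rows = np.flatnonzero(alleles[:, m] == 1)
            alleles[rng.choice(rows, size=c - t, replace=False), m] = 0

    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    site_ids = np.array([f"rs{p}" for p in positions], dtype=object)
    return HaplotypePanel(
        positions=positions,
        alleles=alleles,
        site_ids=site_ids,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        population_af=freqs,
    )


def subsample_panel(panel: HaplotypePanel, n_haplotypes: int, seed: int = 0) -> HaplotypePanel:
    """A reference panel as a random haplotype subsample of a population.

    Real reference panels are finite samples of the population their targets
    come from: rare alleles are frequently absent from the subsample even
    though targets carry them, which is the main reason rare variants impute
    poorly. Subsampled sites may be monomorphic within the reference panel.
    ``population_af`` is inherited from the source panel.
    """
    if n_haplotypes > panel.n_haplotypes:
        raise ValueError("cannot subsample more haplotypes than the panel holds")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(panel.n_haplotypes, size=n_haplotypes, replace=False))
    return HaplotypePanel(
        positions=panel.positions,
        alleles=panel.alleles[rows],
        site_ids=panel.site_ids,
        ref=panel.ref,
        alt=panel.alt,
        population_af=panel.population_af,
    )


def simulate_cohort(
    panel: HaplotypePanel,
    n_individuals: int,
    switch_rate: float = 1e-6,
    mutation_rate: float = 5e-4,
    seed: int = 0,
) -> DiploidGenotypes:
    """Draw diploid targets as Li–Stephens copying mosaics of the panel.

    Each target haplotype copies one panel haplotype at a time, switching
    between consecutive sites with probability 1 - exp(-switch_rate * d)
    (d = physical distance in bp) and flipping the copied allele with
    probability ``mutation_rate``. The genotype is the sum of the two
    haplotypes.
    """
    if panel.n_sites == 0 or panel.n_haplotypes == 0:
        raise ValueError("panel must be non-empty")
    if not (0 <= switch_rate and 0 <= mutation_rate <= 1):
        raise ValueError("rates must be non-negative (mutation_rate <= 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    M = panel.n_sites
    dist = np.diff(panel.positions)
    rho = 1.0 - np.exp(-switch_rate * dist)

    idx = _mosaic_indices(rng, n_hap, M, panel.n_haplotypes, rho)
    haps = np.take_along_axis(panel.alleles, idx, axis=0)
    if mutation_rate > 0:
        flips = rng.random((n_hap, M)) < mutation_rate
        haps = np.where(flips, 1 - haps, haps).astype(np.uint8)
    genotypes = haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)
    return DiploidGenotypes(
        genotypes=genotypes,
        positions=panel.positions,
        site_ids=panel.site_ids,
        haplotypes=haps,
    )


def assign_effects(
    panel_afs: np.ndarray,
    n_causal: int,
    h2: float,
    weight_noise_sd: float = 0.05,
    seed: int = 0,
    site_ids: np.ndarray | None = None,
    eff_sample_size: float = 30_000.0,
    common_causal_bias: bool = True,
) -> GWASWeights:
    """Draw causal effects and the noisy "published" GWAS weight table.

    Causal standardized effects are Gaussian, rescaled so the variance of the
    standardized genetic score equals ``h2`` (sum of squared betas under
    linkage equilibrium). Published weights are the true betas plus Gaussian
    noise of sd ``weight_noise_sd`` (non-causal SNPs: noise only). P-values
    for causal SNPs come from the normal approximation of a Wald test at an
    effective GWAS sample size of ``eff_sample_size``; non-causal SNPs are
    uniform. The published effect allele is chosen at random per SNP and the
    stored weight is oriented to it.

    Causal sites are sampled with probability proportional to the
    heterozygosity p (1 - p): GWAS power scales with heterozygosity, so
    published risk SNPs are predominantly common — mirroring real
    disease-association panels. Uniform sampling is available via
    ``common_causal_bias=False``.

    ``h2 = 0`` is allowed and yields an all-null table (every true beta zero).
    """
    panel_afs = np.asarray(panel_afs, dtype=float)
    n_sites = panel_afs.size
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if n_causal > n_sites:
        raise ValueError("n_causal exceeds number of sites")
    rng = np.random.default_rng(seed)
    if site_ids is None:
        site_ids = np.array([f"s{i:06d}" for i in range(n_sites)], dtype=object)

    true_beta = np.zeros(n_sites)
    is_causal = np.zeros(n_sites, dtype=bool)
    if n_causal > 0:
        if common_causal_bias:
            het = panel_afs * (1 - panel_afs) + 1e-12
            causal = rng.choice(n_sites, size=n_causal, replace=False,
                                p=het / het.sum())
        else:
            causal = rng.choice(n_sites, size=n_causal, replace=False)
        is_causal[causal] = True
        if h2 > 0:
            raw = rng.standard_normal(n_causal)
            raw *= np.sqrt(h2 / np.sum(raw**2))
            true_beta[causal] = raw

    noise = rng.normal(0.0, weight_noise_sd, n_sites) if weight_noise_sd > 0 else 0.0
    alt_weight = true_beta + noise

    p_value = rng.uniform(0.0, 1.0, n_sites)
    if is_causal.any() and h2 > 0:
        z = true_beta[is_causal] * np.sqrt(eff_sample_size) + rng.standard_normal(
            is_causal.sum()
        )
        p_causal = 2 * stats.norm.sf(np.abs(z))
        p_value[is_causal] = np.clip(p_causal, np.nextafter(0, 1), 1.0)

    effect_allele = np.where(rng.random(n_sites) < 0.5, "alt", "ref").astype(object)
    weight = np.where(effect_allele == "alt", alt_weight, -alt_weight)
    return GWASWeights(
        site_id=np.asarray(site_ids, dtype=object),
        effect_allele=effect_allele,
        weight=weight,
        p_value=p_value,
        is_causal=is_causal,
        true_beta=true_beta,
    )


def genetic_values(genotypes: DiploidGenotypes, weights: GWASWeights) -> np.ndarray:
    """True standardized genetic score per individual (simulation truth).

    Genotypes are standardized as (x - 2p) / sqrt(2 p (1-p)) with p the
    empirical cohort AF, making the variance contributed by each causal SNP
    equal to its squared beta irrespective of allele frequency. Monomorphic
    sites contribute zero.
    """
    p = genotypes.allele_frequencies
    sd = np.sqrt(2 * p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (genotypes.genotypes - 2 * p) / np.where(sd > 0, sd, 1), 0.0)
    return z @ weights.true_beta


def simulate_phenotypes(
    genotypes: DiploidGenotypes,
    weights: GWASWeights,
    prevalence: float = 0.01,
    n_cases: int = 87,
    n_controls: int = 101,
    seed: int = 0,
) -> PhenotypeSet:
    """Liability-threshold case/control phenotypes and cohort sampling.

    liability = genetic value + N(0, 1 - h2); an individual is a case iff
    liability exceeds the normal quantile Phi^-1(1 - prevalence). The study
    cohort is then sampled without replacement: ``n_cases`` from the cases and
    ``n_controls`` from the controls of the simulated pool. Raises when the
    pool cannot supply either group (prevalence/pool-size mismatch).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    g = genetic_values(genotypes, weights)
    h2 = float(np.sum(weights.true_beta**2))
    resid_sd = np.sqrt(max(0.0, 1.0 - h2))
    liability = g + rng.normal(0.0, resid_sd, genotypes.n_individuals)
    threshold = stats.norm.ppf(1.0 - prevalence)
    labels = (liability > threshold).astype(np.int8)

    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == 0)
    if cases.size < n_cases or controls.size < n_controls:
        raise ValueError(
            f"pool supplies {cases.size} cases / {controls.size} controls; "
            f"requested {n_cases}/{n_controls} — increase pool size or prevalence"
        )
    case_idx = np.sort(rng.choice(cases, size=n_cases, replace=False))
    control_idx = np.sort(rng.choice(controls, size=n_controls, replace=False))
    return PhenotypeSet(
        labels=labels,
        liability=liability,
        case_indices=case_idx,
        control_indices=control_idx,
        h2=h2,
        prevalence=prevalence,
    )
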