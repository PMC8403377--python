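"""Site-level sequencing read simulation, genotype likelihoods and calls.

The read model is deliberately site-level: per (individual, site) it keeps
only the reference/alternate read counts at a given mean depth and per-base
miscall rate. That is exactly the evidence the downstream genotype-likelihood
and concordance machinery consumes; read lengths, mapping and base qualities
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import DiploidGenotypes

__all__ = [
    "SiteReads",
    "GenotypeLikelihoods",
    "CalledGenotypes",
    "simulate_reads",
    "downsample_reads",
    "compute_gl",
    "hard_call",
    "simulate_array",
]

MISSING = -1  # sentinel for no-call genotypes


@dataclass
class SiteReads:
    """Per-individual, per-site (n_ref, n_alt) read counts."""

    n_ref: np.ndarray
    n_alt: np.ndarray
    mean_depth: float
    error_rate: float
    positions: np.ndarray
    site_ids: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt


@dataclass
class GenotypeLikelihoods:
    """log P(reads | g) for g in {0,1,2}, shape (individuals, sites, 3).

    At zero depth the three log-likelihoods are equal (no data). ``depth`` is
    carried along so calling rules can declare no-calls.
    """

    log_gl: np.ndarray
    depth: np.ndarray
    positions: np.ndarray
    site_ids: np.ndarray

    def linear_normalized(self) -> np.ndarray:
        """Likelihood triples rescaled to sum to 1 (linear space)."""
        m = self.log_gl.max(axis=-1, keepdims=True)
        lin = np.exp(self.log_gl - m)
        return lin / lin.sum(axis=-1, keepdims=True)


@dataclass
class CalledGenotypes:
    """Fixed genotype calls in {0,1,2}, with -1 marking missing."""

    calls: np.ndarray
    positions: np.ndarray
    site_ids: np.ndarray

    @property
    def missing(self) -> np.ndarray:
        return self.calls == MISSING


def _alt_prob(genotypes: np.ndarray, error_rate: float) -> np.ndarray:
    g = genotypes.astype(float)
    return (g / 2.0) * (1 - error_rate) + (1 - g / 2.0) * error_rate


def simulate_reads(
    genotypes: DiploidGenotypes,
    mean_depth: float,
    error_rate: float = 0.001,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> SiteReads:
    """Draw per-site read counts at a requested mean depth.

    Depth is Poisson(mean_depth) when ``overdispersion`` is 0, else
    gamma-Poisson (negative binomial) with the same mean and variance
    mean * (1 + overdispersion * mean) — the overdispersed regime produces
    the non-uniform coverage the Lorenz/Gini diagnostics are built to expose.
    Each read reports the alternate allele with probability
    (g/2)(1-eps) + (1-g/2) eps.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    shape = genotypes.genotypes.shape
    if mean_depth == 0:
        depth = np.zeros(shape, dtype=np.int64)
    elif overdispersion > 0:
        lam = rng.gamma(1.0 / overdispersion, overdispersion * mean_depth, shape)
        depth = rng.poisson(lam)
    else:
        depth = rng.poisson(mean_depth, shape)
    n_alt = rng.binomial(depth, _alt_prob(genotypes.genotypes, error_rate))
    return SiteReads(
        n_ref=(depth - n_alt).astype(np.int64),
        n_alt=n_alt.astype(np.int64),
        mean_depth=float(mean_depth),
        error_rate=error_rate,
        positions=genotypes.positions,
        site_ids=genotypes.site_ids,
    )


def downsample_reads(reads: SiteReads, target_depth: float, seed: int = 0) -> SiteReads:
    """Binomial thinning: keep each read independently with p = target/current.

    Thinning acts on ref and alt counts independently, so the allele
    composition is unbiased; thinning a Poisson depth yields a Poisson depth
    at the target mean.
    """
    if target_depth > reads.mean_depth:
        raise ValueError(
            f"target depth {target_depth} exceeds current mean depth {reads.mean_depth}"
        )
    rng = np.random.default_rng(seed)
    p = target_depth / reads.mean_depth if reads.mean_depth > 0 else 0.0
    if p == 1.0:
        n_ref, n_alt = reads.n_ref.copy(), reads.n_alt.copy()
    else:
        n_ref = rng.binomial(reads.n_ref, p)
        n_alt = rng.binomial(reads.n_alt, p)
    return SiteReads(
        n_ref=n_ref,
        n_alt=n_alt,
        mean_depth=float(target_depth),
        error_rate=reads.error_rate,
        positions=reads.positions,
        site_ids=reads.site_ids,
    )


def compute_gl(reads: SiteReads, error_rate: float | None = None) -> GenotypeLikelihoods:
    """Binomial genotype likelihoods L(g) = Binom(n_alt; n, p_g) in log space.

    p_g = (g/2)(1-eps) + (1-g/2) eps. The binomial coefficient is genotype
    independent and kept, so triples are proportional to the product of
    per-read likelihoods; with no reads all three are equal.
    """
    eps = reads.error_rate if error_rate is None else error_rate
    if not 0 < eps < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    n = reads.depth
    log_gl = np.empty(n.shape + (3,), dtype=float)
    for g in (0, 1, 2):
        p_g = _alt_prob(np.full((), g), eps)
        log_gl[..., g] = stats.binom.logpmf(reads.n_alt, n, p_g)
    return GenotypeLikelihoods(
        log_gl=log_gl,
        depth=n,
        positions=reads.positions,
        site_ids=reads.site_ids,
    )


def hard_call(gl: GenotypeLikelihoods, min_depth: int = 1) -> CalledGenotypes:
    """Fixed calls by likelihood argmax; missing where depth < min_depth.

    Ties break toward the smaller genotype (argmax takes the first maximum),
    the reference-majority convention.
    """
    calls = np.argmax(gl.log_gl, axis=-1).astype(np.int8)
    calls[gl.depth < min_depth] = MISSING
    return CalledGenotypes(calls=calls, positions=gl.positions, site_ids=gl.site_ids)


def simulate_array(
    genotypes: DiploidGenotypes,
    array_fraction: float = 0.16,
    array_error: float = 0.001,
    seed: int = 0,
    afs: np.ndarray | None = None,
) -> CalledGenotypes:
    """Genotyping-array route: truth at a biased subset of sites, missing elsewhere.

    Array sites are drawn without replacement with probability proportional to
    the heterozygosity p(1-p) (``afs`` defaults to the cohort AF), mimicking
    array design bias toward common variants. Typed genotypes equal the truth
    flipped to a uniformly chosen *other* value with probability
    ``array_error``. The default ``array_fraction`` of 0.16 makes the typed
    set about 0.4x the count of sites covered at 0.5x sequencing
    (1 - e^-0.5 ~ 0.39), matching the relative array-vs-LPS site yield the
    analysis contrasts.
    """
    if not 0 < array_fraction <= 1:
        raise ValueError("array_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    M = genotypes.n_sites
    p = genotypes.allele_frequencies if afs is None else np.asarray(afs, dtype=float)
    w = p * (1 - p) + 1e-12
    k = max(1, int(round(array_fraction * M)))
    sites = np.sort(rng.choice(M, size=k, replace=False, p=w / w.sum()))

    calls = np.full(genotypes.genotypes.shape, MISSING, dtype=np.int8)
    truth = genotypes.genotypes[:, sites]
    calls_at = truth.copy()
    if array_error > 0:
        flip = rng.random(truth.shape) < array_error
        shift = rng.integers(1, 3, truth.shape)  # move to one of the two other values
        calls_at = np.where(flip, (truth + shift) % 3, truth).astype(np.int8)
    calls[:, sites] = calls_at
    return CalledGenotypes(
        calls=calls, positions=genotypes.positions, site_ids=genotypes.site_ids
    )
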