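"""Diploid Li–Stephens haplotype-copying imputation HMM.

The hidden state at each site is an ordered pair (i, j) of reference-panel
haplotypes the two target haplotypes are currently copying. Each haplotype
switches independently between consecutive sites with probability
1 - exp(-switch_rate * distance), landing uniformly on the panel; the copied
allele is miscopied with per-allele probability mu. Posteriors are computed
by an exact forward–backward recursion over the K^2 pair states in scaled
probability space.

Two emission modes isolate the genotype-likelihood vs fixed-call contrast:

* GL mode — the emission for a state with copied genotype g is
  sum_g' P(g' | g, mu) * L(g'), with L the binomial read likelihoods. This is
  the exact-posterior stand-in for Gibbs-sampling GL imputation of low-pass
  data.
* hard-call mode — identical HMM, but L(g') concentrates (1 - theta) on the
  fixed call (theta/2 on the other genotypes) and is uniform at missing
  sites. This is the stand-in for phase-then-impute pipelines that consume
  genotype calls.

Everything downstream — posterior genotype probabilities GP, expected dosage
DS = GP(1) + 2 GP(2), and the MaCH-style INFO score — is shared, so any
performance difference between the modes is attributable to the emissions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reads import MISSING, CalledGenotypes, GenotypeLikelihoods
from .simulate import HaplotypePanel

__all__ = [
    "HmmParams",
    "ImputedDosages",
    "impute_gl",
    "impute_hardcall",
    "info_score",
    "filter_by_info",
]


@dataclass
class HmmParams:
    """Copying-model parameters.

    switch_rate: per-bp switch intensity (per-interval switch probability is
    1 - exp(-switch_rate * distance)). miscopy: per-allele copying error mu;
    ``None`` resolves to 1/K at imputation time, the common Li–Stephens
    choice. call_error: genotype-observation error theta for hard-call mode.
    """

    switch_rate: float = 1e-6
    miscopy: float | None = None
    call_error: float = 0.01

    def resolve_miscopy(self, n_haplotypes: int) -> float:
        mu = 1.0 / n_haplotypes if self.miscopy is None else self.miscopy
        if not 0 < mu < 0.5:
            raise ValueError("miscopy rate must be in (0, 0.5)")
        return mu


@dataclass
class ImputedDosages:
    """Posterior genotype probabilities, dosages and per-site INFO scores."""

    gp: np.ndarray  # (individuals, sites, 3), rows sum to 1
    positions: np.ndarray
    site_ids: np.ndarray
    info: np.ndarray  # (sites,)

    @property
    def dosage(self) -> np.ndarray:
        return self.gp[..., 1] + 2.0 * self.gp[..., 2]

    @property
    def best_guess(self) -> np.ndarray:
        """Argmax-GP genotype, ties toward the smaller genotype."""
        return np.argmax(self.gp, axis=-1).astype(np.int8)


def _miscopy_matrix(mu: float) -> np.ndarray:
    """C[pg, g'] = P(true genotype g' | copied pair genotype pg, miscopy mu)."""
    C = np.empty((3, 3))
    for pg, (q1, q2) in enumerate([(mu, mu), (mu, 1 - mu), (1 - mu, 1 - mu)]):
        C[pg] = [
            (1 - q1) * (1 - q2),
            q1 * (1 - q2) + (1 - q1) * q2,
            q1 * q2,
        ]
    return C


def _transition(f: np.ndarray, rho: float, K: int) -> np.ndarray:
    """One interval of the factorized pair transition applied to (B, K, K)."""
    if rho == 0.0:
        return f
    f = (1 - rho) * f + (rho / K) * f.sum(axis=1, keepdims=True)
    f = (1 - rho) * f + (rho / K) * f.sum(axis=2, keepdims=True)
    return f


def _batched_posteriors(
    L: np.ndarray,
    panel: HaplotypePanel,
    params: HmmParams,
    max_batch_bytes: int = 110_000_000,
    dtype=np.float64,
) -> np.ndarray:
    """Exact forward–backward GP for emission weights L of shape (N, M, 3).

    The emission for pair state (i, j) at site m takes one of only three
    values — it depends on the copied genotype h_i + h_j — so per-state work
    reduces to gathers from a (B, 3) table and, in the backward pass, to
    haplotype-indicator contractions that split the state posterior mass by
    copied genotype without materializing per-state quotients. ``dtype``
    trades precision for memory bandwidth (float32 is ample for dosages; the
    default keeps full double precision).
    """
    K = panel.n_haplotypes
    M = panel.n_sites
    N = L.shape[0]
    if K < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    mu = params.resolve_miscopy(K)
    C = _miscopy_matrix(mu).astype(dtype)
    rho = 1.0 - np.exp(-params.switch_rate * np.diff(panel.positions.astype(float)))

    H = panel.alleles.astype(np.int8)
    pair_geno = (H[:, None, :] + H[None, :, :]).astype(np.int8)  # (K, K, M)
    hvec = panel.alleles.astype(dtype)  # (K, M)
    L = L.astype(dtype)
    # per-site state emission values by copied genotype: E[n, m, pg]
    E = np.einsum("nmg,pg->nmp", L, C)

    itemsize = np.dtype(dtype).itemsize
    batch = max(1, int(max_batch_bytes // (M * K * K * itemsize)))
    gp = np.empty((N, M, 3))
    tiny = np.finfo(dtype).tiny
    for lo in range(0, N, batch):
        hi = min(N, lo + batch)
        B = hi - lo
        E_b = E[lo:hi]  # (B, M, 3)
        fwd = np.empty((M, B, K, K), dtype=dtype)
        f = E_b[:, 0][:, pair_geno[:, :, 0]] / (K * K)
        f /= np.maximum(f.sum(axis=(1, 2), keepdims=True), tiny)
        fwd[0] = f
        for m in range(1, M):
            f = _transition(f, rho[m - 1], K)
            f *= E_b[:, m][:, pair_geno[:, :, m]]
            f /= np.maximum(f.sum(axis=(1, 2), keepdims=True), tiny)
            fwd[m] = f

        b = np.full((B, K, K), 1.0 / (K * K), dtype=dtype)
        for m in range(M - 1, -1, -1):
            w = fwd[m] * b  # unnormalized state posterior
            h = hvec[:, m]
            # posterior mass by copied genotype, via indicator contractions
            u1 = w @ h  # (B, K): sum over j with h_j = 1
            r = w.sum(axis=2)  # (B, K)
            s11 = u1 @ h
            s1dot = r @ h  # rows with h_i = 1
            scol1 = u1.sum(axis=1)  # cols with h_j = 1
            stot = r.sum(axis=1)
            mass = np.stack(
                [stot - s1dot - scol1 + s11, s1dot + scol1 - 2 * s11, s11], axis=1
            )
            # fold the miscopy/emission split back out of the state posterior
            u_pg = mass / np.maximum(E_b[:, m], tiny)
            g_un = (u_pg @ C) * L[lo:hi, m]
            gp[lo:hi, m] = g_un / np.maximum(g_un.sum(axis=1, keepdims=True), tiny)
            if m > 0:
                b *= E_b[:, m][:, pair_geno[:, :, m]]
                b = _transition(b, rho[m - 1], K)
                b /= np.maximum(b.sum(axis=(1, 2), keepdims=True), tiny)
    return gp


def _align_to_panel(
    site_ids: np.ndarray, panel: HaplotypePanel, L: np.ndarray
) -> np.ndarray:
    """Expand emission weights onto the panel's site grid (uniform where absent)."""
    panel_index = {s: i for i, s in enumerate(panel.site_ids)}
    idx = np.array([panel_index.get(s, -1) for s in site_ids])
    if (idx < 0).any():
        bad = np.asarray(site_ids)[idx < 0][:5]
        raise ValueError(f"sites absent from panel: {list(bad)}")
    full = np.full((L.shape[0], panel.n_sites, 3), 1.0 / 3.0)
    full[:, idx, :] = L
    return full


def impute_gl(
    gl: GenotypeLikelihoods,
    panel: HaplotypePanel,
    params: HmmParams | None = None,
    dtype=np.float64,
) -> ImputedDosages:
    """Impute posterior dosages from genotype likelihoods (GL emission mode).

    GL sites must be a subset of panel sites; panel sites without read
    evidence receive uniform emissions and are imputed from the copying
    prior plus flanking information.
    """
    params = params or HmmParams()
    L = gl.linear_normalized()
    L = _align_to_panel(gl.site_ids, panel, L)
    gp = _batched_posteriors(L, panel, params, dtype=dtype)
    return ImputedDosages(
        gp=gp,
        positions=panel.positions,
        site_ids=panel.site_ids,
        info=info_score(gp[..., 1] + 2.0 * gp[..., 2]),
    )


def impute_hardcall(
    calls: CalledGenotypes,
    panel: HaplotypePanel,
    params: HmmParams | None = None,
    dtype=np.float64,
) -> ImputedDosages:
    """Impute posterior dosages from fixed genotype calls (hard-call mode).

    The emission is L(g') = 1 - theta at the called genotype and theta/2 at
    the two others; missing calls emit uniformly. The HMM and everything
    downstream are identical to GL mode.
    """
    params = params or HmmParams()
    theta = params.call_error
    if not 0 <= theta < 1:
        raise ValueError("call_error must be in [0, 1)")
    c = calls.calls
    L = np.full(c.shape + (3,), theta / 2.0)
    for g in (0, 1, 2):
        L[..., g][c == g] = 1.0 - theta
    L[c == MISSING] = 1.0 / 3.0
    L = _align_to_panel(calls.site_ids, panel, L)
    gp = _batched_posteriors(L, panel, params, dtype=dtype)
    return ImputedDosages(
        gp=gp,
        positions=panel.positions,
        site_ids=panel.site_ids,
        info=info_score(gp[..., 1] + 2.0 * gp[..., 2]),
    )


def info_score(dosages: np.ndarray) -> np.ndarray:
    """MaCH-style imputation INFO score r-hat^2 per site.

    r2 = Var(DS across individuals) / (2 p (1-p)) with p = mean(DS)/2
    (population variance). Defined as 0 when p is 0 or 1; clipped to [0, 1].
    Accepts a (individuals, sites) dosage matrix; needs >= 2 individuals for
    a meaningful variance.
    """
    ds = np.asarray(dosages, dtype=float)
    if ds.ndim == 1:
        ds = ds[:, None]
    p = ds.mean(axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    var = ds.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, var / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0)


def filter_by_info(dosages: ImputedDosages, threshold: float = 0.3) -> np.ndarray:
    """Boolean mask of sites retained at the INFO threshold.

    Sites with INFO strictly below the threshold are removed (a site at
    exactly the threshold is kept), matching the "filtered variants with
    information score below 0.3" convention.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return dosages.info >= threshold
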