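"""Polygenic risk scores: PRS = sum_k w_k X_k, with P+T model selection.

X_k counts copies of the *effect* allele: for SNPs whose published effect
allele is the reference allele, the alt-dosage is flipped to 2 - X before
weighting. Imputed data are scored on dosages, not best-guess genotypes.
Scores are normalized to cohort mean zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import auc
from .simulate import GWASWeights

__all__ = [
    "PRSResult",
    "compute_prs",
    "normalize_scores",
    "ld_clump",
    "p_plus_t",
    "DEFAULT_P_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLDS = (
    5e-2, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-8, 1e-10, 1e-12, 1e-15, 1e-20,
)


@dataclass
class PRSResult:
    raw: np.ndarray
    normalized: np.ndarray | None
    model: str
    snps_used: list
    snps_skipped: list

    @property
    def scores(self) -> np.ndarray:
        """Normalized scores when available, else raw."""
        return self.raw if self.normalized is None else self.normalized


def compute_prs(
    dosages: np.ndarray,
    site_ids: np.ndarray,
    weights: GWASWeights,
    snp_subset,
    model: str = "unadjusted",
) -> PRSResult:
    """Raw PRS over a SNP subset; subset SNPs absent from the data are skipped.

    ``dosages`` is (individuals, sites) of alt-allele dosages or genotype
    counts aligned with ``site_ids``. An effectively empty subset (nothing
    scorable) raises — it signals that upstream filtering removed every SNP.
    """
    dosages = np.asarray(dosages, dtype=float)
    col = {s: i for i, s in enumerate(site_ids)}
    wcol = {s: i for i, s in enumerate(weights.site_id)}
    used, skipped = [], []
    score = np.zeros(dosages.shape[0])
    for s in snp_subset:
        if s not in col or s not in wcol:
            skipped.append(s)
            continue
        k = wcol[s]
        x = dosages[:, col[s]]
        if weights.effect_allele[k] == "ref":
            x = 2.0 - x
        score = score + weights.weight[k] * x
        used.append(s)
    if not used:
        raise ValueError("no scorable SNPs in subset (all filtered or missing)")
    if skipped:
        logger.info("compute_prs: skipped %d missing SNPs: %s", len(skipped), skipped[:10])
    return PRSResult(raw=score, normalized=None, model=model,
                     snps_used=used, snps_skipped=skipped)


def normalize_scores(result: PRSResult) -> PRSResult:
    """Mean-zero normalization of the cohort's raw scores."""
    if result.raw.size < 1:
        raise ValueError("need at least one individual")
    return replace(result, normalized=result.raw - result.raw.mean())


def ld_clump(
    reference_genotypes: np.ndarray,
    site_ids: np.ndarray,
    weights: GWASWeights,
    r2_threshold: float = 0.5,
    positions: np.ndarray | None = None,
) -> list:
    """Greedy LD clumping: keep the most significant SNP per LD block.

    SNPs are visited by ascending P-value (ties broken by position, then
    site id); a SNP is dropped if its squared genotype correlation with any
    already-kept SNP is >= ``r2_threshold``. Returns the retained site ids.
    """
    col = {s: i for i, s in enumerate(site_ids)}
    idx = [i for i, s in enumerate(weights.site_id) if s in col]
    if not idx:
        return []
    G = np.asarray(reference_genotypes, dtype=float)
    if positions is None:
        positions = np.arange(len(site_ids))
    pos = {s: positions[col[s]] for s in weights.site_id if s in col}

    order = sorted(idx, key=lambda k: (weights.p_value[k], pos[weights.site_id[k]],
                                       str(weights.site_id[k])))
    X = G - G.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    kept: list = []
    kept_cols: list = []
    for k in order:
        s = weights.site_id[k]
        c = col[s]
        drop = False
        for kc in kept_cols:
            if norms[c] == 0 or norms[kc] == 0:
                continue  # monomorphic: treated as uncorrelated
            r = (X[:, c] @ X[:, kc]) / (norms[c] * norms[kc])
            if r * r >= r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(s)
            kept_cols.append(c)
    return kept


def p_plus_t(
    dosages: np.ndarray,
    site_ids: np.ndarray,
    weights: GWASWeights,
    labels: np.ndarray,
    thresholds=DEFAULT_P_THRESHOLDS,
    r2_threshold: float = 0.5,
    ld_reference: np.ndarray | None = None,
) -> tuple[PRSResult | None, pd.DataFrame]:
    """Clumping + thresholding PRS: scan P thresholds, keep the best AUC.

    Clumping runs once (on ``ld_reference`` genotypes if given, else on the
    scoring matrix itself); each threshold then restricts to clumped SNPs
    with P < threshold, scores the cohort, and records the AUC against the
    case/control labels. Thresholds retaining zero SNPs get a null AUC row.
    Returns (best-threshold normalized PRSResult or None, full AUC table).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("need at least one P threshold")
    ld_ref = dosages if ld_reference is None else ld_reference
    clumped = ld_clump(ld_ref, site_ids, weights, r2_threshold)
    pv = {s: weights.p_value[i] for i, s in enumerate(weights.site_id)}

    rows = []
    best: PRSResult | None = None
    best_auc = -np.inf
    for t in thresholds:
        subset = [s for s in clumped if pv[s] < t]
        if not subset:
            rows.append((t, 0, np.nan))
            continue
        res = normalize_scores(
            compute_prs(dosages, site_ids, weights, subset, model=f"P+T@{t:g}")
        )
        a = auc(res.scores, labels, ci=False).auc
        rows.append((t, len(subset), a))
        if a > best_auc:
            best_auc, best = a, res
    table = pd.DataFrame(rows, columns=["p_threshold", "n_snps", "auc"])
    return best, table
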