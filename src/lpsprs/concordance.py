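"""Genotype concordance metrics between truth and imputed data.

Includes overall Pearson R^2 between true genotypes and imputed dosages,
non-reference discordance rate (NDR), false positive/negative rates on
best-guess genotypes, aggregate R^2 stratified by allele-frequency bin
(rare / low / common), and the two-platform fraction-more-accurate
comparison.

Metrics with an empty denominator or a constant input return NaN — an
explicit undefined-result signal, distinct from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AfBins",
    "ConcordanceReport",
    "pearson_r2",
    "per_snp_r2",
    "ndr",
    "fpr_fnr",
    "aggregate_r2_by_bin",
    "fraction_more_accurate",
    "concordance_report",
]


@dataclass(frozen=True)
class AfBins:
    """Non-reference allele-frequency strata.

    Default interior edges 0.5% and 5%: rare (AF < 0.5%),
    low (0.5% <= AF < 5%), common (AF >= 5%).
    """

    edges: tuple = (0.005, 0.05)
    labels: tuple = ("rare", "low", "common")

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size + 1 != len(self.labels):
            raise ValueError("need len(edges) + 1 labels")
        if e.size and (not (np.diff(e) > 0).all() or e[0] <= 0 or e[-1] >= 1):
            raise ValueError("edges must be strictly increasing within (0, 1)")

    def assign(self, afs: np.ndarray) -> np.ndarray:
        return np.digitize(np.asarray(afs, dtype=float), self.edges)


@dataclass
class ConcordanceReport:
    r2_overall: float
    ndr: float
    fpr: float
    fnr: float
    per_bin: pd.DataFrame
    per_snp_r2: np.ndarray = field(repr=False, default=None)


def pearson_r2(truth: np.ndarray, dosage: np.ndarray) -> float:
    """Squared Pearson correlation between true genotypes and dosages.

    NaN when either vector is constant (undefined, not zero).
    """
    t = np.asarray(truth, dtype=float).ravel()
    d = np.asarray(dosage, dtype=float).ravel()
    if t.size != d.size:
        raise ValueError("length mismatch")
    if t.size < 2:
        raise ValueError("need at least 2 pairs")
    t = t - t.mean()
    d = d - d.mean()
    st, sd = np.sqrt((t**2).sum()), np.sqrt((d**2).sum())
    if st == 0 or sd == 0:
        return float("nan")
    r = (t * d).sum() / (st * sd)
    return float(r * r)


def per_snp_r2(truth: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Column-wise R^2 for (individuals, sites) matrices; NaN where undefined."""
    t = np.asarray(truth, dtype=float)
    d = np.asarray(dosage, dtype=float)
    t = t - t.mean(axis=0)
    d = d - d.mean(axis=0)
    st = np.sqrt((t**2).sum(axis=0))
    sd = np.sqrt((d**2).sum(axis=0))
    num = (t * d).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((st > 0) & (sd > 0), num / (st * sd), np.nan)
    return r * r


def ndr(truth: np.ndarray, imputed: np.ndarray) -> float:
    """Non-reference discordance rate on best-guess genotypes.

    Among pairs where truth or imputed carries at least one alternate allele,
    the fraction that disagree. NaN when no pair qualifies (e.g. both vectors
    all hom-ref) — the hom-ref majority never enters the denominator.
    """
    t = np.asarray(truth).ravel()
    i = np.asarray(imputed).ravel()
    if t.size != i.size:
        raise ValueError("length mismatch")
    mask = (t > 0) | (i > 0)
    if not mask.any():
        return float("nan")
    return float(np.mean(t[mask] != i[mask]))


def fpr_fnr(truth: np.ndarray, imputed: np.ndarray) -> tuple[float, float]:
    """False positive and false negative rates on best-guess genotypes.

    FPR: among truth hom-ref pairs, the fraction imputed with >= 1 alternate
    allele. FNR: among truth alt-carrying pairs, the fraction imputed hom-ref.
    Each component is NaN when its denominator is empty.
    """
    t = np.asarray(truth).ravel()
    i = np.asarray(imputed).ravel()
    if t.size != i.size:
        raise ValueError("length mismatch")
    hom_ref = t == 0
    carrier = t > 0
    fpr = float(np.mean(i[hom_ref] > 0)) if hom_ref.any() else float("nan")
    fnr = float(np.mean(i[carrier] == 0)) if carrier.any() else float("nan")
    return fpr, fnr


def aggregate_r2_by_bin(
    truth: np.ndarray,
    dosages: np.ndarray,
    afs: np.ndarray,
    bins: AfBins | None = None,
) -> pd.DataFrame:
    """Aggregate imputation accuracy per allele-frequency bin.

    Reports BOTH the pooled R^2 (all individual x site pairs in the bin
    concatenated) and the mean +/- SD of per-SNP R^2 (SNPs with a defined
    R^2 only), with the SNP count per bin — the two readings of "aggregate
    R^2" are labelled explicitly. Empty bins appear with n = 0 and NaN
    statistics.
    """
    bins = bins or AfBins()
    truth = np.asarray(truth, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    afs = np.asarray(afs, dtype=float)
    if truth.shape != dosages.shape or truth.shape[1] != afs.size:
        raise ValueError("shape mismatch between truth, dosages and afs")
    which = bins.assign(afs)
    snp_r2 = per_snp_r2(truth, dosages)
    rows = []
    for b, label in enumerate(bins.labels):
        cols = np.flatnonzero(which == b)
        if cols.size == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan))
            continue
        pooled = (
            pearson_r2(truth[:, cols], dosages[:, cols])
            if truth[:, cols].size >= 2
            else np.nan
        )
        defined = snp_r2[cols][~np.isnan(snp_r2[cols])]
        rows.append(
            (
                label,
                cols.size,
                pooled,
                defined.mean() if defined.size else np.nan,
                defined.std(ddof=1) if defined.size > 1 else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["bin", "n_snps", "pooled_r2", "mean_snp_r2", "sd_snp_r2"]
    )


def fraction_more_accurate(
    per_snp_r2_a: np.ndarray,
    per_snp_r2_b: np.ndarray,
    quality_threshold: float = 0.8,
) -> float:
    """Fraction of high-quality shared SNPs where platform A beats platform B.

    Vectors must be aligned on the shared SNPs (NaN entries on either side
    are dropped). The comparison is restricted to SNPs where
    max(R^2_a, R^2_b) exceeds ``quality_threshold``; ties count in the
    denominator but never in the numerator. NaN when no SNP qualifies.
    """
    a = np.asarray(per_snp_r2_a, dtype=float)
    b = np.asarray(per_snp_r2_b, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must align on shared SNPs")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    sel = np.maximum(a, b) > quality_threshold
    if not sel.any():
        return float("nan")
    return float(np.mean(a[sel] > b[sel]))


def concordance_report(
    truth: np.ndarray,
    dosages: np.ndarray,
    best_guess: np.ndarray,
    afs: np.ndarray,
    bins: AfBins | None = None,
) -> ConcordanceReport:
    """Full concordance panel: R^2, NDR, FPR/FNR and the per-AF-bin table."""
    return ConcordanceReport(
        r2_overall=pearson_r2(truth, dosages),
        ndr=ndr(truth, best_guess),
        fpr=fpr_fnr(truth, best_guess)[0],
        fnr=fpr_fnr(truth, best_guess)[1],
        per_bin=aggregate_r2_by_bin(truth, dosages, afs, bins),
        per_snp_r2=per_snp_r2(truth, dosages),
    )
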