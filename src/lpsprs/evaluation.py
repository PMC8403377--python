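"""Discrimination and agreement statistics for PRS models.

AUC is the Mann–Whitney probability that a random case outscores a random
control (ties count one half), with a stratified-bootstrap 95% confidence
interval. Cross-platform agreement is plain Pearson correlation of
normalized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AucResult", "GroupSummary", "auc", "roc_points", "score_correlation",
           "group_summary"]


@dataclass
class AucResult:
    auc: float
    ci_low: float | None
    ci_high: float | None
    n_cases: int
    n_controls: int


@dataclass
class GroupSummary:
    case_mean: float
    control_mean: float
    bin_edges: np.ndarray
    case_density: np.ndarray
    control_density: np.ndarray


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> AucResult:
    """AUC with a stratified-bootstrap percentile 95% CI.

    Cases and controls are resampled within their own strata (2000 replicates
    by default, seeded). Raises when a class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    point = _mann_whitney_auc(scores, labels)
    lo = hi = None
    if ci:
        rng = np.random.default_rng(seed)
        s_case = scores[labels == 1]
        s_ctrl = scores[labels == 0]
        boot = np.empty(n_boot)
        lab = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
        for b in range(n_boot):
            sc = s_case[rng.integers(0, n1, n1)]
            st = s_ctrl[rng.integers(0, n0, n0)]
            boot[b] = _mann_whitney_auc(np.concatenate([sc, st]), lab)
        lo, hi = (float(x) for x in np.percentile(boot, [2.5, 97.5]))
    return AucResult(auc=point, ci_low=lo, ci_high=hi, n_cases=n1, n_controls=n0)


def roc_points(scores: np.ndarray, labels: np.ndarray):
    """Exact step-function ROC over all unique thresholds: (fpr, tpr) arrays."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def score_correlation(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Pearson r and r^2 between two platforms' scores on the same individuals.

    NaN pair when either vector is constant. Requires n >= 3.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ValueError("individuals must align")
    if a.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def group_summary(scores: np.ndarray, labels: np.ndarray, n_bins: int = 20) -> GroupSummary:
    """Per-group score means and binned densities (for case/control overlays).

    The direction of the case-control mean difference is reported, never
    assumed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must be present")
    edges = np.histogram_bin_edges(scores, bins=n_bins)
    case_d, _ = np.histogram(scores[labels == 1], bins=edges, density=True)
    ctrl_d, _ = np.histogram(scores[labels == 0], bins=edges, density=True)
    return GroupSummary(
        case_mean=float(scores[labels == 1].mean()),
        control_mean=float(scores[labels == 0].mean()),
        bin_edges=edges,
        case_density=case_d,
        control_density=ctrl_d,
    )
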