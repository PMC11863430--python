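"""X-chromosome upregulation statistics from cross-species factor swaps.

After the model predicts, for each anchor cell, its expression profile in
two species, the per-cell profiles are normalized so their housekeeping-gene
mass is 1, a per-gene log2 fold change between the species is computed per
cell, and the per-gene median across cells summarizes the shift. Genes are
grouped by evolutionary origin (XAR: X-linked only in eutherians; XCR:
X-linked in both mammal clades; autosomal elsewhere) and each group's median
log2FC is tested against dosage-compensation null hypotheses with a
one-sided one-sample Wilcoxon signed-rank test. GGACH (m6A) motif rates in
coding sequence provide an orthogonal RNA-stability comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

XAR, XCR, AUTOSOME = "XAR", "XCR", "AUTOSOME"

__all__ = [
    "XAR", "XCR", "AUTOSOME", "GeneGroupAnnotation", "CrossSpeciesFC",
    "housekeeping_normalize", "per_gene_median_log2fc", "xcu_test",
    "adjust_pvalues", "ggach_frequency", "motif_shift_test",
]


@dataclass(frozen=True)
class GeneGroupAnnotation:
    gene: str
    group: str           # XAR, XCR or AUTOSOME
    chromosomes: tuple = ()   # optional per-species chromosome labels

    def __post_init__(self):
        if self.group not in (XAR, XCR, AUTOSOME):
            raise ValueError(f"unknown gene group {self.group!r}")


@dataclass
class CrossSpeciesFC:
    gene: str
    log2fc_per_cell: np.ndarray
    median_log2fc: float


def housekeeping_normalize(profiles: np.ndarray, hk_mask) -> np.ndarray:
    """Scale each cell (row) so its housekeeping-gene expression sums to 1.

    Cells with zero housekeeping mass are excluded with a warning, so the
    output may have fewer rows than the input.
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=np.float64))
    hk_mask = np.asarray(hk_mask, dtype=bool)
    if hk_mask.shape[0] != X.shape[1]:
        raise ValueError("housekeeping mask length must match the gene axis")
    if not hk_mask.any():
        raise ValueError("no housekeeping genes in the vocabulary")
    mass = X[:, hk_mask].sum(axis=1)
    ok = mass > 0
    if not ok.all():
        import warnings
        warnings.warn(f"excluding {int((~ok).sum())} cells with zero "
                      "housekeeping mass")
    return X[ok] / mass[ok, None]


def per_gene_median_log2fc(pred_upper: np.ndarray, pred_lower: np.ndarray,
                           pseudocount: float = 1e-2) -> np.ndarray:
    """Median over cells of per-cell log2((upper + eps) / (lower + eps)).

    Both inputs must be housekeeping-normalized matrices over the same cells
    and genes; the small pseudocount keeps fold changes finite.
    """
    U = np.atleast_2d(np.asarray(pred_upper, dtype=np.float64))
    L = np.atleast_2d(np.asarray(pred_lower, dtype=np.float64))
    if U.shape != L.shape:
        raise ValueError("predictions must share cells and genes")
    fc = np.log2(U + pseudocount) - np.log2(L + pseudocount)
    return np.median(fc, axis=0)


# -- one-sample Wilcoxon signed-rank test -----------------------------------

def _signed_rank_pvalue_exact(ranks2: np.ndarray, signs: np.ndarray,
                              alternative: str) -> float:
    """Exact one-sided p over all sign assignments via subset-sum counting.

    `ranks2` holds twice the midranks (integers even under ties), so the
    distribution of 2*W+ is the coefficient sequence of prod(1 + x^r).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w_obs = int(ranks2[signs > 0].sum())
    if alternative == "greater":
        return float(counts[w_obs:].sum())
    return float(counts[:w_obs + 1].sum())


def _signed_rank_pvalue_normal(ranks: np.ndarray, signs: np.ndarray,
                               alternative: str) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    w = ranks[signs > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return np.nan
    if alternative == "greater":
        z = (w - mean - 0.5) / np.sqrt(var)
        return float(_stats.norm.sf(z))
    z = (w - mean + 0.5) / np.sqrt(var)
    return float(_stats.norm.cdf(z))


def xcu_test(values, null_median: float, alternative: str = "greater",
             exact_threshold: int = 25) -> float:
    """One-sided one-sample Wilcoxon signed-rank test against `null_median`.

    Tests H0 "median <= null_median" (alternative="greater") or H0
    "median >= null_median" (alternative="less"). Zero differences are
    dropped; the null distribution is exact (all sign assignments of the
    ranked absolute differences) for n <= `exact_threshold` and a
    tie-corrected normal approximation beyond. Returns NaN when every value
    equals the null median.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(values, dtype=np.float64) - null_median
    if not np.all(np.isfinite(d)):
        raise ValueError("values must be finite")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return np.nan
    ranks = _stats.rankdata(np.abs(d))
    signs = np.sign(d)
    if n <= exact_threshold:
        ranks2 = np.round(2 * ranks).astype(int)
        return _signed_rank_pvalue_exact(ranks2, signs, alternative)
    return _signed_rank_pvalue_normal(ranks, signs, alternative)


def adjust_pvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- m6A motif counting ------------------------------------------------------

_H = frozenset("ACTU")
_VALID = frozenset("ACGTUN")


def ggach_frequency(cds: str):
    """Count GGACH (H in {A, C, T/U}) occurrences and the per-kb rate.

    Overlapping matches are counted; returns ``(count, per_kb)``.
    """
    seq = cds.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= _VALID:
        raise ValueError("sequence must be over A, C, G, T/U, N")
    seq = seq.replace("U", "T")
    count = sum(1 for i in range(len(seq) - 4)
                if seq[i:i + 4] == "GGAC" and seq[i + 4] in _H)
    return count, count * 1000.0 / len(seq)


def motif_shift_test(delta_freq_group, delta_freq_autosome) -> float:
    """One-sided Mann-Whitney U: is the group's motif-frequency change
    shifted downward relative to autosomal genes?"""
    g = np.asarray(delta_freq_group, dtype=np.float64)
    a = np.asarray(delta_freq_autosome, dtype=np.float64)
    if g.size == 0 or a.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(_stats.mannwhitneyu(g, a, alternative="less").pvalue)
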