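"""Pseudobulk construction and cross-species prediction evaluation.

Prediction quality for a held-out cell type is judged at the pseudobulk
level: the predicted per-cell profiles are averaged and correlated (Pearson)
with the true held-out pseudobulk. Three comparators frame that number: a
"cheating" donor baseline (agreement between donors inside the test set), a
species baseline (the source-species profile carried over unchanged via
orthologs), and a cell-type baseline (the nearest source cell type's profile
in the target species). A relative prediction error expresses the remaining
per-gene error as a fraction of the original cross-species difference, and
an AD-vs-WT evaluation correlates predicted against observed log2
fold-change vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LIBRARY_SIZE = 10_000.0

__all__ = [
    "LIBRARY_SIZE", "PseudobulkProfile", "EvaluationResult", "pseudobulk",
    "prediction_correlation", "donor_baseline", "species_baseline",
    "celltype_baseline", "relative_prediction_error", "ad_log2fc_eval",
]


@dataclass
class PseudobulkProfile:
    """Per-gene mean of depth-normalized expression for a group of cells."""

    values: np.ndarray
    normalization: str = "linear"   # "linear" or "log"
    cell_type: str | None = None
    species: str | None = None
    donors: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class EvaluationResult:
    prediction_cor: float
    donor_baseline: float | None
    species_baseline: float
    celltype_baseline: float
    indiv_prediction: float | None


def pseudobulk(cells: np.ndarray, normalization: str = "linear",
               library_size: float = LIBRARY_SIZE, **provenance
               ) -> PseudobulkProfile:
    """Average of depth-normalized profiles over cells (rows).

    Every cell is rescaled to ``library_size`` total, then averaged; the
    "log" variant applies log2(x + 1) to the averaged profile. Zero-depth
    cells are excluded with a warning.
    """
    if normalization not in ("linear", "log"):
        raise ValueError("normalization must be 'linear' or 'log'")
    X = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("need at least one cell")
    depth = X.sum(axis=1)
    if np.any(depth == 0):
        import warnings
        warnings.warn(f"excluding {int((depth == 0).sum())} zero-depth cells")
        X = X[depth > 0]
        depth = depth[depth > 0]
        if X.shape[0] == 0:
            raise ValueError("all cells have zero depth")
    scaled = X / depth[:, None] * library_size
    values = scaled.mean(axis=0)
    if normalization == "log":
        values = np.log2(values + 1.0)
    return PseudobulkProfile(values=values, normalization=normalization,
                             **provenance)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("profiles must share the gene axis")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def prediction_correlation(pred_cells: np.ndarray, true_cells: np.ndarray,
                           normalization: str = "log") -> float:
    """Pearson correlation of predicted vs true held-out pseudobulk."""
    p = pseudobulk(pred_cells, normalization)
    t = pseudobulk(true_cells, normalization)
    return _pearson(p.values, t.values)


def donor_baseline(cells_by_donor: dict, normalization: str = "log"
                   ) -> float | None:
    """Mean pairwise correlation of per-donor pseudobulk in the test set.

    Returns None (missing) when fewer than two donors are available.
    """
    donors = sorted(cells_by_donor)
    if len(donors) < 2:
        return None
    profiles = {d: pseudobulk(cells_by_donor[d], normalization).values
                for d in donors}
    cors = [_pearson(profiles[a], profiles[b])
            for i, a in enumerate(donors) for b in donors[i + 1:]]
    return float(np.nanmean(cors))


def indiv_prediction(pred_cells: np.ndarray, cells_by_donor: dict,
                     normalization: str = "log") -> float | None:
    """Mean correlation of the prediction against each donor's pseudobulk."""
    if not cells_by_donor:
        return None
    p = pseudobulk(pred_cells, normalization).values
    cors = [_pearson(p, pseudobulk(c, normalization).values)
            for c in cells_by_donor.values()]
    return float(np.nanmean(cors))


def species_baseline(source_cells: np.ndarray, source_genes,
                     ortho_table: pd.DataFrame, source: str, target: str,
                     target_truth_cells: np.ndarray, target_genes,
                     normalization: str = "log") -> float:
    """Correlation between target truth and the ortholog-translated source.

    The source pseudobulk is carried over to target gene identifiers through
    the one-to-one table (unmapped genes dropped); both sides are depth-
    normalized and log-transformed before the Pearson correlation.
    """
    from .orthology import translate_matrix

    src = pd.DataFrame(np.atleast_2d(source_cells), columns=list(source_genes))
    translated = translate_matrix(src, ortho_table, source, target)
    if translated.shape[1] == 0:
        raise ValueError("no genes shared after ortholog translation")
    truth = pd.DataFrame(np.atleast_2d(target_truth_cells),
                         columns=list(target_genes))
    shared = [g for g in translated.columns if g in set(truth.columns)]
    if not shared:
        raise ValueError("empty gene intersection with the target truth")
    p_src = pseudobulk(translated[shared].to_numpy(), normalization)
    p_tgt = pseudobulk(truth[shared].to_numpy(), normalization)
    return _pearson(p_src.values, p_tgt.values)


def celltype_baseline(heldout_type: str, source_profiles: dict,
                      target_profiles: dict, target_truth: np.ndarray,
                      ) -> float:
    """Nearest-cell-type baseline.

    Finds the cell type (excluding the held-out one) whose source-species
    pseudobulk is closest in Euclidean distance to the held-out type's
    source profile, then correlates that type's target-species profile with
    the held-out truth. All profiles are expected depth-normalized and
    log-transformed.
    """
    if heldout_type not in source_profiles:
        raise KeyError(f"held-out type {heldout_type!r} missing in source")
    anchor = np.asarray(source_profiles[heldout_type], dtype=np.float64)
    candidates = sorted(t for t in source_profiles
                        if t != heldout_type and t in target_profiles)
    if not candidates:
        raise ValueError("need at least one other cell type in both species")
    dists = [np.linalg.norm(np.asarray(source_profiles[t]) - anchor)
             for t in candidates]
    nearest = candidates[int(np.argmin(dists))]
    return _pearson(np.asarray(target_profiles[nearest]),
                    np.asarray(target_truth))


def relative_prediction_error(pred: np.ndarray, target_ori: np.ndarray,
                              source_ori: np.ndarray):
    """Per-gene |pred - target| / |source - target| on pseudobulk values.

    Genes whose source and target original values coincide (zero
    denominator) are excluded; their count is returned alongside.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target_ori = np.asarray(target_ori, dtype=np.float64)
    source_ori = np.asarray(source_ori, dtype=np.float64)
    if not (pred.shape == target_ori.shape == source_ori.shape):
        raise ValueError("profiles must share the gene axis")
    denom = np.abs(source_ori - target_ori)
    valid = denom > 0
    err = np.abs(pred - target_ori)[valid] / denom[valid]
    return err, int((~valid).sum())


def ad_log2fc_eval(pred_ad: np.ndarray, pred_wt: np.ndarray,
                   true_ad: np.ndarray, true_wt: np.ndarray,
                   library_size: float = LIBRARY_SIZE) -> float:
    """Correlation of predicted vs observed disease/control log2 fold change.

    Each pseudobulk profile is rescaled to ``library_size`` total, 1 is
    added, and log2FC = log2((AD + 1) / (WT + 1)) is computed per gene; the
    score is the Pearson correlation between the predicted and true log2FC
    vectors (NaN when either vector is constant).
    """
    def norm(v):
        v = np.asarray(v, dtype=np.float64)
        s = v.sum()
        if s <= 0:
            raise ValueError("profile has no mass")
        return v / s * library_size

    fc_pred = np.log2(norm(pred_ad) + 1.0) - np.log2(norm(pred_wt) + 1.0)
    fc_true = np.log2(norm(true_ad) + 1.0) - np.log2(norm(true_wt) + 1.0)
    return _pearson(fc_pred, fc_true)
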