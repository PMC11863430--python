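"""Local inverse Simpson index (LISI) for label mixing in an embedding.

For each cell, neighbour weights are a Gaussian kernel over Euclidean
distances whose bandwidth is calibrated by binary search so that the
entropy of the weight distribution equals log(perplexity); the score is the
inverse Simpson index of the label distribution under those weights. A score
of 1 means the neighbourhood is one label; a score of k means k labels are
perfectly mixed locally.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def _calibrated_weights(d2: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Weights over one cell's neighbours with entropy ~= log(perplexity)."""
    target = np.log(perplexity)
    if np.allclose(d2, d2[0]):
        # degenerate geometry (e.g. all neighbours equidistant): uniform
        return np.full(d2.shape, 1.0 / d2.size)
    beta, lo, hi = 1.0, 0.0, np.inf
    for _ in range(max_iter):
        w = np.exp(-beta * (d2 - d2.min()))
        wsum = w.sum()
        p = w / wsum
        h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        if abs(h - target) < tol:
            break
        if h > target:  # too flat: sharpen
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (beta + hi)
        else:
            hi = beta
            beta = 0.5 * (beta + lo)
    return p


def compute_lisi(embeddings: np.ndarray, labels, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell LISI of `labels` in the space of `embeddings`.

    Parameters
    ----------
    embeddings
        (n_cells, n_dims) coordinates.
    labels
        Length-n categorical labels.
    perplexity
        Effective neighbourhood size; must be < n_cells.

    Returns
    -------
    Array of per-cell scores in [1, number of label levels].
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] < 2:
        raise ValueError("need at least two cells in a 2-D embedding")
    labels = np.asarray(labels)
    if labels.shape[0] != emb.shape[0]:
        raise ValueError("labels and embeddings disagree on cell count")
    n = emb.shape[0]
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of cells")

    _, codes = np.unique(labels, return_inverse=True)
    n_levels = codes.max() + 1
    k = min(n - 1, max(int(np.ceil(3 * perplexity)), 5))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)

    scores = np.empty(n)
    for i in range(n):
        # drop self; under exact ties sklearn may place it anywhere
        keep = idx[i] != i
        if keep.sum() == k + 1:
            keep[-1] = False
        di, ii = dist[i][keep], idx[i][keep]
        p = _calibrated_weights(di ** 2, perplexity)
        mass = np.bincount(codes[ii], weights=p, minlength=n_levels)
        scores[i] = 1.0 / np.sum(mass ** 2)
    return scores
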