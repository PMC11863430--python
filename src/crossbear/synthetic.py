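"""Seeded generators for every input the pipeline consumes.

The count generator mirrors the model's own generative assumptions: cells
carry low-dimensional latent identities shared across species, each species
decodes latents through its own affine perturbation of a common map into
depth-corrected means, and observed UMIs are zero-inflated negative binomial
draws. Because the species maps are known, "the same cell in another
species" has a well-defined ground truth, which is exactly what the
recovery tests need. Companion generators produce mixed-species barnyard
read counts (with injected doublets) and scored many-to-many ortholog edge
tables (with decoys and deliberate gaps for transitive filling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orthology import OrthologEdge

__all__ = ["SyntheticConfig", "ZINBDataset", "generate_zinb_dataset",
           "generate_barnyard", "generate_orthology"]


@dataclass
class SyntheticConfig:
    seed: int
    n_cells: int = 2000
    n_genes: int = 200
    n_cell_types: int = 5
    n_species: int = 2
    latent_dim_true: int = 8
    depth_range: tuple = (500, 2000)
    dispersion_range: tuple = (1.0, 10.0)
    dropout_rate_range: tuple = (0.0, 0.3)
    species_effect_scale: float = 0.6
    doublet_rate: float = 0.0
    heldout_type: bool = True

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_cell_types,
               self.n_species, self.latent_dim_true) <= 0:
            raise ValueError("all size parameters must be positive")
        if self.n_cell_types > self.n_cells:
            raise ValueError("more cell types than cells")
        lo, hi = self.dropout_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("dropout rates must lie in [0, 1]")
        if not (0 <= self.doublet_rate <= 1):
            raise ValueError("doublet_rate must lie in [0, 1]")


@dataclass
class ZINBDataset:
    """Counts plus metadata plus full generative ground truth."""

    counts: np.ndarray
    species: np.ndarray
    cell_type: np.ndarray
    batch: np.ndarray
    tissue: np.ndarray
    latents: np.ndarray
    type_centers: np.ndarray
    decoder_weights: dict          # species -> (latent_dim, n_genes)
    decoder_bias: dict             # species -> (n_genes,)
    dispersion: np.ndarray
    dropout: np.ndarray
    true_type_means: dict          # (cell_type, species) -> mean mu' profile
    heldout_type: str | None
    heldout_species: str | None
    gene_names: list = field(default_factory=list)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate_zinb_dataset(cfg: SyntheticConfig) -> ZINBDataset:
    """Draw a ZINB count matrix with known latent and species structure.

    Cell-type latent centers are standard-normal; per-species decoders are a
    shared affine map plus a species-specific perturbation scaled by
    ``species_effect_scale``. When ``heldout_type`` is set, the last cell
    type never appears in the last species (the held-out-type scenario).
    ``true_type_means`` holds, for every (type, species) pair including the
    held-out one, the expected depth-corrected mean profile estimated from
    a large fresh latent sample.
    """
    rng = np.random.default_rng(cfg.seed)
    k, g = cfg.latent_dim_true, cfg.n_genes
    types = [f"type{i}" for i in range(cfg.n_cell_types)]
    species = [f"species{chr(65 + i)}" for i in range(cfg.n_species)]
    gene_names = [f"g{j}" for j in range(g)]

    centers = rng.normal(size=(cfg.n_cell_types, k))
    W = rng.normal(size=(k, g)) / np.sqrt(k)
    decoder_weights, decoder_bias = {}, {}
    for s in species:
        decoder_weights[s] = W + cfg.species_effect_scale * \
            rng.normal(size=(k, g)) / np.sqrt(k)
        decoder_bias[s] = cfg.species_effect_scale * rng.normal(size=g)

    heldout_type = types[-1] if cfg.heldout_type and cfg.n_cell_types > 1 else None
    heldout_species = species[-1] if heldout_type else None

    sp = np.array([species[i % cfg.n_species] for i in range(cfg.n_cells)])
    ct = np.empty(cfg.n_cells, dtype=object)
    for i in range(cfg.n_cells):
        allowed = [t for t in types
                   if not (t == heldout_type and sp[i] == heldout_species)]
        ct[i] = allowed[rng.integers(len(allowed))]
    type_idx = np.array([types.index(t) for t in ct])

    latents = centers[type_idx] + 0.3 * rng.normal(size=(cfg.n_cells, k))
    r = np.exp(rng.uniform(np.log(cfg.dispersion_range[0]),
                           np.log(cfg.dispersion_range[1]), size=g))
    pi = rng.uniform(*cfg.dropout_rate_range, size=g)
    depth = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1,
                         size=cfg.n_cells)

    counts = np.empty((cfg.n_cells, g))
    for s in species:
        rows = np.where(sp == s)[0]
        if rows.size == 0:
            continue
        mu = _softmax(latents[rows] @ decoder_weights[s] + decoder_bias[s])
        mean = depth[rows, None] * mu
        lam = rng.gamma(shape=r, scale=mean / r)
        counts[rows] = rng.poisson(lam)
    counts *= rng.random(counts.shape) >= pi  # dropout zeros

    true_type_means = {}
    probe = rng.normal(size=(400, k)) * 0.3
    for t_i, t in enumerate(types):
        zz = centers[t_i] + probe
        for s in species:
            mu = _softmax(zz @ decoder_weights[s] + decoder_bias[s])
            true_type_means[(t, s)] = mu.mean(axis=0)

    n = cfg.n_cells
    return ZINBDataset(
        counts=counts, species=sp, cell_type=ct.astype(str),
        batch=np.full(n, "batch0"), tissue=np.full(n, "tissue0"),
        latents=latents, type_centers=centers,
        decoder_weights=decoder_weights, decoder_bias=decoder_bias,
        dispersion=r, dropout=pi, true_type_means=true_type_means,
        heldout_type=heldout_type, heldout_species=heldout_species,
        gene_names=gene_names)


def generate_barnyard(n_cells: int, species=("mouse", "chicken", "opossum"),
                      doublet_rate: float = 0.1, contamination: float = 0.0,
                      mean_reads: int = 1000, seed: int = 0,
                      doublet_fractions=(0.5, 0.5)):
    """Per-cell per-species read counts with injected species doublets.

    Pure cells draw reads from their own species except for a
    `contamination` fraction spread over the others; doublets mix two
    species at `doublet_fractions`. Returns ``(long_table, truth)`` where
    the table has columns cell_id/species/read_count and truth maps cell_id
    to the generating species or "doublet".
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    if not (0 <= contamination < 1):
        raise ValueError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for i in range(n_cells):
        cid = f"cell{i}"
        total = max(1, int(rng.poisson(mean_reads)))
        p = np.zeros(len(species))
        if rng.random() < doublet_rate:
            a, b = rng.choice(len(species), size=2, replace=False)
            p[a], p[b] = doublet_fractions
            truth[cid] = "doublet"
        else:
            own = rng.integers(len(species))
            p[:] = contamination / (len(species) - 1)
            p[own] = 1.0 - contamination
            truth[cid] = species[own]
        reads = rng.multinomial(total, p)
        for s, c in zip(species, reads):
            rows.append({"cell_id": cid, "species": s, "read_count": int(c)})
    return pd.DataFrame(rows), pd.Series(truth, name="truth")


def generate_orthology(n_genes: int = 30,
                       species=("mouse", "opossum", "chicken"),
                       decoy_rate: float = 0.5, missing_rate: float = 0.0,
                       seed: int = 0):
    """Scored many-to-many ortholog edges with a known one-to-one truth.

    True pairs (index-matched genes across species) receive scores in
    (85, 100]; decoy edges between mismatched indices score strictly lower
    (50, 84). With `missing_rate` > 0, true edges between the first and the
    last species are deleted at that rate, leaving gaps that only the
    transitive-triangle step can restore. Returns ``(edges, truth)`` where
    truth is a DataFrame with one column per species.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    names = {s: [f"{s}_g{i}" for i in range(n_genes)] for s in species}
    edges = []
    for ai in range(len(species)):
        for bi in range(ai + 1, len(species)):
            sa, sb = species[ai], species[bi]
            gap_pair = (ai == 0 and bi == len(species) - 1)
            for i in range(n_genes):
                if gap_pair and rng.random() < missing_rate:
                    continue
                edges.append(OrthologEdge(
                    names[sa][i], sa, names[sb][i], sb,
                    float(rng.uniform(85, 100))))
            n_decoys = int(decoy_rate * n_genes)
            for _ in range(n_decoys):
                i, j = rng.integers(n_genes, size=2)
                if i == j:
                    continue
                edges.append(OrthologEdge(
                    names[sa][i], sa, names[sb][j], sb,
                    float(rng.uniform(50, 84))))
    truth = pd.DataFrame({s: names[s] for s in species})
    return edges, truth
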