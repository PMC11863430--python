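"""Reading and writing the standard on-disk formats.

Count matrices travel as Matrix Market triplets (cells x genes) with
companion ``genes.tsv`` and ``cells.tsv`` annotation tables; in memory they
are AnnData objects with species/batch/tissue/donor/cell_type columns in
``.obs``.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

OBS_COLUMNS = ("cell_id", "species", "batch", "tissue", "donor", "cell_type")


def write_dataset(outdir, counts, gene_names, obs: pd.DataFrame) -> None:
    """Write counts + annotations as matrix.mtx / genes.tsv / cells.tsv."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X)
    pd.DataFrame({"gene_id": list(gene_names)}).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    obs.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)


def read_dataset(outdir) -> ad.AnnData:
    """Read a directory written by :func:`write_dataset` into AnnData."""
    X = scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).tocsr()
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t",
                        dtype=str)
    adata = ad.AnnData(X=X, obs=cells.set_index("cell_id", drop=False),
                       var=genes.set_index("gene_id", drop=False))
    adata.obs_names = adata.obs["cell_id"].astype(str)
    return adata


def anndata_from_synthetic(data) -> ad.AnnData:
    """Wrap a ZINBDataset in AnnData with the standard obs columns."""
    obs = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(data.counts.shape[0])],
        "species": data.species,
        "batch": data.batch,
        "tissue": data.tissue,
        "donor": "donor0",
        "cell_type": data.cell_type,
    })
    return ad.AnnData(X=sp.csr_matrix(data.counts),
                      obs=obs.set_index("cell_id", drop=False),
                      var=pd.DataFrame(index=list(data.gene_names)))


def write_fasta(path, sequences: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
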