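"""Reading and writing datasets: AnnData-style HDF5 and MTX+TSV triplets."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_h5ad", "read_h5ad_layers", "write_mtx", "read_mtx"]


def write_h5ad(dataset, path) -> None:
    """Write a :class:`~veloscope.simulate.SimulatedDataset` as .h5ad."""
    dataset.to_anndata().write_h5ad(path)


def read_h5ad_layers(path) -> tuple[np.ndarray, np.ndarray]:
    """Load dense (spliced, unspliced) cell x gene matrices from an .h5ad."""
    import anndata as ad

    adata = ad.read_h5ad(path)
    spliced = np.asarray(
        adata.layers["spliced"].todense()
        if hasattr(adata.layers["spliced"], "todense")
        else adata.layers["spliced"]
    )
    unspliced = np.asarray(
        adata.layers["unspliced"].todense()
        if hasattr(adata.layers["unspliced"], "todense")
        else adata.layers["unspliced"]
    )
    return spliced, unspliced


def write_mtx(dataset, out_dir) -> None:
    """Write spliced/unspliced MTX files plus barcode/gene/metadata TSVs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "spliced.mtx", csr_matrix(dataset.spliced))
    mmwrite(out / "unspliced.mtx", csr_matrix(dataset.unspliced))
    with open(out / "cells.tsv", "w") as fh:
        fh.write("cell\tprocess_time\tfate\n")
        for i in range(dataset.n_cells):
            fh.write(
                f"cell_{i}\t{dataset.cell_times[i]:.8g}\t{dataset.cell_fates[i]}\n"
            )
    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene\n")
        for j in range(dataset.n_genes):
            fh.write(f"gene_{j}\n")


def read_mtx(in_dir) -> tuple[np.ndarray, np.ndarray]:
    """Load dense (spliced, unspliced) matrices from an MTX+TSV directory."""
    from scipy.io import mmread

    in_path = Path(in_dir)
    spliced = np.asarray(mmread(in_path / "spliced.mtx").todense())
    unspliced = np.asarray(mmread(in_path / "unspliced.mtx").todense())
    return spliced, unspliced
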