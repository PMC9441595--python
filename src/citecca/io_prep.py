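"""Reading paired count matrices and preparing encoder inputs.

The count likelihoods are evaluated on the *raw* counts, so preprocessing
keeps three things side by side: the untouched raw matrices, per-cell size
factors (library size over the per-omics median library size), and the
encoder inputs (gene-wise z-scored log1p of size-factor-normalised counts,
optionally restricted to the highest-variance genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

from .sim import LabeledOmicsPair

__all__ = ["PreprocessedPair", "read_pair", "preprocess"]


@dataclass
class PreprocessedPair:
    """Raw counts, encoder inputs and size factors for one paired data set."""

    rna_raw: np.ndarray
    protein_raw: np.ndarray
    rna_input: np.ndarray
    protein_input: np.ndarray
    size_factors_rna: np.ndarray
    size_factors_protein: np.ndarray
    feature_mask_rna: np.ndarray
    cell_ids: list[str]
    labels: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.rna_raw.shape[0]


def _read_mtx_modality(dirpath: Path):
    mtx = dirpath / "matrix.mtx"
    if not mtx.exists():
        mtx = dirpath / "matrix.mtx.gz"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {dirpath}")
    counts = np.asarray(spio.mmread(str(mtx)).todense()).T  # features x cells on disk
    features = pd.read_csv(dirpath / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(dirpath / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return counts, features, barcodes


def _read_labels(path: Path, cell_ids: list[str]):
    if not path.exists():
        return None
    df = pd.read_csv(path).set_index("cell_id")
    return df.loc[cell_ids, "cluster"].to_numpy()


def read_pair(path, format: str = "mtx") -> LabeledOmicsPair:
    """Load a paired data set written by :func:`citecca.sim.write_pair`.

    Cells are aligned to the intersection of the two barcode lists and sorted
    by barcode string, so the output order is deterministic regardless of the
    on-disk order.  Raises if the two modalities share no cells.
    """
    path = Path(path)
    if format in ("mtx", "mtx-dir"):
        rna, gene_ids, bc_rna = _read_mtx_modality(path / "rna")
        prot, protein_ids, bc_prot = _read_mtx_modality(path / "protein")
        rna_df = pd.DataFrame(rna, index=bc_rna)
        prot_df = pd.DataFrame(prot, index=bc_prot)
        labels_path = path / "labels.csv"
    elif format == "csv":
        rna_df = pd.read_csv(path / "rna.csv", index_col=0)
        prot_df = pd.read_csv(path / "protein.csv", index_col=0)
        gene_ids = rna_df.columns.tolist()
        protein_ids = prot_df.columns.tolist()
        labels_path = path / "labels.csv"
    elif format in ("h5", "hdf5-container", "h5ad"):
        import anndata as ad

        if path.suffix != ".h5ad" and not path.exists():
            path = path.with_suffix(".h5ad")
        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        labels = (adata.obs["cluster"].cat.codes.to_numpy()
                  if "cluster" in adata.obs else None)
        order = np.argsort(np.asarray(adata.obs_names, dtype=object))
        return LabeledOmicsPair(
            rna_counts=np.asarray(X, dtype=np.int64)[order],
            protein_counts=np.asarray(adata.obsm["protein"], dtype=np.int64)[order],
            labels=None if labels is None else labels[order].astype(np.int64),
            cell_ids=[adata.obs_names[i] for i in order],
            gene_ids=adata.var_names.tolist(),
            protein_ids=list(adata.uns.get("protein_ids",
                                           [f"adt_{j}" for j in range(adata.obsm["protein"].shape[1])])),
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    shared = sorted(set(rna_df.index) & set(prot_df.index))
    if not shared:
        raise ValueError("no shared cells between RNA and protein matrices")
    dropped = (len(rna_df) - len(shared)) + (len(prot_df) - len(shared))
    if dropped:
        warnings.warn(f"{dropped} cells present in only one modality were dropped")
    rna_df = rna_df.loc[shared]
    prot_df = prot_df.loc[shared]

    labels = _read_labels(labels_path, shared)
    return LabeledOmicsPair(
        rna_counts=rna_df.to_numpy(dtype=np.int64),
        protein_counts=prot_df.to_numpy(dtype=np.int64),
        labels=None if labels is None else np.asarray(labels, dtype=np.int64),
        cell_ids=list(shared),
        gene_ids=list(gene_ids),
        protein_ids=list(protein_ids),
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=1).astype(float)
    return lib / np.median(lib)


def _encoder_input(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    x = np.log1p(counts / size_factors[:, None])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd < 1e-8] = 1.0  # constant features carry no signal; leave them at 0
    return (x - mu) / sd


def preprocess(pair: LabeledOmicsPair, n_top_genes: int | None = None) -> PreprocessedPair:
    """Build encoder inputs and size factors; raw counts pass through untouched.

    Cells with a zero total count in either omics are dropped with a warning
    (their size factor would be zero and the likelihood undefined).  When
    ``n_top_genes`` is given, the RNA encoder input *and* the raw matrix used
    by the RNA likelihood are restricted to the highest-variance genes of the
    log-normalised data; the protein panel is never subset.
    """
    if np.any(pair.rna_counts < 0) or np.any(pair.protein_counts < 0):
        raise ValueError("counts must be non-negative")
    keep = (pair.rna_counts.sum(axis=1) > 0) & (pair.protein_counts.sum(axis=1) > 0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} cells with zero counts in one omics")
    rna = pair.rna_counts[keep]
    prot = pair.protein_counts[keep]
    cell_ids = [c for c, k in zip(pair.cell_ids, keep) if k]
    labels = pair.labels[keep] if pair.labels is not None else None

    sf_rna = _size_factors(rna)
    sf_prot = _size_factors(prot)

    logn = np.log1p(rna / sf_rna[:, None])
    mask = np.ones(rna.shape[1], dtype=bool)
    if n_top_genes is not None and n_top_genes < rna.shape[1]:
        var = logn.var(axis=0)
        top = np.sort(np.argsort(var)[::-1][:n_top_genes])
        mask = np.zeros(rna.shape[1], dtype=bool)
        mask[top] = True
        rna = rna[:, mask]

    return PreprocessedPair(
        rna_raw=rna,
        protein_raw=prot,
        rna_input=_encoder_input(rna, sf_rna),
        protein_input=_encoder_input(prot, sf_prot),
        size_factors_rna=sf_rna,
        size_factors_protein=sf_prot,
        feature_mask_rna=mask,
        cell_ids=cell_ids,
        labels=labels,
    )
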