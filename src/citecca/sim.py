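"""Synthetic CITE-seq count data with known cluster labels.

The generator emulates the Splatter gamma-Poisson simulation family for paired
RNA / surface-protein (ADT) counts: gamma-distributed base expression means,
per-cluster multiplicative differential-expression (DE) factors drawn for a
random subset of features, log-normal per-cell library sizes, negative-binomial
sampling, and — for the RNA modality only — an extra logistic-in-log-mean
dropout step producing zero inflation.  Proteins are denser and less
overdispersed, so they get a larger library scale and no dropout.

Default design: equal-size clusters, 2500 genes, 75 proteins, DE probability
0.15 for RNA and 0.7 for protein — a regime where the protein panel is the
more informative modality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["SimConfig", "LabeledOmicsPair", "simulate_cite", "write_pair"]


@dataclass(frozen=True)
class SimConfig:
    """Generative design for one simulated CITE-seq data set.

    ``de_prob_*`` is the probability that a feature is differentially
    expressed in a given cluster (independently per cluster and per omics).
    DE features receive a multiplicative log-normal factor, up- or
    down-regulated with equal probability.  ``dispersion_*`` is the NB size
    parameter theta (larger = closer to Poisson).
    """

    n_clusters: int = 8
    cells_per_cluster: int = 500
    n_genes: int = 2500
    n_proteins: int = 75
    de_prob_rna: float = 0.15
    de_prob_protein: float = 0.7
    de_factor_location: float = 0.5
    de_factor_scale: float = 0.4
    library_size_location_rna: float = 9.0
    library_size_scale_rna: float = 0.25
    library_size_location_protein: float = 8.0
    library_size_scale_protein: float = 0.2
    rna_dropout_midpoint: float = 0.5
    rna_dropout_shape: float = 1.0
    dispersion_rna: float = 2.0
    dispersion_protein: float = 4.0
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        for name in ("cells_per_cluster", "n_genes", "n_proteins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("de_prob_rna", "de_prob_protein"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("dispersion_rna", "dispersion_protein", "mean_shape", "mean_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.proportions is not None:
            pr = np.asarray(self.proportions, dtype=float)
            if len(pr) != self.n_clusters or np.any(pr < 0) or not np.isclose(pr.sum(), 1.0):
                raise ValueError("proportions must be length n_clusters, non-negative, sum to 1")

    @property
    def n_cells(self) -> int:
        return self.n_clusters * self.cells_per_cluster

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabeledOmicsPair:
    """Paired raw RNA and protein count matrices over the same cells."""

    rna_counts: np.ndarray  # (n_cells, n_genes), non-negative ints
    protein_counts: np.ndarray  # (n_cells, n_proteins)
    labels: np.ndarray | None  # (n_cells,) ints in {0..K-1}, or None
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rna_counts.shape[0] != self.protein_counts.shape[0]:
            raise ValueError("RNA and protein matrices must have the same number of cells")
        if self.labels is not None and len(self.labels) != self.rna_counts.shape[0]:
            raise ValueError("labels length must equal number of cells")

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]


def _cluster_profiles(base_mean, n_clusters, de_prob, loc, scale, rng):
    """Per-cluster expected-expression profiles with multiplicative DE factors."""
    n_feat = base_mean.shape[0]
    profiles = np.tile(base_mean, (n_clusters, 1))
    for k in range(n_clusters):
        is_de = rng.random(n_feat) < de_prob
        n_de = int(is_de.sum())
        if n_de == 0:
            continue
        factors = rng.lognormal(mean=loc, sigma=scale, size=n_de)
        down = rng.random(n_de) < 0.5
        factors[down] = 1.0 / factors[down]
        profiles[k, is_de] *= factors
    return profiles


def _nb_counts(mean, theta, rng):
    """Gamma-Poisson (negative binomial) sampling with dispersion theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def simulate_cite(config: SimConfig) -> LabeledOmicsPair:
    """Draw one labeled synthetic CITE-seq data set.

    Deterministic given ``config`` (including its seed): identical configs
    produce bit-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_clusters
    if config.proportions is None:
        sizes = np.full(K, config.cells_per_cluster)
    else:
        sizes = np.round(np.asarray(config.proportions) * config.n_cells).astype(int)
        sizes[-1] = config.n_cells - sizes[:-1].sum()
    labels = np.repeat(np.arange(K), sizes)
    n = int(sizes.sum())

    base_rna = rng.gamma(shape=config.mean_shape, scale=1.0 / config.mean_rate,
                         size=config.n_genes)
    base_prot = rng.gamma(shape=config.mean_shape, scale=1.0 / config.mean_rate,
                          size=config.n_proteins)
    prof_rna = _cluster_profiles(base_rna, K, config.de_prob_rna,
                                 config.de_factor_location, config.de_factor_scale, rng)
    prof_prot = _cluster_profiles(base_prot, K, config.de_prob_protein,
                                  config.de_factor_location, config.de_factor_scale, rng)
    # profiles -> proportions, scaled by per-cell library size
    prof_rna /= prof_rna.sum(axis=1, keepdims=True)
    prof_prot /= prof_prot.sum(axis=1, keepdims=True)

    lib_rna = rng.lognormal(config.library_size_location_rna,
                            config.library_size_scale_rna, size=n)
    lib_prot = rng.lognormal(config.library_size_location_protein,
                             config.library_size_scale_protein, size=n)

    mu_rna = prof_rna[labels] * lib_rna[:, None]
    mu_prot = prof_prot[labels] * lib_prot[:, None]

    rna = _nb_counts(mu_rna, config.dispersion_rna, rng)
    # logistic dropout: low-mean genes are zeroed more often (technical zeros)
    if config.rna_dropout_shape > 0:
        logit = -config.rna_dropout_shape * (
            np.log(np.maximum(mu_rna, 1e-12)) - config.rna_dropout_midpoint
        )
        p_drop = 1.0 / (1.0 + np.exp(-logit))
        rna = np.where(rng.random(rna.shape) < p_drop, 0, rna)
    prot = _nb_counts(mu_prot, config.dispersion_protein, rng)

    width = len(str(n - 1))
    return LabeledOmicsPair(
        rna_counts=rna.astype(np.int64),
        protein_counts=prot.astype(np.int64),
        labels=labels.astype(np.int64),
        cell_ids=[f"cell_{i:0{width}d}" for i in range(n)],
        gene_ids=[f"gene_{j}" for j in range(config.n_genes)],
        protein_ids=[f"adt_{j}" for j in range(config.n_proteins)],
    )


def _write_mtx_modality(dirpath: Path, counts, feature_ids, cell_ids) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    # 10x convention: features x cells, coordinate MatrixMarket
    spio.mmwrite(str(dirpath / "matrix.mtx"), sparse.coo_matrix(counts.T))
    pd.Series(feature_ids).to_csv(dirpath / "features.tsv", sep="\t",
                                  index=False, header=False)
    pd.Series(cell_ids).to_csv(dirpath / "barcodes.tsv", sep="\t",
                               index=False, header=False)


def write_pair(pair: LabeledOmicsPair, path, format: str = "mtx") -> Path:
    """Write a pair to disk in ``mtx`` (10x-style dirs), ``csv`` or ``h5`` form.

    Round-trips losslessly through :func:`citecca.io_prep.read_pair`.
    """
    if pair.protein_counts.shape[1] == 0 or pair.rna_counts.shape[1] == 0:
        raise ValueError("cannot write a pair with an empty modality")
    path = Path(path)
    if format in ("mtx", "mtx-dir"):
        path.mkdir(parents=True, exist_ok=True)
        _write_mtx_modality(path / "rna", pair.rna_counts, pair.gene_ids, pair.cell_ids)
        _write_mtx_modality(path / "protein", pair.protein_counts,
                            pair.protein_ids, pair.cell_ids)
        if pair.labels is not None:
            pd.DataFrame({"cell_id": pair.cell_ids, "cluster": pair.labels}).to_csv(
                path / "labels.csv", index=False)
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(pair.rna_counts, index=pair.cell_ids,
                     columns=pair.gene_ids).to_csv(path / "rna.csv")
        pd.DataFrame(pair.protein_counts, index=pair.cell_ids,
                     columns=pair.protein_ids).to_csv(path / "protein.csv")
        if pair.labels is not None:
            pd.DataFrame({"cell_id": pair.cell_ids, "cluster": pair.labels}).to_csv(
                path / "labels.csv", index=False)
    elif format in ("h5", "hdf5-container", "h5ad"):
        import anndata as ad

        path.parent.mkdir(parents=True, exist_ok=True)
        adata = ad.AnnData(
            X=sparse.csr_matrix(pair.rna_counts),
            obs=pd.DataFrame(index=pair.cell_ids),
            var=pd.DataFrame(index=pair.gene_ids),
        )
        adata.obsm["protein"] = pair.protein_counts
        adata.uns["protein_ids"] = list(pair.protein_ids)
        if pair.labels is not None:
            adata.obs["cluster"] = pd.Categorical(pair.labels)
        if path.suffix != ".h5ad":
            path = path.with_suffix(".h5ad")
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}; use mtx, csv or h5")
    return path


def write_config(config: SimConfig, path) -> None:
    """Record the resolved generative design next to its outputs (provenance)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
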