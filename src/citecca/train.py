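"""Optimisation pipeline.

Three stages:

1. **Autoencoder pretraining** — encoders/decoders minimise the count
   negative log-likelihoods alone, giving each omics a latent that explains
   its counts.  The clustering head is untouched.
2. **Head warm-up with restarts** — the encoders are frozen and several
   random re-initialisations of the clustering head (plus fusion logits) are
   each trained briefly on the Cauchy-Schwarz clustering terms; the restart
   with the lowest full-data clustering loss wins.  Divergence-based
   clustering has no centroid initialisation to anchor it, so restart
   selection by the training objective is the standard defence against
   merged-cluster local optima.
3. **Joint training** — the full objective

       gamma * L_AE  -  delta * L_cca  +  (L1 + L2 + L3)

   is minimised per minibatch with Adam over all parameters; the fusion
   logits ride the same gradients, so the modality weights adapt to however
   much each omics contributes to the clustering terms.  The correlation
   weight delta ramps in linearly so the CCA term never acts on unsettled
   latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from . import losses
from .io_prep import PreprocessedPair
from .model import CiteModel, ModelConfig, LatentState, ZinbParams

__all__ = ["TrainConfig", "FitResult", "build_model", "pretrain", "fit", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    n_clusters: int = 8
    gamma: float = 1.0
    delta: float = 0.1
    sigma_rel: float = 0.15
    r1: float = 1e-3
    r2: float = 1e-3
    cca_top_k: int | None = None
    pretrain_epochs: int = 120
    train_epochs: int = 60
    head_warmup_epochs: int = 40
    head_restarts: int = 4
    head_polish_epochs: int = 40
    warmup_epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    latent_dim: int = 16
    protein_likelihood: str = "nb"
    kernel_on: str = "hidden"
    l3_normalize: bool = True

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.pretrain_epochs < 0 or self.train_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (CCA and kernel need pairs)")


@dataclass
class FitResult:
    hard_labels: np.ndarray
    soft_assignments: np.ndarray
    latents: LatentState
    fusion_weight_history: list[tuple[float, float]] = field(default_factory=list)
    loss_history: list[losses.LossBreakdown] = field(default_factory=list)


def build_model(data: PreprocessedPair, config: TrainConfig) -> CiteModel:
    mcfg = ModelConfig(
        n_genes=data.rna_input.shape[1],
        n_proteins=data.protein_input.shape[1],
        n_clusters=config.n_clusters,
        latent_dim=config.latent_dim,
        protein_likelihood=config.protein_likelihood,
        kernel_on=config.kernel_on,
    )
    return CiteModel(mcfg, seed=config.seed)


def _batches(n: int, batch_size: int, rng: np.random.Generator, min_size: int):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        batch = idx[start:start + batch_size]
        if len(batch) >= min_size:
            yield batch


def _nll(x_raw, params) -> Tensor:
    if isinstance(params, ZinbParams):
        return losses.zinb_nll(x_raw, params.mu, params.theta, params.pi)
    return losses.nb_nll(x_raw, params.mu, params.theta)


def _ae_loss(model: CiteModel, data: PreprocessedPair, batch) -> Tensor:
    z_r, z_p, _ = model.encode(data.rna_input[batch], data.protein_input[batch])
    rna_params = model.decode_rna(z_r, data.size_factors_rna[batch])
    prot_params = model.decode_protein(z_p, data.size_factors_protein[batch])
    return (_nll(data.rna_raw[batch], rna_params)
            + _nll(data.protein_raw[batch], prot_params))


def pretrain(model: CiteModel, data: PreprocessedPair, config: TrainConfig,
             log=None) -> list[float]:
    """Optimise encoders/decoders on L_AE alone; returns per-epoch means."""
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.autoencoder_params, lr=config.learning_rate)
    history: list[float] = []
    for epoch in range(config.pretrain_epochs):
        epoch_vals = []
        for batch in _batches(data.n_cells, config.batch_size, rng, min_size=2):
            opt.zero_grad()
            loss = _ae_loss(model, data, batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite autoencoder loss; aborting")
            loss.backward()
            opt.step()
            epoch_vals.append(float(loss.data))
        history.append(float(np.mean(epoch_vals)) if epoch_vals else np.nan)
        if log is not None:
            log({"phase": "pretrain", "epoch": epoch, "l_ae": history[-1]})
    return history


def _cluster_terms(model: CiteModel, z: Tensor, config: TrainConfig):
    head = model.cluster_assign(z)
    kernel = losses.gaussian_kernel(head.hidden_features,
                                    sigma_rel=config.sigma_rel)
    l1 = losses.l1_separability(head.assignments, kernel)
    l2 = losses.l2_simplex(head.assignments, kernel)
    l3 = losses.l3_orthogonality(head.assignments, normalize=config.l3_normalize)
    return l1, l2, l3


def _encode_all(model: CiteModel, data: PreprocessedPair, batch_size: int = 2048):
    zs, zp = [], []
    for start in range(0, data.n_cells, batch_size):
        sl = slice(start, start + batch_size)
        z_r, z_p, _ = model.encode(data.rna_input[sl], data.protein_input[sl])
        zs.append(z_r.data)
        zp.append(z_p.data)
    return np.vstack(zs), np.vstack(zp)


def _full_cluster_loss(model: CiteModel, z_r_all, z_p_all,
                       config: TrainConfig, max_cells: int = 2000) -> float:
    """Restart-selection score: L1+L2+L3 over (a capped sample of) all cells."""
    n = len(z_r_all)
    if n > max_cells:
        sel = np.random.default_rng(config.seed + 9).choice(n, max_cells,
                                                            replace=False)
        z_r_all, z_p_all = z_r_all[sel], z_p_all[sel]
    w = model.fusion_weights()
    z = Tensor(z_r_all) * w[0] + Tensor(z_p_all) * w[1]
    l1, l2, l3 = _cluster_terms(model, z, config)
    return float(l1.data + l2.data + l3.data)


def _mean_breakdown(rows, gamma, delta) -> losses.LossBreakdown:
    if not rows:  # pragma: no cover - only for degenerate tiny data sets
        return losses.LossBreakdown(np.nan, np.nan, np.nan, np.nan, np.nan,
                                    np.nan, gamma, delta)
    return losses.LossBreakdown(**{
        k: float(np.mean([getattr(r, k) for r in rows]))
        for k in ("l_ae", "l_cca", "l1", "l2", "l3", "total", "gamma", "delta")
    })


def _assign_all(model: CiteModel, data: PreprocessedPair,
                batch_size: int = 2048) -> np.ndarray:
    was_training = model.training
    model.train_mode(False)
    try:
        out = []
        for start in range(0, data.n_cells, batch_size):
            sl = slice(start, start + batch_size)
            _, _, z = model.encode(data.rna_input[sl], data.protein_input[sl])
            out.append(model.cluster_assign(z).assignments.data)
        return np.vstack(out)
    finally:
        model.train_mode(was_training)


def _run_head_epochs(model: CiteModel, z_r_all, z_p_all, config: TrainConfig,
                     n_epochs: int, min_batch: int, opt: Adam,
                     rng: np.random.Generator):
    """Train head + fusion logits on the clustering terms over frozen latents."""
    hist_w, hist_l = [], []
    n = len(z_r_all)
    for _epoch in range(n_epochs):
        rows = []
        for batch in _batches(n, config.batch_size, rng, min_batch):
            opt.zero_grad()
            w = model.fusion_weights()
            z = Tensor(z_r_all[batch]) * w[0] + Tensor(z_p_all[batch]) * w[1]
            l1, l2, l3 = _cluster_terms(model, z, config)
            zero = Tensor(np.array(0.0))
            total, breakdown = losses.total_loss(zero, zero, l1, l2, l3,
                                                 gamma=0.0, delta=0.0)
            if not np.isfinite(total.data):
                raise FloatingPointError("non-finite training loss; aborting")
            total.backward()
            opt.step()
            rows.append(breakdown)
        wv = model.fusion_weights().data
        hist_w.append((float(wv[0]), float(wv[1])))
        hist_l.append(_mean_breakdown(rows, 0.0, 0.0))
    return hist_w, hist_l


def _head_warmup(model: CiteModel, data: PreprocessedPair, config: TrainConfig,
                 min_batch: int, log=None):
    """Stage 2: restart the head several times over the frozen pretrained
    latents, keep the restart with the lowest full-data clustering loss, then
    polish the winner head-only.  The warm-up uses a raised learning rate
    (3x) — only the small head moves, so larger steps are safe and make the
    restart scores informative quickly.  Returns history rows."""
    z_r_all, z_p_all = _encode_all(model, data)
    lr = 3.0 * config.learning_rate
    best = None
    for restart in range(max(1, config.head_restarts)):
        model.reinit_head(config.seed + 101 * (restart + 1))
        opt = Adam(model.cluster_params, lr=lr)
        rng = np.random.default_rng(config.seed + 7 * (restart + 1))
        hist_w, hist_l = _run_head_epochs(model, z_r_all, z_p_all, config,
                                          config.head_warmup_epochs,
                                          min_batch, opt, rng)
        score = _full_cluster_loss(model, z_r_all, z_p_all, config)
        if log is not None:
            log({"phase": "head_warmup", "restart": restart,
                 "cluster_loss": score})
        if best is None or score < best[0]:
            best = (score, model.head_state(), opt.state_dict(),
                    hist_w, hist_l, restart)
    score, state, opt_state, hist_w, hist_l, restart = best
    model.load_head_state(state)
    if config.head_polish_epochs > 0:
        opt = Adam(model.cluster_params, lr=lr)
        opt.load_state_dict(opt_state)
        rng = np.random.default_rng(config.seed + 13)
        pw, pl = _run_head_epochs(model, z_r_all, z_p_all, config,
                                  config.head_polish_epochs,
                                  min_batch, opt, rng)
        hist_w, hist_l = hist_w + pw, hist_l + pl
        if log is not None:
            log({"phase": "head_polish", "restart": restart,
                 "cluster_loss": _full_cluster_loss(model, z_r_all, z_p_all,
                                                    config)})
    return hist_w, hist_l


def fit(data: PreprocessedPair, config: TrainConfig,
        model: CiteModel | None = None, do_pretrain: bool = True,
        log=None) -> tuple[FitResult, CiteModel]:
    """Full pipeline: pretraining, head warm-up with restarts, joint phase.

    Returns the fit result and the trained model.  Deterministic under a
    fixed seed and thread count.
    """
    if config.n_clusters > data.n_cells:
        raise ValueError("more clusters than cells")
    if model is None:
        model = build_model(data, config)
    if do_pretrain:
        pretrain(model, data, config, log=log)

    # covariance estimates need clearly more cells than latent dimensions
    min_batch = min(max(2 * config.latent_dim, 2), data.n_cells)
    weight_history: list[tuple[float, float]] = []
    loss_history: list[losses.LossBreakdown] = []

    if config.train_epochs > 0 and config.head_warmup_epochs > 0:
        hist_w, hist_l = _head_warmup(model, data, config, min_batch, log=log)
        weight_history.extend(hist_w)
        loss_history.extend(hist_l)

    rng = np.random.default_rng(config.seed + 2)
    opt = Adam(model.params, lr=config.learning_rate)
    for epoch in range(config.train_epochs):
        if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
            delta_t = config.delta * epoch / config.warmup_epochs
        else:
            delta_t = config.delta
        rows = []
        for batch in _batches(data.n_cells, config.batch_size, rng, min_batch):
            opt.zero_grad()
            z_r, z_p, z = model.encode(data.rna_input[batch],
                                       data.protein_input[batch])
            rna_params = model.decode_rna(z_r, data.size_factors_rna[batch])
            prot_params = model.decode_protein(z_p,
                                               data.size_factors_protein[batch])
            l_ae = (_nll(data.rna_raw[batch], rna_params)
                    + _nll(data.protein_raw[batch], prot_params))
            l_cca = losses.cca_loss(z_r.T, z_p.T, r1=config.r1, r2=config.r2,
                                    top_k=config.cca_top_k)
            l1, l2, l3 = _cluster_terms(model, z, config)
            total, breakdown = losses.total_loss(l_ae, l_cca, l1, l2, l3,
                                                 gamma=config.gamma,
                                                 delta=delta_t)
            if not np.isfinite(total.data):
                raise FloatingPointError("non-finite training loss; aborting")
            total.backward()
            opt.step()
            rows.append(breakdown)
        w = model.fusion_weights().data
        weight_history.append((float(w[0]), float(w[1])))
        loss_history.append(_mean_breakdown(rows, config.gamma, delta_t))
        if log is not None:
            log({"phase": "train", "epoch": epoch,
                 "w_rna": weight_history[-1][0],
                 "w_protein": weight_history[-1][1],
                 **loss_history[-1].as_row()})

    soft = _assign_all(model, data)
    latents = model.latent_state(data.rna_input, data.protein_input)
    return FitResult(
        hard_labels=soft.argmax(axis=1),
        soft_assignments=soft,
        latents=latents,
        fusion_weight_history=weight_history,
        loss_history=loss_history,
    ), model


def predict(model: CiteModel, data: PreprocessedPair) -> FitResult:
    """Deterministic assignments for (new) cells; no optimisation."""
    if data.rna_input.shape[1] != model.config.n_genes:
        raise ValueError(
            f"gene count mismatch: model expects {model.config.n_genes}, "
            f"data has {data.rna_input.shape[1]}")
    if data.protein_input.shape[1] != model.config.n_proteins:
        raise ValueError("protein count mismatch between model and data")
    soft = _assign_all(model, data)
    return FitResult(
        hard_labels=soft.argmax(axis=1),
        soft_assignments=soft,
        latents=model.latent_state(data.rna_input, data.protein_input),
    )
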