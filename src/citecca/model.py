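"""The multimodal clustering network.

Two omics-specific MLP encoders map RNA and protein inputs to latents of a
shared dimension d.  Each latent feeds a mirrored decoder ending in parallel
likelihood heads: mean (exponential activation, scaled by the cell's size
factor), dispersion (softplus), and — for zero-inflated branches — a sigmoid
dropout head.  A learnable two-logit softmax produces the fusion weights
(w_rna, w_protein) combining the latents; the fused latent feeds a small
clustering head whose hidden activations are the features the Gaussian
kernel sees and whose softmax output is the soft assignment matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Parameter, Tensor

__all__ = ["ModelConfig", "CiteModel", "LatentState", "ZinbParams", "NbParams",
           "ClusterHead"]

MEAN_CLAMP = (1e-5, 1e6)
DISP_CLAMP = (1e-4, 1e4)

# single precision keeps the matmul-heavy forward/backward passes fast on CPU;
# the count likelihoods upcast to float64 where raw counts enter
DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    n_genes: int
    n_proteins: int
    n_clusters: int
    latent_dim: int = 16
    rna_hidden: tuple[int, ...] = (256, 64)
    protein_hidden: tuple[int, ...] = (64, 32)
    cluster_hidden: int = 100
    cluster_batchnorm: bool = True
    kernel_on: str = "hidden"  # "hidden" | "fused"
    rna_likelihood: str = "zinb"
    protein_likelihood: str = "nb"  # "nb" | "zinb" (dual-ZINB mode)

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.kernel_on not in ("hidden", "fused"):
            raise ValueError("kernel_on must be 'hidden' or 'fused'")
        if self.protein_likelihood not in ("nb", "zinb"):
            raise ValueError("protein_likelihood must be 'nb' or 'zinb'")


@dataclass
class LatentState:
    """Per-cell latents and the fusion weights that combined them."""

    z_rna: np.ndarray
    z_protein: np.ndarray
    z_fused: np.ndarray
    w_rna: float
    w_protein: float


@dataclass
class ZinbParams:
    mu: Tensor
    theta: Tensor
    pi: Tensor


@dataclass
class NbParams:
    mu: Tensor
    theta: Tensor


@dataclass
class ClusterHead:
    hidden_features: Tensor  # n x h, input to the Gaussian kernel
    assignments: Tensor  # n x K row-stochastic


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    """Feature-wise standardisation with running statistics (no affine).

    Batch statistics are used (and backpropagated through) during training;
    inference uses the running averages so predictions are independent of
    batch composition.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * x.data.mean(axis=0)
            self.running_var = (1 - m) * self.running_var + m * x.data.var(axis=0)
            return (x - mu) / (var + self.eps).sqrt()
        return (x - Tensor(self.running_mean[None, :])) / Tensor(
            np.sqrt(self.running_var[None, :] + self.eps))


class _MLP:
    """Stack of Linear+ELU layers."""

    def __init__(self, sizes, rng):
        self.layers = [_Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).elu()
        return x

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]


class _Decoder:
    """Mirrored decoder with parallel likelihood heads."""

    def __init__(self, latent_dim, hidden, n_out, zero_inflated, rng):
        self.body = _MLP((latent_dim, *hidden), rng)
        width = hidden[-1] if hidden else latent_dim
        self.mean_head = _Linear(width, n_out, rng)
        self.disp_head = _Linear(width, n_out, rng)
        self.pi_head = _Linear(width, n_out, rng) if zero_inflated else None

    def __call__(self, z: Tensor, size_factors: np.ndarray):
        h = self.body(z)
        log_mu = self.mean_head(h).clip(np.log(MEAN_CLAMP[0]), np.log(MEAN_CLAMP[1]))
        mu = log_mu.exp() * Tensor(np.asarray(size_factors, dtype=DTYPE)[:, None])
        theta = self.disp_head(h).softplus().clip(*DISP_CLAMP)
        if self.pi_head is None:
            return NbParams(mu=mu, theta=theta)
        pi = self.pi_head(h).sigmoid().clip(1e-6, 1.0 - 1e-6)
        return ZinbParams(mu=mu, theta=theta, pi=pi)

    @property
    def params(self):
        ps = self.body.params + self.mean_head.params + self.disp_head.params
        if self.pi_head is not None:
            ps += self.pi_head.params
        return ps


class CiteModel:
    """Encoders, decoders, fusion layer and clustering head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d = config.latent_dim
        self.enc_rna = _MLP((config.n_genes, *config.rna_hidden, d), rng)
        self.enc_protein = _MLP((config.n_proteins, *config.protein_hidden, d), rng)
        self.dec_rna = _Decoder(d, tuple(reversed(config.rna_hidden)),
                                config.n_genes,
                                config.rna_likelihood == "zinb", rng)
        self.dec_protein = _Decoder(d, tuple(reversed(config.protein_hidden)),
                                    config.n_proteins,
                                    config.protein_likelihood == "zinb", rng)
        self.fusion_logits = Parameter(np.zeros(2))  # softmax -> (w_rna, w_prot)
        self.head_hidden = _Linear(d, config.cluster_hidden, rng)
        self.head_norm = (_BatchNorm(config.cluster_hidden)
                          if config.cluster_batchnorm else None)
        self.head_out = _Linear(config.cluster_hidden, config.n_clusters, rng)
        self.training = True

    def train_mode(self, training: bool = True) -> None:
        self.training = training
        if self.head_norm is not None:
            self.head_norm.training = training

    def reinit_head(self, seed: int) -> None:
        """Re-draw the clustering head and fusion logits (restart support)."""
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.head_hidden = _Linear(cfg.latent_dim, cfg.cluster_hidden, rng)
        self.head_norm = (_BatchNorm(cfg.cluster_hidden)
                          if cfg.cluster_batchnorm else None)
        self.head_out = _Linear(cfg.cluster_hidden, cfg.n_clusters, rng)
        self.fusion_logits = Parameter(np.zeros(2))
        self.train_mode(self.training)

    def head_state(self) -> dict:
        state = {
            "hidden_w": self.head_hidden.w.data.copy(),
            "hidden_b": self.head_hidden.b.data.copy(),
            "out_w": self.head_out.w.data.copy(),
            "out_b": self.head_out.b.data.copy(),
            "fusion": self.fusion_logits.data.copy(),
        }
        if self.head_norm is not None:
            state["bn_mean"] = self.head_norm.running_mean.copy()
            state["bn_var"] = self.head_norm.running_var.copy()
        return state

    def load_head_state(self, state: dict) -> None:
        self.head_hidden.w.data = state["hidden_w"].copy()
        self.head_hidden.b.data = state["hidden_b"].copy()
        self.head_out.w.data = state["out_w"].copy()
        self.head_out.b.data = state["out_b"].copy()
        self.fusion_logits.data = state["fusion"].copy()
        if self.head_norm is not None and "bn_mean" in state:
            self.head_norm.running_mean = state["bn_mean"].copy()
            self.head_norm.running_var = state["bn_var"].copy()

    # -- parameter groups -------------------------------------------------
    @property
    def autoencoder_params(self):
        return (self.enc_rna.params + self.enc_protein.params
                + self.dec_rna.params + self.dec_protein.params)

    @property
    def cluster_params(self):
        return [self.fusion_logits] + self.head_hidden.params + self.head_out.params

    @property
    def params(self):
        return self.autoencoder_params + self.cluster_params

    # -- forward pieces ----------------------------------------------------
    def fusion_weights(self) -> Tensor:
        return self.fusion_logits.softmax()

    def encode(self, rna_input, protein_input) -> tuple[Tensor, Tensor, Tensor]:
        """Latents (z_rna, z_protein, z_fused); fused uses current weights."""
        z_r = self.enc_rna(Tensor(np.asarray(rna_input, dtype=DTYPE)))
        z_p = self.enc_protein(Tensor(np.asarray(protein_input, dtype=DTYPE)))
        if z_r.shape[1] != z_p.shape[1]:
            raise ValueError("latent dimensions of the two omics must match")
        w = self.fusion_weights()
        z = z_r * w[0] + z_p * w[1]
        return z_r, z_p, z

    def decode_rna(self, z_rna: Tensor, size_factors):
        return self.dec_rna(z_rna, size_factors)

    def decode_protein(self, z_protein: Tensor, size_factors):
        return self.dec_protein(z_protein, size_factors)

    def cluster_assign(self, z_fused: Tensor) -> ClusterHead:
        hidden = self.head_hidden(z_fused)
        if self.head_norm is not None:
            hidden = self.head_norm(hidden)
        hidden = hidden.clip(lo=0.0)  # ReLU
        logits = self.head_out(hidden)
        assignments = logits.softmax(axis=1)
        kernel_feats = hidden if self.config.kernel_on == "hidden" else z_fused
        return ClusterHead(hidden_features=kernel_feats, assignments=assignments)

    def latent_state(self, rna_input, protein_input) -> LatentState:
        z_r, z_p, z = self.encode(rna_input, protein_input)
        w = self.fusion_weights().data
        return LatentState(z_rna=z_r.data, z_protein=z_p.data, z_fused=z.data,
                           w_rna=float(w[0]), w_protein=float(w[1]))

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params)}

    def save(self, path, rng_state: dict | None = None) -> None:
        """Single-file checkpoint: weights + config + optional RNG state."""
        path = Path(path)
        payload = dict(self.state_arrays())
        if self.head_norm is not None:
            payload["_bn_mean"] = self.head_norm.running_mean
            payload["_bn_var"] = self.head_norm.running_var
        payload["_config"] = np.array(json.dumps(asdict(self.config)))
        payload["_seed"] = np.array(self.seed)
        if rng_state is not None:
            payload["_rng"] = np.array(json.dumps(rng_state, default=int))
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "CiteModel":
        path = Path(path)
        if path.suffix != ".npz" and not path.exists():
            path = path.with_suffix(".npz")
        with np.load(path, allow_pickle=False) as archive:
            cfg_dict = json.loads(str(archive["_config"]))
            for key in ("rna_hidden", "protein_hidden"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict), seed=int(archive["_seed"]))
            for i, p in enumerate(model.params):
                p.data = archive[f"p{i}"].copy()
            if model.head_norm is not None and "_bn_mean" in archive:
                model.head_norm.running_mean = archive["_bn_mean"].copy()
                model.head_norm.running_var = archive["_bn_var"].copy()
        return model
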