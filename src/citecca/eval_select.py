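"""Clustering evaluation and cluster-number selection.

ARI and NMI wrap scikit-learn's implementations.  ``select_k`` follows the
pretraining-based elbow recipe: train the autoencoders alone, take the fused
latent, run k-means over a range of K keeping the best of several restarts,
and pick the K at the sharpest bend (largest second-order forward difference)
of the SSE-versus-K curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io_prep import PreprocessedPair
from .train import TrainConfig, build_model, pretrain

__all__ = ["ari", "nmi", "KSelectionResult", "select_k"]


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index in [-1, 1]; 1 = identical partitions."""
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_true, labels_pred))


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information in [0, 1]."""
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(labels_true, labels_pred))


@dataclass
class KSelectionResult:
    candidate_ks: list[int]
    sse_curve: list[float]
    chosen_k: int
    repeats: int
    elbow_strength: float
    has_elbow: bool


def _best_sse(z: np.ndarray, k: int, repeats: int, seed: int) -> float:
    best = np.inf
    for r in range(repeats):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                    random_state=seed * 1000 + r).fit(z)
        best = min(best, float(km.inertia_))
    return best


def select_k(data: PreprocessedPair, config: TrainConfig, k_range,
             repeats: int = 10, elbow_threshold: float = 1.0) -> KSelectionResult:
    """Choose the cluster number from the SSE elbow over a pretrained latent.

    ``k_range`` needs at least three candidates so a second difference
    exists.  The latent is standardised before k-means, making the choice
    invariant to global scaling.  Elbow strength is the largest second-order
    difference of the SSE curve divided by its mean first-order difference —
    curvature relative to slope; a featureless (near-linear) curve scores
    well below 1, a genuine elbow well above.  When the strength falls below
    ``elbow_threshold`` the curve is flagged as having no pronounced elbow
    (``has_elbow=False``) and the smallest candidate K is returned.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 candidates")
    if ks[0] < 2 or ks[-1] >= data.n_cells:
        raise ValueError("k_range must lie within [2, n_cells - 1]")

    model = build_model(data, config)
    pretrain(model, data, config)
    latents = model.latent_state(data.rna_input, data.protein_input)
    z = latents.z_fused
    z = (z - z.mean(axis=0)) / np.maximum(z.std(axis=0), 1e-8)

    sse = [_best_sse(z, k, repeats, seed=config.seed + k) for k in ks]
    # best-of-repeats SSE should not increase with K; enforce monotone envelope
    sse = list(np.minimum.accumulate(sse))
    second_diff = [sse[i - 1] - 2.0 * sse[i] + sse[i + 1] for i in range(1, len(ks) - 1)]
    mean_slope = max(float(np.mean(np.abs(np.diff(sse)))), 1e-12)
    strength = max(second_diff) / mean_slope if second_diff else 0.0
    if strength < elbow_threshold:
        warnings.warn("no pronounced elbow in the SSE curve")
        chosen = ks[0]
        has_elbow = False
    else:
        chosen = ks[1 + int(np.argmax(second_diff))]
        has_elbow = True
    return KSelectionResult(candidate_ks=ks, sse_curve=sse, chosen_k=chosen,
                            repeats=repeats, elbow_strength=float(strength),
                            has_elbow=has_elbow)
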