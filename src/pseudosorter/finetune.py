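"""Iterative fine-tuning: the full sorting loop.

After contrastive pretraining, a linear classification head is attached to
the 10-dim bottleneck and the network is trained on K-means++ pseudolabels
sampled from the latent space, over a growing fraction schedule
(1% -> 40% of the dataset by default). After every iteration the latent
space is recomputed with the updated encoder and fresh pseudolabels are
sampled, so early mistakes can be revised. The final per-spike classes are
the classifier's argmax over the whole dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._net import Adam, Dense, log_softmax, softmax
from . import pseudolabel as pl
from .embed import (ContrastiveConfig, Encoder, EncoderSpec, LatentSpace,
                    augment, embed_all, pretrain)
from .evaluate import match_accuracy

logger = logging.getLogger(__name__)

__all__ = ["FineTuneConfig", "SortResult", "Classifier", "build_classifier",
           "finetune_step", "run_pseudosorter"]

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40)


@dataclass
class FineTuneConfig:
    """Schedule and hyperparameters of the iterative fine-tuning loop."""

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    epochs_per_iter: int = 50
    batch_size: int = 128
    max_rel_noise: float = 0.1
    learning_rate: float = 1e-3
    sampling: str = "weighted"
    reestimate_k: bool = False
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size == 0 or np.any(fr <= 0) or np.any(fr > 1):
            raise ValueError("fractions must lie in (0, 1]")
        if np.any(np.diff(fr) <= 0):
            raise ValueError("fractions must be strictly increasing")
        if self.epochs_per_iter < 0 or self.batch_size < 1:
            raise ValueError("invalid schedule")
        if self.sampling not in ("weighted", "densest"):
            raise ValueError(f"unknown sampling method {self.sampling!r}")


@dataclass
class SortResult:
    """Final per-spike classes plus per-iteration diagnostics."""

    labels: np.ndarray
    k_estimate: int
    iterations: list[dict] = field(default_factory=list)
    fingerprint: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= self.k_estimate):
            raise ValueError("labels outside [0, k_estimate)")


class Classifier:
    """Pretrained encoder with a linear classification head."""

    def __init__(self, encoder: Encoder, k: int, seed: int = 0):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.encoder = encoder
        self.k = k
        rng = np.random.default_rng(seed)
        self.head = Dense(encoder.spec.layer_dims[-1], k, rng, scale=0.0)
        self.history: list[float] = []

    def logits(self, features: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.encoder.net.forward(self.encoder.prep(features), train=train)
        return self.head.forward(h, train=train)

    def predict_proba(self, features: np.ndarray,
                      batch_size: int = 4096) -> np.ndarray:
        features = np.asarray(features, dtype=np.float32)
        out = [softmax(self.logits(features[i:i + batch_size]))
               for i in range(0, len(features), batch_size)]
        return np.concatenate(out) if out else np.empty((0, self.k))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)


def build_classifier(encoder: Encoder, k: int, seed: int = 0) -> Classifier:
    """Attach a seeded k-way linear head to the pretrained encoder."""
    return Classifier(encoder, k, seed=seed)


def finetune_step(clf: Classifier, features: np.ndarray,
                  pls: pl.PseudoLabelSet, cfg: FineTuneConfig,
                  rng: np.random.Generator | None = None) -> Classifier:
    """Train the classifier on the pseudolabeled subset only.

    Cross-entropy on augmented features (Gaussian noise, max relative level
    0.1), Adam, ``epochs_per_iter`` epochs of ``batch_size`` minibatches.
    The full network (encoder and head) is trainable.
    """
    cfg.validate()
    features = np.asarray(features, dtype=np.float32)
    if pls.indices.size and pls.indices.max() >= len(features):
        raise ValueError("pseudolabel indices outside the dataset")
    if pls.labels.size and (pls.labels.min() < 0 or pls.labels.max() >= clf.k):
        raise ValueError("pseudolabel outside [0, k)")
    if cfg.epochs_per_iter == 0:
        return clf
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = features[pls.indices]
    y = pls.labels
    n = len(x)
    opt = Adam([clf.encoder.net, clf.head], lr=cfg.learning_rate)
    for _ in range(cfg.epochs_per_iter):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb = augment(x[sel], cfg.max_rel_noise, rng)
            yb = y[sel]
            logits = clf.logits(xb, train=True)
            logp = log_softmax(logits.astype(np.float64))
            losses.append(float(-logp[np.arange(len(sel)), yb].mean()))
            g = np.exp(logp)
            g[np.arange(len(sel)), yb] -= 1.0
            g = (g / len(sel)).astype(np.float32)
            clf.encoder.net.zero_grad()
            clf.head.zero_grad()
            gh = clf.head.backward(g)
            clf.encoder.net.backward(gh)
            opt.step()
        clf.history.append(float(np.mean(losses)))
    return clf


def _align_to_head(pls: pl.PseudoLabelSet, clf: Classifier,
                   features: np.ndarray) -> pl.PseudoLabelSet:
    """Rename pseudoclasses to best match the head's current predictions.

    Each iteration re-clusters from scratch, so K-means++ class ids are an
    arbitrary permutation; training the same head on permuted targets would
    force it to relearn the naming every iteration. A maximum-agreement
    one-to-one relabeling (Hungarian on the confusion matrix of the sampled
    subset) is semantically neutral and keeps the head consistent.
    """
    from scipy.optimize import linear_sum_assignment

    pred = clf.predict(features[pls.indices])
    k = clf.k
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (pls.labels, pred), 1)
    rows, cols = linear_sum_assignment(cm, maximize=True)
    mapping = np.arange(k)
    mapping[rows] = cols
    return pl.PseudoLabelSet(indices=pls.indices, labels=mapping[pls.labels],
                             k=k, fraction=pls.fraction, method=pls.method,
                             seed=pls.seed)


def run_pseudosorter(features: np.ndarray,
                     spec: EncoderSpec | None = None,
                     pre_cfg: ContrastiveConfig | None = None,
                     samp_cfg: pl.SamplingConfig | None = None,
                     ft_cfg: FineTuneConfig | None = None,
                     true_labels: np.ndarray | None = None,
                     k: int | None = None,
                     encoder: Encoder | None = None) -> SortResult:
    """Execute the full sorting loop.

    pretrain -> embed -> estimate k (elbow on the densest 50%) -> for each
    scheduled fraction: density -> sample -> K-means++ pseudolabels ->
    fine-tune -> re-embed. Pass ``k`` to skip the elbow estimate (the
    benchmark setting where the neuron count is given as prior knowledge),
    ``true_labels`` to record per-iteration matched accuracy, or a
    pretrained ``encoder`` to skip pretraining.
    """
    spec = spec or EncoderSpec()
    pre_cfg = pre_cfg or ContrastiveConfig()
    samp_cfg = samp_cfg or pl.SamplingConfig()
    ft_cfg = ft_cfg or FineTuneConfig()
    samp_cfg.validate()
    ft_cfg.validate()
    features = np.asarray(features, dtype=np.float32)
    n = len(features)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    if encoder is None:
        encoder = _stage("pretrain", pretrain, features, spec, pre_cfg)
    latent = _stage("embed", embed_all, encoder, features)

    def _unit(latent: LatentSpace) -> np.ndarray:
        # contrastive training shapes the latent on the unit sphere (cosine
        # similarity); density and K-means++ use the same geometry
        z = latent.embeddings
        return z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True),
                              1e-12)

    K = pl.density_k(n, samp_cfg.k_frac)

    def _estimate_k(latent: LatentSpace) -> int:
        z = _unit(latent)
        density = pl.knn_density(z, K)
        subset = pl.sample_densest(density, samp_cfg.elbow_subset_fraction)
        return pl.estimate_k_elbow(z[subset], samp_cfg.k_search_range,
                                   seed=samp_cfg.seed)

    if k is None:
        k = _stage("estimate_k", _estimate_k, latent)
    logger.info("using k = %d classes", k)

    clf = _stage("build_classifier", build_classifier, encoder, k,
                 ft_cfg.seed)
    rng = np.random.default_rng(ft_cfg.seed)
    iterations: list[dict] = []
    for it, fraction in enumerate(ft_cfg.fractions):
        if ft_cfg.reestimate_k and it > 0:
            k_new = _stage("estimate_k", _estimate_k, latent)
            if k_new != k:
                logger.info("re-estimated k: %d -> %d", k, k_new)
                k = k_new
                clf = _stage("build_classifier", build_classifier, encoder,
                             k, ft_cfg.seed + it)
        z = _unit(latent)
        density = _stage("knn_density", pl.knn_density, z, K)
        if ft_cfg.sampling == "densest":
            idx = _stage("sample", pl.sample_densest, density, fraction)
        else:
            idx = _stage("sample", pl.sample_weighted, density, fraction,
                         samp_cfg.decay_lambda, rng)
        pls = _stage("pseudolabel", pl.assign_pseudolabels, z, idx, k,
                     seed=samp_cfg.seed + it, fraction=fraction,
                     method=ft_cfg.sampling)
        if it > 0:
            pls = _stage("align", _align_to_head, pls, clf, features)
        _stage("finetune", finetune_step, clf, features, pls, ft_cfg, rng)
        latent = _stage("embed", embed_all, clf.encoder, features)
        entry = {
            "fraction": float(fraction),
            "n_pseudolabels": int(len(pls)),
            "loss": clf.history[-1] if clf.history else np.nan,
        }
        if true_labels is not None:
            entry["accuracy"] = match_accuracy(clf.predict(features),
                                               true_labels)
        iterations.append(entry)
        logger.info("iteration %d/%d (fraction %.2f): %s",
                    it + 1, len(ft_cfg.fractions), fraction, entry)

    labels = _stage("predict", clf.predict, features)
    return SortResult(labels=labels, k_estimate=k, iterations=iterations,
                      fingerprint=encoder.fingerprint())
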