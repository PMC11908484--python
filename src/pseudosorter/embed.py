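"""Self-supervised contrastive pretraining of the spike-waveform encoder.

The encoder is a fully connected network [63, 500, 500, 2000, 10] with ReLU
hidden activations; a two-layer projection head of width 10 sits on top of
the bottleneck during pretraining only. Training follows the
nearest-neighbor contrastive scheme (NNCLR): each waveform is augmented
twice with Gaussian noise, the positive for an anchor embedding is its
nearest neighbor (cosine) in a FIFO memory queue of past embeddings, and
the InfoNCE loss

    L = -log exp(sim(z_i, z_i+)/tau) / sum_j exp(sim(z_i, z_j)/tau)

is minimized with Adam, with the denominator running over the batch's
other augmented views and the loss symmetrized over the two views. The
queue is fed by the detached second view, so every entry is refreshed
after queue_size/batch_size steps. Pseudolabeling downstream uses the
10-dim bottleneck, not the projection output.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from ._net import MLP, Adam, ProjectionHead

logger = logging.getLogger(__name__)

__all__ = ["EncoderSpec", "ContrastiveConfig", "LatentSpace", "Encoder",
           "augment", "nnclr_loss", "pretrain", "embed_all"]


@dataclass
class EncoderSpec:
    """Architecture of the encoder and its projection head."""

    layer_dims: tuple[int, ...] = (63, 500, 500, 2000, 10)
    projection_width: int = 10

    def validate(self) -> None:
        if len(self.layer_dims) < 2:
            raise ValueError("encoder needs at least two layer dims")
        if self.layer_dims[-1] != self.projection_width:
            raise ValueError("bottleneck width must equal projection width")


@dataclass
class ContrastiveConfig:
    """Pretraining hyperparameters."""

    temperature: float = 0.1
    max_rel_noise: float = 0.075
    epochs: int = 25
    batch_size: int = 256
    learning_rate: float = 1e-3
    queue_size: int = 8192
    #: how the positive is picked: the anchor's nearest neighbor in the
    #: memory queue ("queue_nn", NNCLR-style) or the second augmented view
    #: of the same waveform ("augmented", with queue negatives)
    positive_mode: str = "queue_nn"
    seed: int = 0

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0.0 <= self.max_rel_noise < 1.0):
            raise ValueError("max_rel_noise must be in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid training schedule")
        if self.positive_mode not in ("queue_nn", "augmented"):
            raise ValueError(f"unknown positive_mode {self.positive_mode!r}")


class Encoder:
    """Trained (or freshly initialized) waveform encoder.

    ``net`` maps features to the 10-dim bottleneck; ``projection`` is only
    used during contrastive training.
    """

    def __init__(self, spec: EncoderSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.net = MLP(spec.layer_dims, rng)
        self.projection = ProjectionHead(spec.projection_width, rng)
        self.history: list[float] = []
        # per-dimension input scaler, fitted on the pretraining features;
        # gradient features carry the 1/dt scale (~1e4), which would
        # otherwise dwarf the He-initialized weights
        self._mu = np.zeros(spec.layer_dims[0], dtype=np.float32)
        self._sd = np.ones(spec.layer_dims[0], dtype=np.float32)

    def fit_scaler(self, features: np.ndarray) -> None:
        # per-dimension centering plus one global scale: translation and
        # isotropic scaling preserve the feature geometry (unlike per-dim
        # standardization, which would equalize signal- and noise-dominated
        # dimensions) while bringing magnitudes to O(1)
        features = np.asarray(features, dtype=np.float32)
        self._mu = features.mean(axis=0)
        sd = float(features.std()) or 1.0
        self._sd = np.full(features.shape[1], sd, dtype=np.float32)

    def prep(self, features: np.ndarray) -> np.ndarray:
        """Apply the input scaler (identity until fitted)."""
        return (np.asarray(features, dtype=np.float32) - self._mu) / self._sd

    def embed(self, features: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        features = np.asarray(features, dtype=np.float32)
        if features.ndim != 2:
            features = np.atleast_2d(features)
        if features.shape[0] == 0:
            return np.empty((0, self.spec.layer_dims[-1]), dtype=np.float32)
        out = [self.net.forward(self.prep(features[i:i + batch_size]))
               for i in range(0, features.shape[0], batch_size)]
        return np.concatenate(out)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for w in self.net.get_weights():
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: str) -> None:
        weights = self.net.get_weights() + self.projection.get_weights()
        np.savez(path,
                 layer_dims=np.asarray(self.spec.layer_dims),
                 scaler_mu=self._mu, scaler_sd=self._sd,
                 n_encoder_arrays=np.asarray(len(self.net.get_weights())),
                 fingerprint=np.frombuffer(
                     self.fingerprint().encode(), dtype=np.uint8),
                 **{f"w{i}": w for i, w in enumerate(weights)})

    @classmethod
    def load(cls, path: str) -> "Encoder":
        with np.load(path) as z:
            dims = tuple(int(d) for d in z["layer_dims"])
            n_enc = int(z["n_encoder_arrays"])
            weights = [z[f"w{i}"] for i in range(len(
                [k for k in z.files if k.startswith("w")]))]
        enc = cls(EncoderSpec(layer_dims=dims, projection_width=dims[-1]),
                  seed=0)
        enc.net.set_weights(weights[:n_enc])
        enc.projection.set_weights(weights[n_enc:])
        with np.load(path) as z:
            if "scaler_mu" in z.files:
                enc._mu = z["scaler_mu"].astype(np.float32)
                enc._sd = z["scaler_sd"].astype(np.float32)
        return enc


@dataclass
class LatentSpace:
    """n x 10 embeddings with optional per-point KNN density."""

    embeddings: np.ndarray
    fingerprint: str = ""
    density: np.ndarray | None = None

    def __post_init__(self):
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings,
                                                   dtype=np.float64))
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite values")

    def __len__(self) -> int:
        return self.embeddings.shape[0]


def augment(features: np.ndarray, max_rel_noise: float,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Gaussian-noise augmentation with a randomized per-row level.

    Each row i receives N(0, s_i) noise with s_i = u_i * max_rel_noise *
    ptp_i, where u_i ~ Uniform(0, 1) and ptp_i is the row's peak-to-peak
    range — "relative" is relative to the row's own span, keeping the
    perturbation commensurate across spikes of different amplitude.
    """
    if max_rel_noise < 0:
        raise ValueError("max_rel_noise must be >= 0")
    features = np.asarray(features, dtype=np.float32)
    if max_rel_noise == 0 or features.size == 0:
        return features.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ptp = (features.max(axis=1) - features.min(axis=1)).astype(np.float32)
    level = (rng.uniform(0.0, max_rel_noise, size=features.shape[0])
             .astype(np.float32) * ptp)
    noise = rng.standard_normal(features.shape, dtype=np.float32)
    return features + noise * level[:, None]


def _unit_rows(z: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    norms = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(norms < eps):
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    return z / norms


def nnclr_loss(anchor: np.ndarray, support: np.ndarray,
               temperature: float = 0.1, positive_index: int = 0) -> float:
    """Contrastive loss of one anchor against a support set.

    ``support`` holds the positive (at ``positive_index``) and the other
    contrast embeddings. Returns
    -log softmax(cos(anchor, support)/tau)[positive_index]; zero when the
    support set contains only the positive.
    """
    anchor = np.asarray(anchor, dtype=np.float64).ravel()
    support = np.atleast_2d(np.asarray(support, dtype=np.float64))
    a = _unit_rows(anchor[None, :])[0]
    s = _unit_rows(support)
    sims = s @ a / float(temperature)
    m = sims.max()
    logz = m + np.log(np.exp(sims - m).sum())
    return float(logz - sims[positive_index])


def _contrastive_step(encoder: Encoder, batch: np.ndarray,
                      queue: np.ndarray, queue_n: int,
                      cfg: ContrastiveConfig,
                      rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """One NNCLR step; returns (mean loss, detached second-view embeddings).

    Gradient flows through the first augmented view only; the second view is
    detached, feeds the queue, and (while the queue is still empty) stands
    in as the positive directly.
    """
    tau = cfg.temperature
    eps = np.float32(1e-12)
    a1 = augment(batch, cfg.max_rel_noise, rng)
    a2 = augment(batch, cfg.max_rel_noise, rng)

    def _direction(a_anchor: np.ndarray, u_other: np.ndarray) -> float:
        """One direction of the symmetric loss.

        The anchor view carries gradients; its positive is the nearest
        queue neighbor of the (detached) other view, contrasted against
        the anchors of the rest of the batch.
        """
        h = encoder.net.forward(encoder.prep(a_anchor), train=True)
        z = encoder.projection.forward(h, train=True)
        nz = np.maximum(np.linalg.norm(z, axis=1, keepdims=True), eps)
        u = z / nz
        B = len(u)
        rows = np.arange(B)
        if cfg.positive_mode == "queue_nn" and queue_n > 0:
            bank = queue[:queue_n]
            pos = bank[np.argmax(u_other @ bank.T, axis=1)]  # detached
        else:
            pos = u_other
        logits64 = ((pos @ u.T) / tau).astype(np.float64)  # i x k
        m = logits64.max(axis=1, keepdims=True)
        logz = m + np.log(np.exp(logits64 - m).sum(axis=1, keepdims=True))
        loss = float((logz[:, 0] - logits64[rows, rows]).mean())
        p = np.exp(logits64 - logz)
        p[rows, rows] -= 1.0
        g_u = ((p / (tau * B)).astype(np.float32).T @ pos)
        # through row normalization: g_z = (g - (g.u)u)/||z||
        g_z = (g_u - (g_u * u).sum(axis=1, keepdims=True) * u) / nz
        encoder.net.backward(encoder.projection.backward(g_z))
        return loss

    # detached embeddings of both views (positive selection, queue feed)
    u_det = []
    for a in (a1, a2):
        z = encoder.projection.forward(encoder.net.forward(encoder.prep(a)))
        u_det.append(z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True),
                                    eps))
    u1, u2 = u_det

    encoder.net.zero_grad()
    encoder.projection.zero_grad()
    loss = 0.5 * (_direction(a2, u1) + _direction(a1, u2))
    return loss, u2


def pretrain(features: np.ndarray, spec: EncoderSpec | None = None,
             cfg: ContrastiveConfig | None = None) -> Encoder:
    """Contrastive pretraining of the encoder on unlabeled features.

    Runs ``cfg.epochs`` passes (epochs = 0 returns the seeded random
    initialization, still usable for embedding); per-epoch mean loss is
    appended to ``encoder.history``.
    """
    spec = spec or EncoderSpec()
    cfg = cfg or ContrastiveConfig()
    spec.validate()
    cfg.validate()
    features = np.asarray(features, dtype=np.float32)
    if features.ndim != 2 or features.shape[1] != spec.layer_dims[0]:
        raise ValueError(
            f"feature width {features.shape[-1] if features.ndim == 2 else '?'}"
            f" does not match encoder input dim {spec.layer_dims[0]}"
        )
    n = features.shape[0]
    if cfg.epochs > 0 and n < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} samples")

    encoder = Encoder(spec, seed=cfg.seed)
    encoder.fit_scaler(features)
    if cfg.epochs == 0:
        return encoder
    rng = np.random.default_rng(cfg.seed)
    opt = Adam([encoder.net, encoder.projection], lr=cfg.learning_rate)

    qsize = min(cfg.queue_size, n)
    queue = np.zeros((qsize, spec.projection_width), dtype=np.float32)
    q_ptr = 0
    # prefill the queue with embeddings of a random subset under the initial
    # weights, so the contrast-set size is constant from the first step and
    # per-epoch losses are comparable
    warm = rng.choice(n, size=qsize, replace=False)
    z0 = encoder.projection.forward(
        encoder.net.forward(encoder.prep(features[warm])))
    queue[:] = z0 / np.maximum(np.linalg.norm(z0, axis=1, keepdims=True),
                               np.float32(1e-12))
    queue_n = qsize

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = features[order[start:start + cfg.batch_size]]
            loss, u2 = _contrastive_step(encoder, batch, queue, queue_n,
                                         cfg, rng)
            opt.step()
            losses.append(loss)
            # FIFO queue update with the detached second view
            for row in u2:
                queue[q_ptr] = row
                q_ptr = (q_ptr + 1) % qsize
                queue_n = min(queue_n + 1, qsize)
        epoch_loss = float(np.mean(losses))
        encoder.history.append(epoch_loss)
        logger.info("pretrain epoch %d/%d: loss %.4f",
                    epoch + 1, cfg.epochs, epoch_loss)
    return encoder


def embed_all(encoder: Encoder, features: np.ndarray) -> LatentSpace:
    """Embed every waveform into the 10-dim latent space."""
    z = encoder.embed(features)
    return LatentSpace(embeddings=z, fingerprint=encoder.fingerprint())
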