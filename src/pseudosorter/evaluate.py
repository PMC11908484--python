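"""Scoring of sort results against ground truth, plus a classical baseline.

Matched accuracy uses a maximum-weight one-to-one (Hungarian) assignment
between predicted and true classes on the confusion matrix; unmatched
predicted classes contribute zero. SNR is the spike's trough amplitude over
the robust noise estimate sigma_m, binned into [4, 6), [6, 8) and [8, inf)
for noise-stratified accuracy. The PCA-GMM baseline (PCA to a few
components, then a Gaussian mixture) stands in for the classical
feature-projection sorters commonly used as reference points.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = ["EvalReport", "match_accuracy", "predict_k_error", "spike_snr",
           "snr_bin_indices", "snr_binned_accuracy", "baseline_pca_gmm",
           "repeated_eval", "SNR_BINS"]

#: accuracy stratification bins: [4, 6), [6, 8), [8, inf)
SNR_BINS: tuple[tuple[float, float], ...] = ((4.0, 6.0), (6.0, 8.0),
                                             (8.0, np.inf))


@dataclass
class EvalReport:
    """Aggregate of repeated evaluations of one sorter on one dataset."""

    accuracy: float
    per_run: list[float]
    accuracy_std: float = 0.0
    k_true: int | None = None
    k_pred: int | None = None
    snr_bin_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.per_run)


def _confusion(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(true, return_inverse=True)
    cm = np.zeros((pu.size, tu.size), dtype=np.int64)
    np.add.at(cm, (pi, ti), 1)
    return cm


def match_accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    """Fraction correct under the best one-to-one class matching.

    Invariant to relabeling of either argument; with more predicted than
    true classes (or vice versa) the surplus classes are left unmatched and
    score zero.
    """
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if pred.size == 0:
        raise ValueError("empty label arrays")
    cm = _confusion(pred, true)
    rows, cols = linear_sum_assignment(cm, maximize=True)
    return float(cm[rows, cols].sum() / pred.size)


def predict_k_error(k_pred: int, k_true: int) -> int:
    """Signed neuron-count error k_pred - k_true (negative = underestimate)."""
    if k_pred < 1 or k_true < 1:
        raise ValueError("class counts must be >= 1")
    return int(k_pred) - int(k_true)


def spike_snr(waveforms: np.ndarray, sigma_m: float) -> np.ndarray:
    """Per-spike SNR: |trough amplitude| / sigma_m."""
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    w = np.atleast_2d(np.asarray(waveforms, dtype=np.float64))
    return np.abs(w.min(axis=1)) / sigma_m


def snr_bin_indices(snr: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean masks for the three SNR bins; keys like '4-6', '6-8', '>8'."""
    snr = np.asarray(snr, dtype=np.float64)
    out = {}
    for lo, hi in SNR_BINS:
        key = f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"
        out[key] = (snr >= lo) & (snr < hi)
    return out


def snr_binned_accuracy(pred: np.ndarray, true: np.ndarray,
                        snr: np.ndarray) -> dict[str, float]:
    """Matched accuracy computed separately within each SNR bin.

    The class matching is established once on the full dataset, then scored
    per bin, so a bin cannot invent its own favorable matching.
    """
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    cm = _confusion(pred, true)
    rows, cols = linear_sum_assignment(cm, maximize=True)
    pu = np.unique(pred)
    tu = np.unique(true)
    mapping = {pu[r]: tu[c] for r, c in zip(rows, cols)}
    mapped = np.asarray([mapping.get(p, -1) for p in pred])
    correct = mapped == true
    out = {}
    for key, mask in snr_bin_indices(snr).items():
        out[key] = float(correct[mask].mean()) if mask.any() else np.nan
    return out


def baseline_pca_gmm(features: np.ndarray, k: int, n_components: int = 3,
                     seed: int | None = 0) -> np.ndarray:
    """Classical baseline: PCA projection followed by a Gaussian mixture."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = features.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    n_components = min(n_components, features.shape[1], n)
    proj = PCA(n_components=n_components, random_state=seed)
    x = proj.fit_transform(features)
    gmm = GaussianMixture(n_components=k, covariance_type="full",
                          random_state=seed, n_init=1, max_iter=200)
    return gmm.fit_predict(x)


def repeated_eval(sorter, features: np.ndarray, true_labels: np.ndarray,
                  n_runs: int = 5, seeds=None,
                  snr: np.ndarray | None = None) -> EvalReport:
    """Run ``sorter(features, seed) -> labels`` n_runs times and aggregate.

    Per-run matched accuracies, their mean and std are reported; when
    per-spike SNR values are supplied, SNR-binned accuracy of the last run
    is included.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    true_labels = np.asarray(true_labels).ravel()
    per_run, k_pred, last_pred = [], None, None
    for i, seed in enumerate(seeds):
        try:
            pred = np.asarray(sorter(features, seed)).ravel()
        except Exception as exc:
            raise RuntimeError(f"sorter failed on run {i} "
                               f"(seed {seed}): {exc}") from exc
        per_run.append(match_accuracy(pred, true_labels))
        k_pred = int(np.unique(pred).size)
        last_pred = pred
    report = EvalReport(
        accuracy=float(np.mean(per_run)),
        per_run=per_run,
        accuracy_std=float(np.std(per_run)),
        k_true=int(np.unique(true_labels).size),
        k_pred=k_pred,
    )
    if snr is not None and last_pred is not None:
        report.snr_bin_accuracy = snr_binned_accuracy(last_pred, true_labels,
                                                      snr)
    return report
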