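"""Raw-trace preprocessing: bandpass, noise estimate, detection, extraction,
normalization and gradient mapping.

The chain turns a single-channel extracellular voltage trace into the n x 63
feature matrix the encoder consumes:

1. zero-phase Butterworth bandpass (300-3000 Hz by default);
2. robust noise estimate ``sigma_m = median(|x|) / 0.6745``;
3. threshold detection at ``-threshold_multiplier * sigma_m`` (negative-going
   crossings; extracellular somatic spikes are negative deflections);
4. extraction of 64-sample windows (20 before + 44 after the event), aligned
   on the threshold crossing or on the trough;
5. per-spike min-max normalization to [0, 1] followed by the first
   difference divided by the sampling step (50 us at 20 kHz), giving 63
   gradient features per spike.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: factor mapping the median absolute deviation of a centered Gaussian to its
#: standard deviation: median(|N(0, 1)|) = 0.6745.
MAD_SCALE = 0.6745


@dataclass
class DetectionConfig:
    """Detection and extraction parameters."""

    band_low_hz: float = 300.0
    band_high_hz: float = 3000.0
    threshold_multiplier: float = 5.0
    pre_samples: int = 20
    post_samples: int = 44
    dead_time_samples: int = 20
    align_on: str = "minimum"  # or "threshold_crossing"
    #: samples after the crossing searched for the trough; the trough of a
    #: spike of FWHM <= 0.6 ms follows its 5-sigma crossing within ~0.5 ms
    trough_search_samples: int = 16
    detect_positive: bool = False
    filter_order: int = 4

    @property
    def n_samples(self) -> int:
        return self.pre_samples + self.post_samples

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < {self.band_low_hz} < "
                f"{self.band_high_hz} < Nyquist ({nyq})"
            )
        if self.align_on not in ("minimum", "threshold_crossing"):
            raise ValueError(f"unknown align_on: {self.align_on!r}")
        if self.pre_samples < 1 or self.post_samples < 1:
            raise ValueError("pre_samples and post_samples must be positive")


@dataclass
class WaveformSet:
    """Aligned spike waveforms with times, optional labels and features.

    ``waveforms`` is n x 64 in microvolts, ``features`` the n x 63 gradient
    matrix of the min-max-normalized waveforms (units 1/s). ``labels`` is
    None for unlabeled data. ``flat_mask`` marks degenerate (constant)
    waveforms whose feature rows were zeroed.
    """

    waveforms: np.ndarray
    times_ms: np.ndarray
    dt_s: float
    labels: np.ndarray | None = None
    features: np.ndarray | None = None
    sigma_m: float | None = None
    flat_mask: np.ndarray | None = None

    def __post_init__(self):
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=np.float64))
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.waveforms.shape[0] != self.times_ms.shape[0]:
            raise ValueError("waveforms and times_ms disagree on n")
        if self.labels is not None and self.labels.shape[0] != len(self):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def copy(self) -> "WaveformSet":
        return replace(
            self,
            waveforms=self.waveforms.copy(),
            times_ms=self.times_ms.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            features=None if self.features is None else self.features.copy(),
            flat_mask=None if self.flat_mask is None else self.flat_mask.copy(),
        )


def bandpass_filter(trace: np.ndarray, cfg: DetectionConfig,
                    sampling_rate_hz: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass.

    Forward-backward application (``sosfiltfilt``) so spike times are not
    shifted by the filter's phase response.
    """
    cfg.validate(sampling_rate_hz)
    trace = np.asarray(trace, dtype=np.float64)
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=sampling_rate_hz,
        output="sos",
    )
    pad = 3 * (2 * cfg.filter_order + 1)
    if trace.size <= pad:
        raise ValueError(f"trace too short to filter (need > {pad} samples)")
    return signal.sosfiltfilt(sos, trace)


def estimate_noise(x: np.ndarray) -> float:
    """Robust noise estimate sigma_m = median(|x|) / 0.6745."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("cannot estimate noise of an empty trace")
    return float(np.median(np.abs(x)) / MAD_SCALE)


def trough_index(segment: np.ndarray) -> int:
    """Trough locator: argmin of the 3-sample moving average.

    The light smoothing stabilizes the argmin on wide, flat troughs where
    single-sample noise would otherwise jitter the alignment by several
    samples; symmetric averaging does not shift a locally symmetric trough.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size < 3:
        return int(np.argmin(segment))
    sm = np.convolve(segment, np.ones(3) / 3.0, mode="same")
    # edge samples average fewer points; rescale to keep them comparable
    sm[0] = segment[:2].mean()
    sm[-1] = segment[-2:].mean()
    i = int(np.argmin(sm))
    # refine by raw value among the smoothed minimum's direct neighbors
    lo = max(i - 1, 0)
    return lo + int(np.argmin(segment[lo:i + 2]))


def detect_spikes(x: np.ndarray, cfg: DetectionConfig,
                  sigma_m: float | None = None) -> np.ndarray:
    """Threshold crossings of the filtered trace.

    Returns the sample indices of negative-going crossings of
    ``-threshold_multiplier * sigma_m`` (positive crossings instead when
    ``detect_positive``). Crossings closer than ``dead_time_samples`` to the
    previous accepted event are suppressed; events too close to the trace
    edges for a full window are dropped.
    """
    x = np.asarray(x, dtype=np.float64)
    if sigma_m is None:
        sigma_m = estimate_noise(x)
    thr = cfg.threshold_multiplier * sigma_m
    if cfg.detect_positive:
        below = x > thr
    else:
        below = x < -thr
    # first sample of each run below threshold
    crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))

    events = []
    last = -np.inf
    for c in crossings:
        if c - last < cfg.dead_time_samples:
            continue
        events.append(c)
        last = c
    events = np.asarray(events, dtype=np.int64)

    lo, hi = cfg.pre_samples, x.size - cfg.post_samples
    keep = (events >= lo) & (events < hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d edge events without a full window", n_dropped)
    return events[keep]


def extract_waveforms(x: np.ndarray, events: np.ndarray, cfg: DetectionConfig,
                      sampling_rate_hz: float,
                      sigma_m: float | None = None) -> WaveformSet:
    """Cut 64-sample windows around each event.

    With ``align_on='minimum'`` the window is re-centered so the trough sits
    at index ``pre_samples``; the trough is searched within ``post_samples``
    of the crossing. Events whose final window would run off either end of
    the trace are silently dropped (count logged).
    """
    x = np.asarray(x, dtype=np.float64)
    if sigma_m is None:
        sigma_m = estimate_noise(x)
    pre, post = cfg.pre_samples, cfg.post_samples
    rows, kept = [], []
    n_dropped = 0
    for e in np.asarray(events, dtype=np.int64):
        if cfg.align_on == "minimum":
            stop = min(e + cfg.trough_search_samples, x.size)
            seg = x[e:stop]
            if seg.size == 0:
                n_dropped += 1
                continue
            center = e + (int(np.argmax(seg)) if cfg.detect_positive
                          else trough_index(seg))
        else:
            center = int(e)
        if center - pre < 0 or center + post > x.size:
            n_dropped += 1
            continue
        rows.append(x[center - pre:center + post])
        kept.append(center)
    if n_dropped:
        logger.info("dropped %d events during extraction", n_dropped)
    dt_s = 1.0 / sampling_rate_hz
    if not rows:
        return WaveformSet(
            waveforms=np.empty((0, pre + post)),
            times_ms=np.empty(0),
            dt_s=dt_s,
            sigma_m=sigma_m,
        )
    return WaveformSet(
        waveforms=np.stack(rows),
        times_ms=np.asarray(kept, dtype=np.float64) * dt_s * 1e3,
        dt_s=dt_s,
        sigma_m=sigma_m,
    )


def minmax_normalize(waveforms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row min-max normalization to [0, 1].

    Returns the normalized matrix and a boolean mask of flat rows (max ==
    min), which are mapped to all-zeros rather than raising — keeping row
    indices stable for label bookkeeping.
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=np.float64))
    lo = w.min(axis=1, keepdims=True)
    hi = w.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0.0
    span[flat] = 1.0
    out = (w - lo) / span
    out[flat] = 0.0
    return out, flat


def normalize_and_gradient(wset: WaveformSet) -> WaveformSet:
    """Min-max normalize each spike and map to its gradient representation.

    The gradient of spike x is (x(t+1) - x(t)) / dt, one fewer column than
    the waveform (63 for 64-sample spikes). Flat waveforms produce all-zero
    feature rows and are flagged in ``flat_mask``.
    """
    norm, flat = minmax_normalize(wset.waveforms)
    if flat.any():
        logger.warning("%d flat waveform(s): features zeroed", int(flat.sum()))
    feats = np.diff(norm, axis=1) / wset.dt_s
    feats[flat] = 0.0
    out = wset.copy()
    out.features = feats
    out.flat_mask = flat
    return out


def preprocess_trace(trace: np.ndarray, sampling_rate_hz: float,
                     cfg: DetectionConfig | None = None) -> WaveformSet:
    """Full chain: bandpass -> sigma_m -> detect -> extract -> features."""
    cfg = cfg or DetectionConfig()
    x = bandpass_filter(trace, cfg, sampling_rate_hz)
    sigma_m = estimate_noise(x)
    events = detect_spikes(x, cfg, sigma_m)
    wset = extract_waveforms(x, events, cfg, sampling_rate_hz, sigma_m)
    return normalize_and_gradient(wset)
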