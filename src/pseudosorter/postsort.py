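"""Per-unit quality metrics and treatment analytics.

For each sorted unit: mean waveform, trough amplitude (signed, uV), FWHM of
the trough (time between the two half-amplitude crossings, linearly
interpolated), refractory-period-violation (RPV) rate at a 2 ms absolute
refractory period, and pre/post-treatment firing-rate change. Units with an
RPV rate of 0.1% or more are excluded from aggregate analyses, since their
spike trains are inconsistent with a single source neuron.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["UnitSummary", "fwhm", "rpv_rate", "filter_units", "rate_change",
           "unit_summaries"]


@dataclass
class UnitSummary:
    """Quality summary of one sorted unit."""

    unit_id: int
    n_spikes: int
    mean_waveform: np.ndarray
    fwhm_ms: float
    amplitude_uv: float
    rpv_rate: float
    rate_pre_hz: float | None = None
    rate_post_hz: float | None = None
    relative_change: float | None = None


def fwhm(waveform: np.ndarray, dt_s: float) -> float:
    """Full width at half maximum of the spike trough, in ms.

    Peak amplitude is measured trough-to-zero (bandpassed waveforms are
    zero-mean). The two crossings of the half-amplitude level flanking the
    trough are located by linear interpolation between samples; if either
    side never rises back above half amplitude, NaN is returned (undefined
    FWHM) rather than raising.
    """
    w = np.asarray(waveform, dtype=np.float64).ravel()
    if w.size < 3 or dt_s <= 0:
        raise ValueError("waveform too short or invalid dt_s")
    trough = int(np.argmin(w))
    amp = w[trough]
    if amp >= 0:
        return float("nan")
    half = amp / 2.0

    def _cross(idx_range) -> float:
        # scan away from the trough for the first sample above half level
        prev = trough
        for i in idx_range:
            if w[i] > half:
                # crossing between i and prev (w[prev] <= half < w[i])
                frac = (half - w[i]) / (w[prev] - w[i])
                return i + frac * (prev - i)
            prev = i
        return float("nan")

    left = _cross(range(trough - 1, -1, -1))
    right = _cross(range(trough + 1, w.size))
    if np.isnan(left) or np.isnan(right):
        return float("nan")
    return float((right - left) * dt_s * 1e3)


def rpv_rate(spike_times_ms: np.ndarray, refractory_ms: float = 2.0) -> float:
    """Fraction of spikes whose preceding inter-spike interval violates the
    refractory period. Empty or singleton trains score 0."""
    t = np.asarray(spike_times_ms, dtype=np.float64).ravel()
    if t.size <= 1:
        return 0.0
    isi = np.diff(t)
    if np.any(isi < 0):
        raise ValueError("spike times must be sorted ascending")
    return float((isi < refractory_ms).sum() / t.size)


def filter_units(summaries: list[UnitSummary],
                 rpv_threshold: float = 0.001) -> list[UnitSummary]:
    """Keep units with an RPV rate strictly below the threshold."""
    kept = [s for s in summaries if s.rpv_rate < rpv_threshold]
    dropped = len(summaries) - len(kept)
    if dropped:
        logger.info("filter_units: dropped %d of %d units (RPV >= %g)",
                    dropped, len(summaries), rpv_threshold)
    return kept


def rate_change(pre_times_ms: np.ndarray, post_times_ms: np.ndarray,
                pre_duration_s: float, post_duration_s: float) -> float:
    """Relative firing-rate change (post - pre) / pre.

    NaN (undefined) when the unit fired no spikes pre-treatment.
    """
    if pre_duration_s <= 0 or post_duration_s <= 0:
        raise ValueError("durations must be > 0")
    pre_rate = len(np.asarray(pre_times_ms).ravel()) / pre_duration_s
    post_rate = len(np.asarray(post_times_ms).ravel()) / post_duration_s
    if pre_rate == 0:
        return float("nan")
    return float((post_rate - pre_rate) / pre_rate)


def unit_summaries(waveforms: np.ndarray, times_ms: np.ndarray,
                   labels: np.ndarray, dt_s: float,
                   refractory_ms: float = 2.0,
                   pre_post_split_ms: float | None = None,
                   pre_duration_s: float | None = None,
                   post_duration_s: float | None = None) -> list[UnitSummary]:
    """Build one UnitSummary per predicted class.

    When ``pre_post_split_ms`` is given, spikes before/after the split feed
    the pre/post firing rates and the relative change (durations default to
    the split position and the remaining span of the recording).
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=np.float64))
    times_ms = np.asarray(times_ms, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    out = []
    for unit in np.unique(labels):
        sel = labels == unit
        t = np.sort(times_ms[sel])
        mean_w = waveforms[sel].mean(axis=0)
        summary = UnitSummary(
            unit_id=int(unit),
            n_spikes=int(sel.sum()),
            mean_waveform=mean_w,
            fwhm_ms=fwhm(mean_w, dt_s),
            amplitude_uv=float(mean_w.min()),
            rpv_rate=rpv_rate(t, refractory_ms),
        )
        if pre_post_split_ms is not None:
            pre_t = t[t < pre_post_split_ms]
            post_t = t[t >= pre_post_split_ms]
            pre_dur = pre_duration_s or pre_post_split_ms / 1e3
            post_dur = post_duration_s or max(
                (times_ms.max() - pre_post_split_ms) / 1e3, 1e-9)
            summary.rate_pre_hz = len(pre_t) / pre_dur
            summary.rate_post_hz = len(post_t) / post_dur
            summary.relative_change = rate_change(pre_t, post_t, pre_dur,
                                                  post_dur)
        out.append(summary)
    return out
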