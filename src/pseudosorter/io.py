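"""Serialization of traces, waveform datasets and sort results.

Two interchangeable layouts per artifact:

* raw trace — flat little-endian float32 binary plus a JSON sidecar
  ``{"sampling_rate_hz": ..., "units": "uV"}``, or one HDF5 file with
  ``/trace`` and optional ``/truth/times_ms`` + ``/truth/labels``;
* waveform dataset — CSV with header ``label,time_ms,s0..s63`` (label -1
  when unknown), or HDF5 with ``/waveforms``, ``/times_ms``, ``/labels``
  and optional ``/features``.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .finetune import SortResult
from .preprocess import WaveformSet

__all__ = ["save_trace", "load_trace", "save_trace_h5", "load_trace_h5",
           "save_waveforms_csv", "load_waveforms_csv", "save_waveforms_h5",
           "load_waveforms_h5", "save_result_h5", "load_result_h5",
           "atomic_write"]


def atomic_write(path: str | Path, writer) -> None:
    """Write via a temp file + rename so partial failures leave no artifact."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


# -- raw trace ---------------------------------------------------------------

def save_trace(path: str | Path, trace: np.ndarray,
               sampling_rate_hz: float) -> None:
    path = Path(path)
    np.asarray(trace, dtype="<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"sampling_rate_hz": sampling_rate_hz, "units": "uV",
         "dtype": "<f4", "n_samples": int(len(trace))}))


def load_trace(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    trace = np.fromfile(path, dtype=meta.get("dtype", "<f4")).astype(np.float64)
    return trace, float(meta["sampling_rate_hz"])


def save_trace_h5(path: str | Path, trace: np.ndarray,
                  sampling_rate_hz: float,
                  truth_times_ms: np.ndarray | None = None,
                  truth_labels: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=np.asarray(trace, dtype=np.float32))
        d.attrs["units"] = "uV"
        f.attrs["sampling_rate_hz"] = sampling_rate_hz
        if truth_times_ms is not None:
            f.create_dataset("truth/times_ms", data=truth_times_ms)
        if truth_labels is not None:
            f.create_dataset("truth/labels",
                             data=np.asarray(truth_labels, dtype=np.int64))


def load_trace_h5(path: str | Path):
    with h5py.File(path, "r") as f:
        trace = f["trace"][...].astype(np.float64)
        fs = float(f.attrs["sampling_rate_hz"])
        times = f["truth/times_ms"][...] if "truth/times_ms" in f else None
        labels = f["truth/labels"][...] if "truth/labels" in f else None
    return trace, fs, times, labels


# -- waveform datasets -------------------------------------------------------

def save_waveforms_csv(path: str | Path, wset: WaveformSet) -> None:
    n, d = wset.waveforms.shape
    labels = wset.labels if wset.labels is not None \
        else np.full(n, -1, dtype=np.int64)
    df = pd.DataFrame(wset.waveforms, columns=[f"s{i}" for i in range(d)])
    df.insert(0, "time_ms", wset.times_ms)
    df.insert(0, "label", labels)
    df.to_csv(path, index=False)


def load_waveforms_csv(path: str | Path, dt_s: float = 5e-5,
                       sigma_m: float | None = None) -> WaveformSet:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("s")]
    labels = df["label"].to_numpy(dtype=np.int64)
    return WaveformSet(
        waveforms=df[cols].to_numpy(dtype=np.float64),
        times_ms=df["time_ms"].to_numpy(dtype=np.float64),
        dt_s=dt_s,
        labels=None if (labels < 0).all() else labels,
        sigma_m=sigma_m,
    )


def save_waveforms_h5(path: str | Path, wset: WaveformSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=wset.waveforms)
        f.create_dataset("times_ms", data=wset.times_ms)
        if wset.labels is not None:
            f.create_dataset("labels", data=wset.labels)
        if wset.features is not None:
            f.create_dataset("features", data=wset.features)
        f.attrs["dt_s"] = wset.dt_s
        if wset.sigma_m is not None:
            f.attrs["sigma_m"] = wset.sigma_m


def load_waveforms_h5(path: str | Path) -> WaveformSet:
    with h5py.File(path, "r") as f:
        return WaveformSet(
            waveforms=f["waveforms"][...],
            times_ms=f["times_ms"][...],
            dt_s=float(f.attrs["dt_s"]),
            labels=f["labels"][...] if "labels" in f else None,
            features=f["features"][...] if "features" in f else None,
            sigma_m=float(f.attrs["sigma_m"]) if "sigma_m" in f.attrs
            else None,
        )


# -- pseudolabel sets --------------------------------------------------------

def save_pseudolabels_csv(path: str | Path, pls) -> None:
    """CSV ``index,label`` with the sampling metadata in comment headers."""
    lines = [f"# fraction={pls.fraction}", f"# k={pls.k}",
             f"# method={pls.method}", f"# seed={pls.seed}",
             "index,label"]
    lines += [f"{i},{l}" for i, l in zip(pls.indices, pls.labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_pseudolabels_csv(path: str | Path):
    from .pseudolabel import PseudoLabelSet

    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
        elif line and not line.startswith("index"):
            i, _, l = line.partition(",")
            rows.append((int(i), int(l)))
    idx, labels = (np.array(x, dtype=np.int64)
                   for x in zip(*rows)) if rows else (np.empty(0, np.int64),) * 2
    seed = meta.get("seed")
    return PseudoLabelSet(
        indices=idx, labels=labels, k=int(meta["k"]),
        fraction=float(meta["fraction"]), method=meta.get("method", ""),
        seed=None if seed in (None, "None") else int(seed))


# -- sort results ------------------------------------------------------------

def save_result_h5(path: str | Path, result: SortResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=result.labels)
        f.attrs["k"] = result.k_estimate
        f.attrs["fingerprint"] = result.fingerprint
        f.attrs["iterations_json"] = json.dumps(result.iterations)


def load_result_h5(path: str | Path) -> SortResult:
    with h5py.File(path, "r") as f:
        return SortResult(
            labels=f["labels"][...],
            k_estimate=int(f.attrs["k"]),
            iterations=json.loads(f.attrs.get("iterations_json", "[]")),
            fingerprint=str(f.attrs.get("fingerprint", "")),
        )
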