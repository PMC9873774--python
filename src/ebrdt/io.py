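"""Plain-text I/O: CSV matrices with JSON sidecars, long tables, codebooks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blinks import BlinkSeries, EEGRecording


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> None:
    """Samples x channels CSV (header = labels) + ``<path>.json`` sidecar with fs."""
    path = Path(path)
    pd.DataFrame(recording.signal, columns=recording.channel_labels).to_csv(
        path, index=False)
    sidecar = {"fs": recording.fs, "channel_labels": recording.channel_labels}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_eeg_csv(path: str | Path, fs: float | None = None) -> EEGRecording:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    sidecar = Path(str(path) + ".json")
    labels = list(df.columns)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = fs or meta.get("fs")
        labels = meta.get("channel_labels", labels)
    if fs is None:
        raise ValueError(f"no sampling rate: pass fs or provide {sidecar}")
    return EEGRecording(df.to_numpy(dtype=float), float(fs), labels)


def read_eeg_edf(path: str | Path) -> EEGRecording:
    """Optional EDF reader (requires mne)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF support requires mne") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data().T, float(raw.info["sfreq"]),
                        list(raw.ch_names))


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> None:
    """BED-like 3-column onset/peak/offset sample table (TSV)."""
    gt[["onset", "peak", "offset"]].to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_blinks(series: BlinkSeries, table_path: str | Path,
                 summary_path: str | Path | None = None,
                 fs: float = 1.0) -> None:
    """Accepted blinks as (onset_s, peak_s, offset_s, tent_r, pavr) + JSON summary."""
    rows = [(b.onset / fs, b.peak / fs, b.offset / fs, b.tent_r, b.pavr)
            for b in series.blinks]
    pd.DataFrame(rows, columns=["onset_s", "peak_s", "offset_s",
                                "tent_r", "pavr"]).to_csv(table_path, index=False)
    if summary_path is not None:
        summary = {"best_channel": series.best_channel,
                   "n_blinks": series.count,
                   "rate_per_min": series.rate}
        Path(summary_path).write_text(json.dumps(summary, indent=2))


def write_codebook(codebook: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(codebook, indent=2))


def read_codebook(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())


def read_stop_phrases(path: str | Path) -> tuple[str, ...]:
    lines = Path(path).read_text().splitlines()
    return tuple(s.strip() for s in lines if s.strip() and not s.startswith("#"))
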