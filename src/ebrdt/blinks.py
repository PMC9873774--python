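"""Spontaneous eye-blink rate (sEBR) extraction from resting frontal EEG.

Blinks produce large, slow, tent-shaped deflections on frontal channels.
The detector band-limits the signal to 1-20 Hz, finds excursions above
mean + 1.5 SD that last longer than 50 ms, and keeps only events whose
waveform correlates > 0.90 with a two-piece linear (tent) template and
whose positive amplitude-velocity ratio (pAVR) is at least 3 — saccades
are fast relative to their size and fall below that ratio.  The blink
rate is taken from the single channel on which the most events survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

#: Frontal channels that usually carry the clearest blink signal.
FRONTAL_CHANNELS = ("Fpz", "Fz", "Fp1", "Fp2", "F3", "F4", "FC3", "FC4")

#: Relative blink amplitude by distance from the eyes (unknown labels get 0.3).
FRONTAL_GRADIENT = {
    "Fpz": 1.0, "Fp1": 0.95, "Fp2": 0.95,
    "Fz": 0.75, "F3": 0.60, "F4": 0.60,
    "FC3": 0.45, "FC4": 0.45,
}

MIN_EVENT_S = 0.050     # events must last longer than this
MIN_GAP_S = 0.050       # inter-blink interval floor


@dataclass
class EEGRecording:
    """Multichannel EEG: ``signal`` is samples x channels."""

    signal: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D samples x channels array")
        if len(self.channel_labels) != self.signal.shape[1]:
            raise ValueError("channel_labels must match the number of columns")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.signal[:, self.channel_labels.index(label)]


@dataclass
class BlinkCandidate:
    """One supra-threshold excursion, before or after quality scoring."""

    onset: int
    peak: int
    offset: int
    amplitude: float
    channel: str = ""
    tent_r: float = float("nan")
    pavr: float = float("nan")
    rejected: bool = False

    @property
    def n_samples(self) -> int:
        return self.offset - self.onset + 1

    def duration(self, fs: float) -> float:
        return (self.offset - self.onset) / fs


@dataclass
class BlinkSeries:
    """Accepted blinks on the best channel and the per-minute rate."""

    blinks: list[BlinkCandidate]
    best_channel: str
    rate: float
    duration: float
    n_candidates: int = 0

    @property
    def count(self) -> int:
        return len(self.blinks)


def bandpass(recording: EEGRecording, low: float = 1.0, high: float = 20.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order and removes phase distortion, so blink peak times are preserved.
    """
    nyq = recording.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="band", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=0)
    return EEGRecording(filtered, recording.fs, list(recording.channel_labels))


def find_candidates(channel_signal: np.ndarray, fs: float) -> list[BlinkCandidate]:
    """Maximal runs above mean + 1.5 SD lasting > 50 ms.

    Runs separated by less than 50 ms are pruned, keeping the larger
    peak, so the inter-blink-interval rule holds by construction.
    A constant signal (SD = 0) yields no candidates.
    """
    x = np.asarray(channel_signal, dtype=float)
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return []
    above = x > mu + 1.5 * sd
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    cands: list[BlinkCandidate] = []
    for s, e in zip(starts, ends):
        if (e - s) / fs <= MIN_EVENT_S:
            continue
        peak = s + int(np.argmax(x[s:e]))
        cands.append(BlinkCandidate(onset=int(s), peak=int(peak), offset=int(e - 1),
                                    amplitude=float(x[peak] - mu)))
    # enforce >= 50 ms separation: keep the larger of any too-close pair
    pruned: list[BlinkCandidate] = []
    for c in cands:
        if pruned and (c.onset - pruned[-1].offset) / fs < MIN_GAP_S:
            if c.amplitude > pruned[-1].amplitude:
                pruned[-1] = c
            continue
        pruned.append(c)
    return pruned


def _tent_template(seg: np.ndarray, apex: int) -> np.ndarray:
    """Two-piece linear template through the segment's endpoints and apex."""
    n = seg.size
    tent = np.empty(n)
    tent[: apex + 1] = np.linspace(seg[0], seg[apex], apex + 1)
    tent[apex:] = np.linspace(seg[apex], seg[-1], n - apex)
    return tent


def score_candidate(candidate: BlinkCandidate, channel_signal: np.ndarray,
                    fs: float) -> BlinkCandidate:
    """Fill ``tent_r`` and ``pavr`` for a candidate.

    tent_r is the Pearson correlation between the excursion and the tent
    anchored at its onset, peak and offset.  pAVR is 100 x (peak amplitude
    above the local baseline) / (rising-limb velocity in units/s); the
    velocity is a least-squares slope over the 20-95 % portion of the rise,
    which is noise-robust and exact for piecewise-linear events.
    """
    x = np.asarray(channel_signal, dtype=float)
    on, pk, off = candidate.onset, candidate.peak, candidate.offset
    seg = x[on:off + 1]
    if seg.size < 3:
        return replace(candidate, rejected=True)

    flank = max(1, int(round(0.100 * fs)))
    pre = x[max(0, on - flank):on]
    post = x[off + 1:off + 1 + flank]
    baseline_parts = [p.mean() for p in (pre, post) if p.size]
    baseline = float(np.mean(baseline_parts)) if baseline_parts else float(seg[0])
    amp = float(x[pk] - baseline)
    if amp <= 0:
        return replace(candidate, rejected=True)

    tent = _tent_template(seg, pk - on)
    if np.ptp(seg) == 0 or np.ptp(tent) == 0:
        tent_r = float("nan")
    else:
        tent_r = float(np.corrcoef(seg, tent)[0, 1])

    # rising limb: walk back from the peak to where the signal last sat
    # near baseline (10 % of amplitude), at most 100 ms before onset
    lo = max(0, on - flank)
    rise = x[lo:pk + 1]
    below = np.flatnonzero(rise - baseline <= 0.10 * amp)
    r0 = lo + (below[-1] if below.size else 0)
    limb = x[r0:pk + 1]
    rel = (limb - baseline) / amp
    sel = np.flatnonzero((rel >= 0.20) & (rel <= 0.95))
    if sel.size >= 3:
        t = sel / fs
        vel = float(np.polyfit(t, limb[sel], 1)[0])
    elif pk > r0:
        vel = amp / ((pk - r0) / fs)
    else:
        vel = float("inf")
    pavr = 100.0 * amp / vel if vel > 0 else 0.0
    return replace(candidate, amplitude=amp, tent_r=tent_r, pavr=float(pavr))


def detect_blinks(recording: EEGRecording, low: float = 1.0, high: float = 20.0,
                  tent_r_min: float = 0.90, pavr_min: float = 3.0) -> BlinkSeries:
    """Band-pass, threshold, score and select the best channel.

    Acceptance requires tent_r > ``tent_r_min`` and pAVR >= ``pavr_min``
    (low pAVR marks saccades).  The best channel is the one with the most
    accepted blinks; ties go to the higher median tent_r.  The reported
    rate is 60 x count / duration on that channel alone.
    """
    present = [c for c in recording.channel_labels
               if c.upper() in {f.upper() for f in FRONTAL_CHANNELS}]
    if not present:
        raise ValueError(
            "no frontal channel found; expected one of "
            + ", ".join(FRONTAL_CHANNELS)
        )
    filt = bandpass(recording, low, high)
    per_channel: dict[str, list[BlinkCandidate]] = {}
    n_cands = 0
    for label in present:
        x = filt.channel(label)
        cands = find_candidates(x, filt.fs)
        n_cands += len(cands)
        scored = [score_candidate(c, x, filt.fs) for c in cands]
        accepted = [replace(c, channel=label) for c in scored
                    if not c.rejected
                    and np.isfinite(c.tent_r) and c.tent_r > tent_r_min
                    and np.isfinite(c.pavr) and c.pavr >= pavr_min]
        per_channel[label] = accepted

    def key(label: str):
        acc = per_channel[label]
        med = float(np.median([c.tent_r for c in acc])) if acc else -np.inf
        return (len(acc), med)

    best = max(present, key=key)
    blinks = per_channel[best]
    rate = blink_rate(len(blinks), recording.duration)
    return BlinkSeries(blinks=blinks, best_channel=best, rate=rate,
                       duration=recording.duration, n_candidates=n_cands)


def blink_rate(count: int, duration: float) -> float:
    """Blinks per minute: 60 * count / duration_seconds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * count / duration
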