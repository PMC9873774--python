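"""Synthetic study data with known ground truth.

Three generators mirror the three data layers of the analysis:

* ``simulate_eeg`` — frontal-channel EEG with additive tent-shaped blink
  waveforms, step-like saccade surrogates and white noise, plus an exact
  sample-level blink ground truth;
* ``simulate_participants`` — per-participant sEBR (X), flexibility (M)
  and originality (Y) following the mediation model the analysis assumes:
  an inverted-U X->M path, a linear M->Y path and a weaker quadratic
  direct X->Y path;
* ``simulate_aut_responses`` — a long-format Alternative Uses Task table
  whose realised category diversity tracks latent flexibility and whose
  two rater scores are calibrated to a target inter-rater ICC.

Every generator is fully determined by its config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blinks import EEGRecording, FRONTAL_CHANNELS, FRONTAL_GRADIENT

# --------------------------------------------------------------------------
# EEG layer
# --------------------------------------------------------------------------

SACCADE_RAMP_S = 0.020      # rise/fall of the saccade surrogate
SACCADE_PLATEAU_S = 0.150   # hold at plateau
SACCADE_REL_AMP = 0.4       # relative to blink amplitude


@dataclass
class EEGSimConfig:
    """Resting-state EEG segment with implanted blinks and saccades.

    Amplitudes are in the recording's native units (think microvolts);
    the default 3-minute duration matches an eyes-open resting segment.
    """

    blink_times: list[float] = field(default_factory=list)
    saccade_times: list[float] = field(default_factory=list)
    fs: float = 256.0
    duration: float = 180.0
    n_channels: int = 8
    channel_labels: list[str] = field(default_factory=lambda: list(FRONTAL_CHANNELS))
    blink_amplitude: float = 100.0
    rise_ms: float = 120.0
    fall_ms: float = 180.0
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 100:
            raise ValueError("fs < 100 Hz cannot represent 50 ms events")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        bt = np.sort(np.asarray(self.blink_times, dtype=float))
        if bt.size and (bt[0] < 0 or bt[-1] > self.duration):
            raise ValueError("blink_times must lie within [0, duration]")
        min_sep = 0.050 + (self.rise_ms + self.fall_ms) / 1000.0
        if bt.size > 1 and np.min(np.diff(bt)) <= min_sep:
            raise ValueError(
                f"blink_times closer than {min_sep:.3f} s would overlap")


def _add_tent(col: np.ndarray, peak: int, rise_n: int, fall_n: int,
              amp: float) -> tuple[int, int]:
    """Add a piecewise-linear tent peaking at ``peak``; returns (onset, offset)."""
    n = col.size
    on, off = peak - rise_n, peak + fall_n
    up = np.linspace(0.0, amp, rise_n + 1)
    down = np.linspace(amp, 0.0, fall_n + 1)
    shape = np.concatenate([up, down[1:]])
    lo, hi = max(on, 0), min(off, n - 1)
    col[lo:hi + 1] += shape[lo - on:hi - on + 1]
    return max(on, 0), min(off, n - 1)


def simulate_eeg(config: EEGSimConfig) -> tuple[EEGRecording, pd.DataFrame]:
    """Build the recording and its blink ground truth.

    Blinks are tents (linear rise over ``rise_ms`` to ``blink_amplitude``,
    linear fall over ``fall_ms``) centred on each ``blink_times`` entry and
    scaled per channel by a frontal gradient.  Saccade surrogates are
    trapezoids with 20 ms ramps — high velocity relative to amplitude —
    so the pAVR criterion has something to reject.  Ground truth gives
    exact onset/peak/offset sample indices per blink.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    sig = np.zeros((n, config.n_channels))
    gains = np.array([FRONTAL_GRADIENT.get(lbl, 0.3) for lbl in config.channel_labels])

    rise_n = max(1, int(round(config.rise_ms / 1000.0 * config.fs)))
    fall_n = max(1, int(round(config.fall_ms / 1000.0 * config.fs)))

    truth = []
    for t in sorted(config.blink_times):
        peak = int(round(t * config.fs))
        peak = min(max(peak, 0), n - 1)
        for j, g in enumerate(gains):
            on, off = _add_tent(sig[:, j], peak, rise_n, fall_n,
                                config.blink_amplitude * g)
        truth.append((on, peak, off))

    ramp_n = max(1, int(round(SACCADE_RAMP_S * config.fs)))
    plat_n = int(round(SACCADE_PLATEAU_S * config.fs))
    amp_s = SACCADE_REL_AMP * config.blink_amplitude
    shape = np.concatenate([
        np.linspace(0.0, amp_s, ramp_n + 1),
        np.full(plat_n, amp_s),
        np.linspace(amp_s, 0.0, ramp_n + 1)[1:],
    ])
    for t in sorted(config.saccade_times):
        s0 = int(round(t * config.fs))
        lo, hi = max(s0, 0), min(s0 + shape.size, n)
        sig[lo:hi] += shape[:hi - lo, None] * gains[None, :]

    if config.noise_sd > 0:
        sig = sig + rng.normal(0.0, config.noise_sd, size=sig.shape)

    rec = EEGRecording(sig, config.fs, list(config.channel_labels))
    gt = pd.DataFrame(truth, columns=["onset", "peak", "offset"], dtype=int)
    return rec, gt


def draw_blink_times(rate_per_min: float, duration: float, rng: np.random.Generator,
                     min_gap: float = 0.6) -> list[float]:
    """Poisson-like blink times with a refractory gap between events."""
    n_target = rng.poisson(rate_per_min * duration / 60.0)
    times: list[float] = []
    for _ in range(20 * max(n_target, 1)):
        if len(times) >= n_target:
            break
        t = rng.uniform(min_gap, duration - min_gap)
        if all(abs(t - u) > min_gap for u in times):
            times.append(t)
    return sorted(times)


# --------------------------------------------------------------------------
# Participant layer (mediation structure)
# --------------------------------------------------------------------------

@dataclass
class PopulationSimConfig:
    """Ground-truth mediation model X -> M -> Y with quadratic X paths.

    X is sEBR (blinks/min, truncated normal above ``ebr_floor``);
    M = i_M + a1 X + a2 X^2 + e_M is latent flexibility;
    Y = i_Y + c1 X + c2 X^2 + b M + e_Y is latent originality.

    Defaults put the inverted-U vertex of the X->M path near 16.8
    blinks/min, i.e. the instantaneous indirect effect (a1 + 2 a2 x) b is
    positive at low/moderate sEBR and vanishes at high sEBR, and the sEBR
    mean/SD (10.76 / 6.05) make mean +/- 1 SD fall at 4.71, 10.76, 16.81.
    """

    n_participants: int = 73
    ebr_mean: float = 10.76
    ebr_sd: float = 6.05
    ebr_floor: float = 0.5
    a1: float = 0.134
    a2: float = -0.004
    b: float = 0.4
    c1: float = 0.05
    c2: float = -0.0015
    i_m: float = 2.0
    i_y: float = 1.8
    sigma_m: float = 0.6
    sigma_y: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        if self.sigma_m < 0 or self.sigma_y < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.ebr_sd <= 0:
            raise ValueError("ebr_sd must be positive")


def simulate_participants(config: PopulationSimConfig) -> pd.DataFrame:
    """Draw (sebr, flexibility, originality) per participant.

    The returned flexibility/originality columns are the latent scores of
    the structural model; ``simulate_aut_responses`` turns them into an
    observable response table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a = (config.ebr_floor - config.ebr_mean) / config.ebr_sd
    x = stats.truncnorm.rvs(a, np.inf, loc=config.ebr_mean, scale=config.ebr_sd,
                            size=config.n_participants, random_state=rng)
    m = (config.i_m + config.a1 * x + config.a2 * x ** 2
         + rng.normal(0.0, config.sigma_m, x.size))
    y = (config.i_y + config.c1 * x + config.c2 * x ** 2 + config.b * m
         + rng.normal(0.0, config.sigma_y, x.size))
    return pd.DataFrame({
        "participant_id": [f"P{i + 1:03d}" for i in range(x.size)],
        "sebr": x,
        "flexibility": m,
        "originality": y,
    })


# --------------------------------------------------------------------------
# Response layer (AUT table)
# --------------------------------------------------------------------------

DEFAULT_OBJECTS = ("brick", "hat", "hammer", "newspaper", "shoe")

DEFAULT_CODEBOOK = {
    obj: [f"{obj}_cat{k}" for k in range(1, 9)] for obj in DEFAULT_OBJECTS
}


@dataclass
class ResponseSimConfig:
    """Observable AUT responses for simulated participants.

    ``target_icc`` calibrates rater noise from the two-way-random
    average-measures closed form  ICC(2,k) = s_q^2 / (s_q^2 + s_e^2 / k):
    with k = 2 raters, s_e = s_q * sqrt(2 (1 - ICC) / ICC), where s_q is
    the realised between-idea quality SD of the generated sample.  An
    explicit ``rater_noise_sd`` overrides the calibration.
    """

    n_objects: int = 5
    category_codebook: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CODEBOOK.items()})
    mean_responses_per_object: float = 4.6
    idea_noise_sd: float = 0.5
    rater_noise_sd: float | None = None
    target_icc: float = 0.88
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.target_icc <= 1:
            raise ValueError("target_icc must be in (0, 1]")
        if len(self.category_codebook) < self.n_objects:
            raise ValueError("codebook must cover n_objects objects")
        for obj, cats in self.category_codebook.items():
            if not cats:
                raise ValueError(f"empty category codebook for object {obj!r}")

    def resolved_rater_noise_sd(self, quality_sd: float) -> float:
        if self.rater_noise_sd is not None:
            return self.rater_noise_sd
        t = self.target_icc
        return quality_sd * np.sqrt(2.0 * (1.0 - t) / t)


def simulate_aut_responses(participants: pd.DataFrame,
                           config: ResponseSimConfig) -> pd.DataFrame:
    """Long-format AUT table: one row per idea with category and 2 ratings.

    Per object, a participant produces a Poisson number of responses whose
    mean is a participant-level fluency propensity; the number of distinct
    categories used tracks latent flexibility; response text frequencies
    follow a Zipf-like draw within category so frequency-based originality
    varies.  Idea quality is the participant's latent originality plus
    idea noise; each rater adds independent noise and scores are clipped
    to [1, 5].
    """
    if participants.empty:
        raise ValueError("participants table is empty")
    config.validate()
    rng = np.random.default_rng(config.seed)
    objects = list(config.category_codebook)[:config.n_objects]

    rows = []
    qualities = []
    for row in participants.itertuples(index=False):
        propensity = max(1.0, rng.normal(config.mean_responses_per_object, 1.0))
        for obj in objects:
            cats = config.category_codebook[obj]
            n_resp = max(1, rng.poisson(propensity))
            k = int(np.clip(round(row.flexibility + rng.normal(0.0, 0.3)),
                            1, min(n_resp, len(cats))))
            used = rng.choice(len(cats), size=k, replace=False)
            for j in range(n_resp):
                cat = cats[used[j % k]]
                idea = min(int(rng.zipf(1.8)), 40)
                quality = row.originality + rng.normal(0.0, config.idea_noise_sd)
                qualities.append(quality)
                rows.append([row.participant_id, obj,
                             f"{cat} use {idea}", cat])

    q = np.asarray(qualities)
    sd_q = float(q.std(ddof=1)) if q.size > 1 else 1.0
    sd_e = config.resolved_rater_noise_sd(sd_q)
    r1 = np.clip(q + rng.normal(0.0, sd_e, q.size), 1.0, 5.0)
    r2 = np.clip(q + rng.normal(0.0, sd_e, q.size), 1.0, 5.0)

    out = pd.DataFrame(rows, columns=[
        "participant_id", "object_id", "raw_text", "category_label"])
    out["rater1_score"] = r1
    out["rater2_score"] = r2
    return out
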