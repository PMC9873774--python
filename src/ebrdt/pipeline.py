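"""End-to-end orchestration: simulate -> detect -> score -> analyze -> mediate.

``run_full_analysis`` executes the whole chain from a single config,
writes every intermediate table under the output directory and emits a
manifest with per-file SHA-256 hashes, so a rerun with the same config is
verifiably identical.  Per-stage seeds are derived deterministically from
the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aut import compute_icc, score_participants
from .blinks import detect_blinks
from .io import write_blinks, write_codebook, write_eeg_csv, write_ground_truth
from .mediation import MediationSpec, bootstrap_mediation
from .models import (PowerSpec, correlation_matrix, hierarchical_quadratic_fit,
                     required_sample_size, robust_quadratic_fit)
from .synthetic import (EEGSimConfig, PopulationSimConfig, ResponseSimConfig,
                        draw_blink_times, simulate_aut_responses,
                        simulate_eeg, simulate_participants)

log = logging.getLogger("ebrdt")

AUT_INDICES = ("flexibility", "rb_originality", "fb_originality", "fluency")


@dataclass
class RunConfig:
    """Single-file configuration for a full synthetic-study run."""

    seed: int = 0
    n_participants: int = 73
    eeg_fs: float = 256.0
    eeg_duration: float = 180.0
    eeg_noise_sd: float = 10.0
    n_saccades_per_min: float = 2.0
    population: dict = field(default_factory=dict)
    responses: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    write_eeg: bool = False     # per-participant EEG CSVs are large; opt-in
    codebook_path: str | None = None
    stop_phrases_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**(yaml.safe_load(Path(path).read_text()) or {}))
        cfg.check_paths()
        return cfg

    def check_paths(self) -> None:
        for p in (self.codebook_path, self.stop_phrases_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def _child_seeds(seed: int, k: int) -> list[int]:
    """k reproducible sub-seeds below 2**31."""
    return [int(s) % (2 ** 31) for s in
            np.random.SeedSequence(seed).generate_state(k, dtype=np.uint64)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage in order and return the manifest dict."""
    config.check_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    seeds = _child_seeds(config.seed, 5)
    stage = "init"
    try:
        # --- stage 1: participant ground truth -----------------------------
        stage = "simulate_participants"
        pop = PopulationSimConfig(n_participants=config.n_participants,
                                  seed=seeds[0], **config.population)
        participants = simulate_participants(pop)
        participants.to_csv(out / "participants_latent.csv", index=False)
        log.info("simulated %d participants", len(participants))

        # --- stage 2: EEG simulation + blink detection ---------------------
        stage = "detect_blinks"
        rng = np.random.default_rng(seeds[1])
        measured = []
        for row in participants.itertuples(index=False):
            blink_times = draw_blink_times(row.sebr, config.eeg_duration, rng)
            sacc = draw_blink_times(config.n_saccades_per_min,
                                    config.eeg_duration, rng)
            sim = EEGSimConfig(blink_times=blink_times, saccade_times=sacc,
                               fs=config.eeg_fs, duration=config.eeg_duration,
                               noise_sd=config.eeg_noise_sd,
                               seed=int(rng.integers(2 ** 31)))
            rec, gt = simulate_eeg(sim)
            series = detect_blinks(rec)
            if config.write_eeg:
                write_eeg_csv(rec, out / f"eeg_{row.participant_id}.csv")
                write_ground_truth(gt, out / f"gt_{row.participant_id}.tsv")
            measured.append((row.participant_id, series.rate,
                             series.best_channel, len(blink_times)))
        sebr = pd.DataFrame(measured, columns=[
            "participant_id", "sebr_measured", "best_channel", "n_blinks_true"])
        sebr.to_csv(out / "sebr_measured.csv", index=False)
        log.info("detected blinks for %d recordings", len(sebr))

        # --- stage 3: AUT responses + scoring ------------------------------
        stage = "score_aut"
        resp_cfg = ResponseSimConfig(seed=seeds[2], **config.responses)
        responses = simulate_aut_responses(participants, resp_cfg)
        responses.to_csv(out / "aut_responses.csv", index=False)
        write_codebook(resp_cfg.category_codebook, out / "codebook.json")
        scores = score_participants(
            responses,
            sebr=sebr.set_index("participant_id")["sebr_measured"])
        scores.to_csv(out / "participant_scores.csv")
        icc = compute_icc(responses[["rater1_score", "rater2_score"]].to_numpy())
        log.info("scored %d participants; ICC=%.3f", len(scores), icc.icc)

        # --- stage 4: correlations + hierarchical/robust regressions -------
        stage = "associations"
        corr = correlation_matrix(scores, list(AUT_INDICES))
        corr.r.to_csv(out / "correlations_r.csv")
        corr.p.to_csv(out / "correlations_p.csv")
        regressions = {}
        x = scores["sebr"].to_numpy()
        for index in AUT_INDICES:
            y = scores[index].to_numpy()
            regressions[index] = {
                "ols": hierarchical_quadratic_fit(x, y).to_dict(),
                "robust": robust_quadratic_fit(x, y).to_dict(),
            }
        power_n = required_sample_size(PowerSpec())
        analysis = {"icc": {"icc": icc.icc, "variant": icc.variant,
                            "n_items": icc.n_items},
                    "power_minimum_n": power_n,
                    "regressions": regressions}
        (out / "associations.json").write_text(json.dumps(analysis, indent=2))

        # --- stage 5: mediation --------------------------------------------
        stage = "mediation"
        med = {}
        for a_path in ("linear", "quadratic"):
            spec = MediationSpec(x_to_m=a_path, seed=seeds[3],
                                 **config.mediation)
            res = bootstrap_mediation(scores.reset_index(), spec,
                                      x="sebr", m="flexibility",
                                      y="rb_originality")
            med[f"a_path_{a_path}"] = res.to_dict()
        (out / "mediation.json").write_text(json.dumps(med, indent=2))
    except Exception as e:
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    log.removeHandler(handler)
    handler.close()
    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name not in ("manifest.json", "run.log"))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
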