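"""The generators: determinism, ground-truth conservation, recoverable structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from ebrdt import (EEGSimConfig, PopulationSimConfig, ResponseSimConfig,
                   compute_icc, score_flexibility_fluency,
                   simulate_aut_responses, simulate_eeg, simulate_participants)

from conftest import BLINK_TIMES_30


def _ols_quadratic(x, y):
    """Minimal independent quadratic fit: coefficients and the t-based
    two-sided p-value of the squared term."""
    X = np.column_stack([np.ones_like(x), x, x ** 2])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - 3
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    from scipy import stats
    t = beta[2] / np.sqrt(cov[2, 2])
    return beta, 2 * stats.t.sf(abs(t), dof)


class TestEEG:
    def test_seed_determinism(self):
        cfg = EEGSimConfig(blink_times=[5.0, 10.0], seed=3)
        r1, g1 = simulate_eeg(cfg)
        r2, g2 = simulate_eeg(cfg)
        assert np.array_equal(r1.signal, r2.signal)
        assert g1.equals(g2)

    def test_noiseless_peaks_at_blink_times(self, clean_recording):
        rec, gt, cfg = clean_recording
        x = rec.channel("Fpz")
        peaks, _ = sps.find_peaks(x, height=50.0)
        assert len(peaks) == 30
        assert np.allclose(peaks / cfg.fs, BLINK_TIMES_30, atol=1.0 / cfg.fs)

    def test_empty_blinks_noiseless_is_flat(self):
        rec, gt = simulate_eeg(EEGSimConfig(noise_sd=0.0))
        assert np.all(rec.signal == 0.0)
        assert gt.empty

    def test_ground_truth_conserves_blink_count(self, noisy_recording):
        _, gt, cfg = noisy_recording
        assert len(gt) == len(cfg.blink_times)
        assert (gt["onset"] < gt["peak"]).all()
        assert (gt["peak"] < gt["offset"]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_eeg(EEGSimConfig(blink_times=[5.0, 5.1]))
        with pytest.raises(ValueError, match="fs"):
            simulate_eeg(EEGSimConfig(fs=50.0))
        with pytest.raises(ValueError, match="within"):
            simulate_eeg(EEGSimConfig(blink_times=[500.0]))


class TestParticipants:
    def test_noiseless_refit_recovers_paths_exactly(self):
        cfg = PopulationSimConfig(n_participants=100, sigma_m=0.0, sigma_y=0.0,
                                  seed=1)
        df = simulate_participants(cfg)
        x, m = df["sebr"].to_numpy(), df["flexibility"].to_numpy()
        beta, _ = _ols_quadratic(x, m)
        assert np.allclose(beta, [cfg.i_m, cfg.a1, cfg.a2], atol=1e-8)
        # with zero residuals Y is an exact function of (X, M)
        y_pred = cfg.i_y + cfg.c1 * x + cfg.c2 * x ** 2 + cfg.b * m
        assert np.allclose(df["originality"], y_pred, atol=1e-10)

    def test_large_sample_recovery_within_3_se(self):
        cfg = PopulationSimConfig(n_participants=10000, a1=0.08, a2=-0.004,
                                  b=1.5, sigma_m=0.3, sigma_y=0.3, seed=1)
        df = simulate_participants(cfg)
        import statsmodels.api as sm
        x = df["sebr"].to_numpy()
        Xm = sm.add_constant(np.column_stack([x, x ** 2]))
        fm = sm.OLS(df["flexibility"].to_numpy(), Xm).fit()
        assert abs(fm.params[1] - cfg.a1) < 3 * fm.bse[1]
        assert abs(fm.params[2] - cfg.a2) < 3 * fm.bse[2]
        Xy = sm.add_constant(np.column_stack([df["flexibility"], x, x ** 2]))
        fy = sm.OLS(df["originality"].to_numpy(), Xy).fit()
        assert abs(fy.params[1] - cfg.b) < 3 * fy.bse[1]

    def test_inverted_u_hides_linear_correlation(self):
        # predictor centred on the vertex: linear r ~ 0 but strong quadratic fit
        cfg = PopulationSimConfig(n_participants=4000, a1=0.24, a2=-0.012,
                                  ebr_mean=10.0, ebr_sd=3.0, sigma_m=0.2,
                                  seed=5)
        assert abs(-cfg.a1 / (2 * cfg.a2) - cfg.ebr_mean) < 1e-9
        df = simulate_participants(cfg)
        x, m = df["sebr"].to_numpy(), df["flexibility"].to_numpy()
        r = np.corrcoef(x, m)[0, 1]
        beta, _ = _ols_quadratic(x, m)
        fitted = beta[0] + beta[1] * x + beta[2] * x ** 2
        r2 = 1 - np.sum((m - fitted) ** 2) / np.sum((m - m.mean()) ** 2)
        assert abs(r) < 0.1
        assert r2 > 0.3

    def test_truncation_and_validation(self):
        df = simulate_participants(PopulationSimConfig(ebr_mean=1.0, ebr_sd=3.0,
                                                       seed=2))
        assert (df["sebr"] > 0).all()
        with pytest.raises(ValueError):
            simulate_participants(PopulationSimConfig(n_participants=3))

    def test_quadratic_term_detection_rates(self):
        """a2 != 0 is detected nearly always at n=1000; a2 = 0 at ~alpha."""
        hits = sum(
            _ols_quadratic(*simulate_participants(
                PopulationSimConfig(n_participants=1000, seed=s)
            )[["sebr", "flexibility"]].to_numpy().T)[1] < 0.05
            for s in range(200))
        assert hits / 200 >= 0.95
        null_hits = sum(
            _ols_quadratic(*simulate_participants(
                PopulationSimConfig(n_participants=1000, a2=0.0, seed=1000 + s)
            )[["sebr", "flexibility"]].to_numpy().T)[1] < 0.05
            for s in range(500))
        assert abs(null_hits / 500 - 0.05) <= 0.03


class TestResponses:
    def test_seed_determinism(self, participants):
        a = simulate_aut_responses(participants, ResponseSimConfig(seed=9))
        b = simulate_aut_responses(participants, ResponseSimConfig(seed=9))
        assert a.equals(b)

    def test_zero_rater_noise_gives_perfect_icc(self, participants):
        resp = simulate_aut_responses(
            participants, ResponseSimConfig(rater_noise_sd=0.0, seed=4))
        icc = compute_icc(resp[["rater1_score", "rater2_score"]].to_numpy())
        assert icc.icc == pytest.approx(1.0, abs=1e-9)

    def test_single_category_codebook_forces_flexibility_one(self, participants):
        cb = {f"obj{k}": ["only"] for k in range(5)}
        resp = simulate_aut_responses(
            participants, ResponseSimConfig(category_codebook=cb, seed=4))
        ff = score_flexibility_fluency(resp)
        assert (ff["flexibility"] == 1.0).all()

    def test_categories_come_from_codebook(self, responses):
        cfg = ResponseSimConfig()
        for obj, sub in responses.groupby("object_id"):
            assert set(sub["category_label"]) <= set(cfg.category_codebook[obj])

    def test_scores_clipped_to_scale(self, responses):
        for col in ("rater1_score", "rater2_score"):
            assert responses[col].between(1.0, 5.0).all()

    def test_empty_codebook_rejected(self, participants):
        with pytest.raises(ValueError, match="empty"):
            simulate_aut_responses(participants, ResponseSimConfig(
                category_codebook={"obj": []}, n_objects=1))
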