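"""Synthetic session generator: determinism, spectra, planted ground truth."""

import numpy as np
import pytest

from srk.mapping import ANALYSIS_BANDS
from srk.preprocess import epoch_signal
from srk.simulate import (
    BehaviourParams,
    SimulationConfig,
    simulate_behavior,
    simulate_condition_eeg,
    simulate_rest_eeg,
)


class TestRest:
    def test_spectral_peak_at_planted_iaf(self):
        from srk.spectral import compute_psd

        rest = simulate_rest_eeg(SimulationConfig(seed=1, iaf_true=10.5))
        spec = compute_psd(epoch_signal(rest))
        mean = spec.psd.mean(axis=(0, 1))
        sel = (spec.freqs >= 7) & (spec.freqs <= 13)
        assert spec.freqs[sel][np.argmax(mean[sel])] in (10.0, 11.0)

    def test_noise_free_limit_is_pure_line(self):
        from srk.spectral import compute_psd

        rest = simulate_rest_eeg(SimulationConfig(seed=1, iaf_true=10.0,
                                                  noise_level=0.0))
        spec = compute_psd(epoch_signal(rest))
        psd = spec.psd.mean(axis=(0, 1))
        # the Hann window spreads a pure line over exactly +-1 bin
        line = psd[np.abs(spec.freqs - 10.0) <= 1.0].sum()
        assert line / psd.sum() > 0.999

    def test_same_seed_identical_samples(self):
        a = simulate_rest_eeg(SimulationConfig(seed=9))
        b = simulate_rest_eeg(SimulationConfig(seed=9))
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_duration_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.durations["rest"] = 0.0
        with pytest.raises(ValueError):
            simulate_rest_eeg(cfg)


class TestConditionEEG:
    def test_determinism_of_full_session(self, effect_session):
        from srk.simulate import simulate_session

        again = simulate_session(SimulationConfig(
            seed=101, effect_map=dict(effect_session.config.effect_map)))
        for seg, rec in effect_session.recordings.items():
            assert np.array_equal(rec.samples, again.recordings[seg].samples)

    def test_unknown_condition_rejected(self, effect_session):
        with pytest.raises(ValueError):
            simulate_condition_eeg(effect_session.config, "Z9",
                                   effect_session.leadfield,
                                   effect_session.atlas)

    def test_unknown_ba_rejected(self, effect_session):
        cfg = SimulationConfig(seed=0, effect_map={("K1", "BA99-L", "Gamma"): 1.0})
        with pytest.raises(ValueError, match="BA99"):
            simulate_condition_eeg(cfg, "K1", effect_session.leadfield,
                                   effect_session.atlas)

    def test_empty_effect_map_matches_ref_statistically(self, null_session):
        """With nothing planted, condition vs REF rejects on about alpha of cells."""
        from scipy import stats

        from srk.simulate import _MeasurementPath

        path = _MeasurementPath(null_session.config, null_session.leadfield,
                                null_session.atlas)
        f_ref = path.ba_features(null_session.recordings["REF"].samples)
        f_s1 = path.ba_features(null_session.recordings["S1"].samples)
        p = stats.ttest_ind(f_s1, f_ref, axis=0).pvalue.ravel()
        frac = float((p <= 0.05).mean())
        assert frac < 0.12       # near the 5% floor, never wildly above

    def test_planted_z_recovered_at_ba_level(self, effect_session):
        """Calibrated Knowledge effects read back at 1.5 +- 0.25 z."""
        from srk.simulate import _MeasurementPath

        sess = effect_session
        path = _MeasurementPath(sess.config, sess.leadfield, sess.atlas)
        f_ref = path.ba_features(sess.recordings["REF"].samples)
        mu, sd = f_ref.mean(0), f_ref.std(0, ddof=1)
        for (cond, ba, band), z_target in sess.config.effect_map.items():
            f = path.ba_features(sess.recordings[cond].samples)
            z = (f.mean(0) - mu) / sd
            got = z[sess.atlas.labels.index(ba), ANALYSIS_BANDS.index(band)]
            assert got == pytest.approx(z_target, abs=0.25)

    def test_planted_parcel_effect_visible_at_nearby_electrodes(self):
        """A channel-calibrated parcel effect lifts band z at its peak electrode."""
        from srk.pipeline import RunConfig, classification_features
        from srk.simulate import simulate_session

        effects = {(c, "BA10-L", "Gamma"): 1.5 for c in ("K1", "K2")}
        sess = simulate_session(SimulationConfig(seed=55, effect_map=effects,
                                                 effect_space="channel"))
        p1, _ = classification_features(sess, RunConfig(seed=55))
        dz = p1.X[p1.y == "K"].mean(0) - p1.X[p1.y == "SR"].mean(0)
        # strongest gamma feature shift should clearly exceed 1 z-unit
        gamma_idx = [i for i in range(366) if i % 6 == ANALYSIS_BANDS.index("Gamma")]
        assert dz[gamma_idx].max() > 1.0

    def test_state_map_shifts_every_channel(self):
        """A global state shift moves each channel's band feature by ~z."""
        from srk.simulate import _ChannelPath, knowledge_state_map, simulate_session

        cfg = SimulationConfig(seed=66, state_map=knowledge_state_map(1.5))
        sess = simulate_session(cfg)
        cp = _ChannelPath(cfg)
        ref = cp.features(sess.recordings["REF"].samples)
        mu, sd = ref.mean(0), ref.std(0, ddof=1)
        z = (cp.features(sess.recordings["K1"].samples).mean(0) - mu) / sd
        for band in ("Theta", "Beta3", "Gamma"):
            zb = z[:, ANALYSIS_BANDS.index(band)]
            assert np.abs(zb - 1.5).max() < 0.25
        # untargeted bands stay near the null
        alpha = z[:, ANALYSIS_BANDS.index("AlphaHigh")]
        assert np.abs(np.median(alpha)) < 0.5

    def test_gross_artifacts_planted_and_recoverable(self):
        from srk.preprocess import reject_artifacts

        cfg = SimulationConfig(seed=13, gross_artifact_rate=2.0, blink_rate=0.0)
        cfg.durations["K1"] = 120.0
        rec, truth = simulate_condition_eeg(cfg, "K1", *_lf_atlas(cfg))
        assert len(truth["gross_onsets"]) >= 1
        ep = reject_artifacts(epoch_signal(rec))
        flagged = set(np.flatnonzero(ep.artifact_mask))
        assert set(truth["gross_epochs"]) <= flagged

    def test_blink_events_recorded_in_truth(self):
        cfg = SimulationConfig(seed=14, blink_rate=6.0)
        rec, truth = simulate_condition_eeg(cfg, "S1", *_lf_atlas(cfg))
        assert len(truth["blink_onsets"]) >= 2
        assert rec.eog is not None
        # blinks dominate the EOG trace
        assert np.abs(rec.eog).max() > 100.0


def _lf_atlas(cfg):
    from srk.inverse import build_leadfield
    from srk.mapping import make_atlas
    from srk.montage import make_montage

    m = make_montage()
    lf = build_leadfield(m.positions, m.labels, n_sources=660, seed=cfg.seed)
    return lf, make_atlas(lf.source_positions)


class TestBehaviourLogs:
    def test_zero_jitter_perfect_tracking(self):
        from srk.behavior import track_geometry

        cfg = SimulationConfig(seed=0, behaviour=BehaviourParams(tracking_jitter=0.0))
        log = simulate_behavior(cfg, "S1")
        L, l_opt, err, err_max = track_geometry(log)
        assert L == pytest.approx(l_opt, rel=1e-9)
        assert err == pytest.approx(0.0, abs=1e-9)

    def test_certain_rule_success(self):
        cfg = SimulationConfig(seed=0, behaviour=BehaviourParams(rule_success_p=1.0))
        log = simulate_behavior(cfg, "R2")
        assert sum(log.turn_outcomes) + sum(log.alt_outcomes) == 14

    def test_perfect_knowledge2(self):
        from srk.behavior import knowledge2_accuracy

        cfg = SimulationConfig(seed=0, behaviour=BehaviourParams(k2_n_att=1,
                                                                 k2_t_used=0.0))
        assert knowledge2_accuracy(simulate_behavior(cfg, "K2")) == 100.0

    def test_rule_log_has_7_plus_7_slots(self):
        log = simulate_behavior(SimulationConfig(seed=3), "R1")
        assert len(log.turn_outcomes) == 7 and len(log.alt_outcomes) == 7

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            simulate_behavior(SimulationConfig(seed=0), "REF")
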