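from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from imprintstat.densitometry import relative_amounts_from_od
from imprintstat.exceptions import ImprintstatError
from imprintstat.synthetic import (
    DensitometryConfig,
    ScenarioConfig,
    generate_densitometry,
    generate_experiment,
    scenario_presets,
)
from tests.conftest import frames_equal


class TestPresets:
    def test_paper_like_1h_design(self):
        cfg = scenario_presets("paper-like-1h")
        data = generate_experiment(cfg)
        assert cfg.n_batches == 10
        trained = [c for c in data.chicks if c.trained]
        untrained = [c for c in data.chicks if not c.trained]
        assert (len(trained), len(untrained)) == (21, 10)

    def test_paper_like_24h_design(self):
        cfg = scenario_presets("paper-like-24h")
        data = generate_experiment(cfg)
        assert cfg.n_batches == 9
        assert sum(c.trained for c in data.chicks) == 19
        assert data.timepoint == "h24"

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ImprintstatError, match="paper-like-1h"):
            scenario_presets("paper-like-3h")

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ImprintstatError, match="scenario"):
            scenario_presets("paper-like-1h", "osmosis")


class TestGenerateExperiment:
    def test_same_seed_is_bit_identical(self):
        cfg = scenario_presets("paper-like-1h", "learning", seed=42)
        a, b = generate_experiment(cfg), generate_experiment(cfg)
        assert frames_equal(a.behavior_frame(), b.behavior_frame())
        assert frames_equal(a.measurement_frame(), b.measurement_frame())

    def test_different_seed_differs(self):
        a = generate_experiment(scenario_presets("paper-like-1h", "learning", seed=1))
        b = generate_experiment(scenario_presets("paper-like-1h", "learning", seed=2))
        assert not frames_equal(a.measurement_frame(), b.measurement_frame())

    def test_noiseless_learning_lies_exactly_on_line(self):
        cfg = replace(
            scenario_presets("paper-like-1h", "learning", seed=0),
            batch_sd=0.0, residual_sd=0.0,
        )
        data = generate_experiment(cfg)
        scores = {c.chick_id: c.preference_score for c in data.chicks}
        for m in data.measurements:
            s = scores[m.chick_id]
            if s is None:  # untrained: exactly baseline
                assert m.relative_amount == pytest.approx(1.0, abs=1e-12)
            else:
                assert m.relative_amount == pytest.approx(
                    1.0 + 0.005 * (s - 50.0), abs=1e-12
                )

    def test_out_of_scenario_effects_forced_to_zero(self):
        # a learning-slope setting must not leak into the null scenario
        cfg = replace(scenario_presets("paper-like-1h", "null", seed=0),
                      learning_slope=0.5, batch_sd=0.0, residual_sd=0.0)
        data = generate_experiment(cfg)
        amounts = {m.relative_amount for m in data.measurements}
        assert amounts == {1.0}

    def test_predisposition_trained_untrained_exchangeable(self):
        """Training never touches the protein in the predisposition scenario:
        pooled over seeds, trained and untrained amounts agree in mean."""
        tr, un = [], []
        for seed in range(100):
            data = generate_experiment(
                scenario_presets("paper-like-1h", "predisposition", seed=seed)
            )
            trained_ids = {c.chick_id for c in data.chicks if c.trained}
            for m in data.measurements:
                (tr if m.chick_id in trained_ids else un).append(m.relative_amount)
        assert np.mean(tr) == pytest.approx(np.mean(un), abs=0.01)
        assert np.std(tr) == pytest.approx(np.std(un), rel=0.1)

    def test_predisposition_scores_track_aptitude(self):
        """With gain * aptitude_sd >> score noise, amounts and scores are
        strongly correlated in trained chicks (the score reads out aptitude)."""
        data = generate_experiment(
            scenario_presets("paper-like-1h", "predisposition", seed=3,
                             score_noise_sd=0.5, batch_sd=0.0, residual_sd=1e-4)
        )
        scores = {c.chick_id: c.preference_score for c in data.chicks if c.trained}
        s, y = [], []
        for m in data.measurements:
            if m.chick_id in scores:
                s.append(scores[m.chick_id])
                y.append(m.relative_amount)
        r = np.corrcoef(s, y)[0, 1]
        assert r > 0.95

    def test_scores_valid_and_consistent(self):
        data = generate_experiment(scenario_presets("paper-like-1h", "null", seed=9))
        for c in data.chicks:
            if c.trained:
                assert 0.0 <= c.preference_score <= 100.0
        data.validate()  # includes score/approach consistency

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ImprintstatError):
            generate_experiment(ScenarioConfig(scenario="null", n_batches=2,
                                               trained_per_batch=(3,)))
        with pytest.raises(ImprintstatError):
            generate_experiment(ScenarioConfig(scenario="null", residual_sd=-1.0))


class TestGenerateDensitometry:
    def test_zero_noise_recovers_amounts_for_any_gain(self):
        data = generate_experiment(scenario_presets("paper-like-1h", "null", seed=1))
        dcfg = DensitometryConfig(gain_range=(0.3, 3.0), od_noise_sd=0.0)
        standards, samples = generate_densitometry(data, dcfg, seed=5)
        out = relative_amounts_from_od(samples, standards)
        truth = {m.chick_id: m.relative_amount for m in data.measurements}
        for _, row in out.iterrows():
            assert row["relative_amount"] == pytest.approx(
                truth[row["chick_id"]], abs=1e-10
            )

    def test_deterministic_given_seed(self):
        data = generate_experiment(scenario_presets("paper-like-1h", "null", seed=1))
        s1, m1 = generate_densitometry(data, seed=7)
        s2, m2 = generate_densitometry(data, seed=7)
        assert frames_equal(s1, s2) and frames_equal(m1, m2)

    def test_small_noise_recovery_within_10_percent(self):
        """At 2% multiplicative OD noise, recovered amounts stay within 10%
        of truth for >=95% of samples pooled over seeds."""
        data = generate_experiment(scenario_presets("paper-like-1h", "null", seed=2))
        truth = {m.chick_id: m.relative_amount for m in data.measurements}
        ok = total = 0
        for seed in range(100):
            standards, samples = generate_densitometry(
                data, DensitometryConfig(od_noise_sd=0.02), seed=seed
            )
            out = relative_amounts_from_od(samples, standards,
                                           linearity_threshold=None)
            rel = out["relative_amount"].to_numpy()
            tv = out["chick_id"].map(truth).to_numpy()
            ok += int(np.sum(np.abs(rel / tv - 1.0) <= 0.10))
            total += len(out)
        assert ok / total >= 0.95

    def test_invalid_densitometry_config(self):
        data = generate_experiment(scenario_presets("paper-like-1h", "null", seed=1))
        with pytest.raises(ImprintstatError):
            generate_densitometry(data, DensitometryConfig(gain_range=(0.0, 1.0)))
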