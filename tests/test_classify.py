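"""Features, support-vector detection and the yes/no answer rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import cross_val_score

from _oracles import brute_force_cnr, brute_force_pearson

from trfnirs.classify import (
    ChannelDecision,
    ClassifierError,
    FeatureVector,
    classify_channel,
    compute_cnr,
    compute_model_correlation,
    cycle_average_report,
    decide_answer,
    train_classifier,
)
from trfnirs.hrf import build_regressor
from trfnirs.paradigm import BlockDesign, Timeline, build_timeline
from trfnirs.simulate import SignalSimConfig, simulate_activation_series


def _toy_timeline(task_mask):
    task_mask = np.asarray(task_mask, dtype=float)
    return Timeline(times=np.arange(task_mask.size) * 0.3,
                    task_indicator=task_mask, frame_interval_s=0.3)


class TestCNR:
    def test_definition_arithmetic(self):
        tl = _toy_timeline([0, 0, 0, 0, 1, 1])
        series = np.array([1.0, -1.0, 1.0, -1.0, 2.0, 2.0])
        assert compute_cnr(series, tl) == pytest.approx(2.0)

    def test_equal_means_zero(self):
        tl = _toy_timeline([0, 0, 0, 0, 1, 1])
        series = np.array([2.0, 4.0, 2.0, 4.0, 3.0, 3.0])
        # task mean 3 == rest mean 3, rest SD 1
        assert compute_cnr(series, tl) == pytest.approx(0.0)

    def test_matches_brute_force_on_1000_series(self, rng, design, timeline):
        for _ in range(1000):
            series = rng.normal(size=timeline.n_frames)
            ours = compute_cnr(series, timeline)
            ref = brute_force_cnr(series.tolist(),
                                  timeline.task_mask.tolist())
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_zero_rest_sd_rejected(self):
        tl = _toy_timeline([0, 0, 1, 1])
        with pytest.raises(ClassifierError):
            compute_cnr(np.array([1.0, 1.0, 2.0, 3.0]), tl)


class TestModelCorrelation:
    def test_regressor_itself_gives_unity(self, design):
        reg = build_regressor(design)
        assert compute_model_correlation(reg, design) == pytest.approx(1.0)

    def test_negated_regressor_gives_minus_one(self, design):
        reg = build_regressor(design)
        assert compute_model_correlation(-reg, design) == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng, design):
        reg = build_regressor(design)
        for _ in range(200):
            series = rng.normal(size=reg.size)
            ours = compute_model_correlation(series, design)
            ref = brute_force_pearson(series.tolist(), reg.tolist())
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_rest_runs_rarely_exceed_r_03(self, design):
        hits = 0
        for s in range(200):
            cfg = SignalSimConfig(design=design, activation_amplitude=0.0,
                                  noise_sd=3.0, seed=s)
            series, _ = simulate_activation_series(cfg)
            if abs(compute_model_correlation(series, design)) < 0.3:
                hits += 1
        assert hits >= 190  # >= 95% of draws

    def test_constant_series_rejected(self, design):
        with pytest.raises(ClassifierError):
            compute_model_correlation(np.ones(1100), design)


class TestTraining:
    def test_separable_toy_corpus_perfect(self, design):
        reg = build_regressor(design)
        rows = []
        rng = np.random.default_rng(0)
        for i in range(10):
            rows.append({"label": 1, "noise_sd": 0.1, "seed": i,
                         "series": 10 * reg + rng.normal(0, 0.1, reg.size)})
            rows.append({"label": 0, "noise_sd": 0.1, "seed": i,
                         "series": rng.normal(0, 0.1, reg.size)})
        model = train_classifier(pd.DataFrame(rows), design=design,
                                 cross_validate=False)
        assert model.training_report["train_accuracy"] == 1.0

    def test_shuffled_labels_near_chance(self, corpus, design, model):
        from trfnirs.classify import _corpus_features
        X = _corpus_features(corpus, design, model.hrf, None, None)
        rng = np.random.default_rng(3)
        y = rng.permutation(corpus["label"].to_numpy())
        acc = cross_val_score(model.pipeline, X, y, cv=5).mean()
        # binomial 99% band around 0.5 for n=100
        assert 0.35 <= acc <= 0.65

    def test_accuracy_nonincreasing_with_noise(self, model, design):
        rates = []
        for ns in (2.0, 5.0, 8.0):
            hits = 0
            for s in range(40):
                cfg = SignalSimConfig(design=design, noise_sd=ns,
                                      seed=5000 + 13 * s)
                x, _ = simulate_activation_series(cfg)
                hits += classify_channel(x, model, preprocessed=False).activated
            rates.append(hits / 40)
        tol = 0.1  # sampling error at n=40
        assert rates[0] >= rates[1] - tol >= rates[2] - 2 * tol

    def test_single_class_corpus_rejected(self, design):
        df = pd.DataFrame([{"label": 1, "noise_sd": 1.0, "seed": 0,
                            "series": np.ones(design.n_frames)}])
        with pytest.raises(ClassifierError):
            train_classifier(df, design=design)


class TestChannelDecision:
    def test_strong_activation_detected(self, model, design):
        cfg = SignalSimConfig(design=design, noise_sd=1.0, seed=77)
        x, _ = simulate_activation_series(cfg)
        d = classify_channel(x, model, preprocessed=False)
        assert d.activated and d.features.cnr > 0

    def test_pure_noise_false_positive_rate_bounded(self, model, design):
        fp = 0
        for s in range(100):
            cfg = SignalSimConfig(design=design, activation_amplitude=0.0,
                                  noise_sd=2.0 + (s % 4), seed=9000 + s)
            x, _ = simulate_activation_series(cfg)
            fp += classify_channel(x, model, preprocessed=False).activated
        assert fp / 100 <= 0.25

    def test_constant_series_errors(self, model):
        with pytest.raises(ClassifierError):
            classify_channel(np.ones(1100), model, preprocessed=True)


def _decision(ch, act, cnr=1.0, r=0.5):
    return ChannelDecision(channel=ch, activated=act,
                           features=FeatureVector(cnr=cnr, r=r))


class TestAnswerRule:
    def test_single_activated_channel_yields_yes(self):
        ans = decide_answer([_decision("ch1", False), _decision("ch2", False),
                             _decision("ch3", False), _decision("ch4", True)])
        assert ans.response == "yes" and ans.n_activated == 1

    def test_no_activated_channels_yields_no(self):
        ans = decide_answer([_decision(f"ch{i}", False) for i in range(4)])
        assert ans.response == "no" and ans.n_activated == 0

    def test_all_activated(self):
        ans = decide_answer([_decision(f"ch{i}", True) for i in range(4)])
        assert ans.response == "yes" and ans.n_activated == 4

    def test_summary_pools_activated_for_yes_all_for_no(self):
        yes = decide_answer([_decision("a", True, cnr=6.0, r=0.8),
                             _decision("b", False, cnr=0.0, r=0.0)])
        assert yes.mean_cnr == pytest.approx(6.0)
        no = decide_answer([_decision("a", False, cnr=1.0, r=0.2),
                            _decision("b", False, cnr=3.0, r=0.4)])
        assert no.mean_cnr == pytest.approx(2.0)

    def test_adding_activated_channel_never_flips_yes_to_no(self, rng):
        for _ in range(50):
            base = [_decision(f"ch{i}", bool(rng.integers(2)))
                    for i in range(rng.integers(1, 5))]
            before = decide_answer(base).response
            after = decide_answer(base + [_decision("extra", True)]).response
            assert after == "yes"
            if before == "yes":
                assert after == "yes"

    def test_empty_decisions_rejected(self):
        with pytest.raises(ClassifierError):
            decide_answer([])


class TestCycleAverage:
    def test_periodic_input_recovered_exactly(self, design):
        cyc = design.frames(design.cycle_s)
        one = np.sin(np.linspace(0, 2 * np.pi, cyc, endpoint=False))
        series = np.concatenate([np.zeros(design.frames(design.lead_in_rest_s)),
                                 np.tile(one, design.n_cycles)])
        rep = cycle_average_report(series, design)
        np.testing.assert_allclose(rep["mean"], one, atol=1e-12)
        np.testing.assert_allclose(rep["sem"], 0.0, atol=1e-12)

    def test_white_noise_shrinks_by_sqrt_cycles(self, design, rng):
        sds = []
        for _ in range(30):
            series = rng.normal(size=design.n_frames)
            rep = cycle_average_report(series, design)
            sds.append(rep["mean"].std())
        assert np.mean(sds) == pytest.approx(1 / np.sqrt(5), rel=0.15)

    def test_activation_peaks_in_task_window(self, design):
        cfg = SignalSimConfig(design=design, noise_sd=1.0, seed=3)
        x, _ = simulate_activation_series(cfg)
        rep = cycle_average_report(x, design)
        peak_t = rep.loc[rep["mean"].idxmax(), "time_s"]
        assert peak_t < design.task_s + 10  # peak during/just after task block

    def test_incomplete_cycle_rejected(self, design):
        with pytest.raises(ClassifierError):
            cycle_average_report(np.zeros(50), design)
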