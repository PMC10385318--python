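import re

import numpy as np
import pytest

from epifed.anfis import (
    ANFISModel,
    FuzzyVariable,
    PSOConfig,
    TABLE1_RANGES,
    aggregate_inputs,
    anfis_predict,
    classify_hrv_pattern,
    discretize_changes,
    localize_preictal_sph,
    stage_risk,
    train_anfis_pso,
)
from epifed.synth import generate_hrv_series
from epifed.types import ClinicalRecord, HRVSeries


def _series(values_by_feature):
    keys = ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")
    first = next(iter(values_by_feature.values()))
    return HRVSeries(
        "t",
        times=np.arange(len(first), dtype=float) * 60.0,
        features={k: np.asarray(values_by_feature.get(k, first), float) for k in keys},
    )


def _uniform_series(values):
    return _series({"Lmax": values})


def independent_pattern_matcher(values, ds, dl):
    """Regex-style scan over the discretized change string (the oracle)."""
    v = np.asarray(values, float)
    rel = np.diff(v) / np.abs(v[:-1])
    sym = ""
    for r in rel:
        if abs(r) <= ds:
            sym += "E"
        elif ds < r <= dl:
            sym += "L"
        elif r > dl:
            sym += "G"
        else:
            sym += "D"
    matches = []
    for m in re.finditer(r"(?=LG)", sym):
        if "D" not in sym[m.start() + 2:]:
            matches.append((m.start(), 0, "alpha"))
    for m in re.finditer(r"(?=ELG)", sym):
        matches.append((m.start(), 1, "beta"))
    for m in re.finditer(r"(?=EELG)", sym):
        matches.append((m.start(), 2, "gamma"))
    if not matches:
        return "none", None
    idx, _, name = min(matches)
    return name, idx


class TestFuzzyVariable:
    def test_eeg_low_range(self):
        var = FuzzyVariable.from_class_ranges("EEG", TABLE1_RANGES["EEG"])
        mu = var.fuzzify(0.15)
        assert np.argmax(mu) == 0 and mu[0] == 1.0  # Low peak

    def test_eeg_high_range(self):
        var = FuzzyVariable.from_class_ranges("EEG", TABLE1_RANGES["EEG"])
        assert np.argmax(var.fuzzify(0.80)) == 2

    def test_peak_membership_is_one(self):
        for name, ranges in TABLE1_RANGES.items():
            var = FuzzyVariable.from_class_ranges(name, ranges)
            for i, (_, peak, _) in enumerate(var.mfs):
                assert var.fuzzify(peak)[i] == 1.0

    def test_coverage_positive_everywhere(self):
        for name, ranges in TABLE1_RANGES.items():
            var = FuzzyVariable.from_class_ranges(name, ranges)
            lo = min(r[0] for r in ranges)
            hi = max(r[1] for r in ranges)
            for v in np.linspace(lo, hi, 200):
                assert var.fuzzify(v).sum() > 0, (name, v)

    def test_tie_breaks_toward_higher_risk(self):
        var = FuzzyVariable("x", [(0, 1, 2), (0, 1, 2), (2, 3, 4)])
        assert var.classify(1.0) == 1  # classes 0 and 1 tie at 1.0

    def test_invalid_triangle(self):
        with pytest.raises(ValueError):
            FuzzyVariable("x", [(2, 1, 3), (0, 1, 2), (1, 2, 3)])


class TestAggregateInputs:
    def _clinical(self, genetic=False, metabolic=False, events=1):
        return ClinicalRecord("s", 30.0, "F", genetic, metabolic, events)

    def test_all_high_class_hrv(self):
        # values at each feature's class-3 peak
        hrv = {
            k: 0.5 * (TABLE1_RANGES[k][2][0] + TABLE1_RANGES[k][2][1])
            for k in ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")
        }
        x = aggregate_inputs(0.9, hrv, self._clinical())
        assert x[1] == pytest.approx(1.0)

    def test_mixed_classes_mean(self):
        peaks = {
            k: [0.5 * (lo + hi) for lo, hi in TABLE1_RANGES[k]]
            for k in ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")
        }
        hrv = {
            "Lmax": peaks["Lmax"][0],
            "SDNN": peaks["SDNN"][0],
            "LF_HF": peaks["LF_HF"][1],
            "MeanHR": peaks["MeanHR"][1],
            "pNN50": peaks["pNN50"][2],
        }
        x = aggregate_inputs(0.5, hrv, self._clinical())
        assert x[1] == pytest.approx(0.4)  # mean of {0, 0, 0.5, 0.5, 1}

    def test_clinical_low_class_zero(self):
        hrv = {k: 0.5 * sum(TABLE1_RANGES[k][0]) for k in
               ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")}
        x = aggregate_inputs(0.1, hrv, self._clinical(False, False, 1))
        assert x[2] == 0.0

    def test_clinical_high_class_one(self):
        hrv = {k: 0.5 * sum(TABLE1_RANGES[k][0]) for k in
               ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")}
        x = aggregate_inputs(0.1, hrv, self._clinical(True, True, 7))
        assert x[2] == 1.0

    def test_missing_feature_named(self):
        with pytest.raises(ValueError, match="SDNN"):
            aggregate_inputs(0.5, {"Lmax": 200.0}, self._clinical())


class TestANFIS:
    def test_firing_strengths_normalized(self):
        model = ANFISModel()
        g = np.random.default_rng(0)
        w = model.firing_strengths(g.random((50, 3)))
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_consequents_identity(self):
        model = ANFISModel()
        model.consequents = np.zeros((27, 4))
        model.consequents[:, 0] = 0.42
        g = np.random.default_rng(1)
        out = model.raw_output(g.random((20, 3)))
        np.testing.assert_allclose(out, 0.42, atol=1e-12)

    def test_single_dominant_rule(self):
        model = ANFISModel()
        model.consequents = np.arange(27 * 4, dtype=float).reshape(27, 4)
        x = np.array([v.mfs[0][1] for v in model.variables])  # all Low peaks
        w = model.firing_strengths(x[None, :])
        r = model.rule_index(0, 0, 0)
        if w[0, r] > 0.999:  # single-rule firing
            expected = model.consequents[r] @ np.concatenate([[1.0], x])
            assert model.raw_output(x[None, :])[0] == pytest.approx(expected)

    def test_output_continuous(self):
        model = ANFISModel()
        g = np.random.default_rng(2)
        model.consequents = g.normal(0, 1, (27, 4))
        xs = np.linspace(0.01, 0.99, 400)
        grid = np.stack([xs, np.full_like(xs, 0.5), np.full_like(xs, 0.5)], axis=1)
        out = model.raw_output(grid)
        assert np.max(np.abs(np.diff(out))) < 0.2  # no jumps on a fine grid


class TestTrainAnfis:
    def _monotone_data(self, seed, n=60):
        g = np.random.default_rng(seed)
        X = g.random((n, 3))
        y = 0.2 * X[:, 0] + 0.5 * X[:, 1] + 0.3 * X[:, 2]
        return X, y

    def test_mae_decreases_5_seeds(self):
        for seed in range(5):
            X, y = self._monotone_data(seed)
            model = train_anfis_pso(
                ANFISModel(), X, y,
                pso=PSOConfig(swarm=2, iterations=1, hybrid_epochs=4),
                seed=seed,
            )
            assert model.mae_log[-1] <= model.mae_log[0] + 1e-12

    def test_seed_determinism(self):
        X, y = self._monotone_data(3)
        kw = dict(pso=PSOConfig(swarm=3, iterations=2, hybrid_epochs=2), seed=11)
        m1 = train_anfis_pso(ANFISModel(), X, y, **kw)
        m2 = train_anfis_pso(ANFISModel(), X, y, **kw)
        np.testing.assert_array_equal(m1.consequents, m2.consequents)
        for v1, v2 in zip(m1.variables, m2.variables):
            assert v1.mfs == v2.mfs

    def test_pso_degenerate_reduces_to_hybrid(self):
        from epifed.anfis import _hybrid_train

        X, y = self._monotone_data(4)
        cfg = PSOConfig(swarm=1, iterations=0, hybrid_epochs=3, validation_split=0.0)
        m1 = train_anfis_pso(ANFISModel(), X, y, pso=cfg, seed=5)
        m2 = _hybrid_train(ANFISModel(), X, y, epochs=3)
        np.testing.assert_allclose(m1.consequents, m2.consequents)

    def test_constant_targets_warn(self):
        X = np.random.default_rng(0).random((15, 3))
        with pytest.warns(UserWarning, match="identical targets"):
            model = train_anfis_pso(ANFISModel(), X, np.full(15, 0.7), seed=0)
        np.testing.assert_allclose(model.raw_output(X), 0.7)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            train_anfis_pso(ANFISModel(), np.zeros((5, 3)), np.zeros(5))


class TestPatternMatching:
    def test_worked_alpha_example(self):
        pattern, idx = classify_hrv_pattern(
            _uniform_series([100.0, 110.0, 150.0, 160.0, 161.0]),
            delta_small=0.05, delta_large=0.25,
        )
        assert (pattern, idx) == ("alpha", 0)

    def test_flat_series_none(self):
        pattern, idx = classify_hrv_pattern(
            _uniform_series([100.0, 101.0, 100.5, 101.0, 100.8])
        )
        assert (pattern, idx) == ("none", None)

    def test_beta_and_gamma(self):
        beta = [100.0, 100.5, 110.0, 150.0, 151.0]
        assert classify_hrv_pattern(_uniform_series(beta))[0] == "beta"
        gamma = [100.0, 100.5, 100.0, 110.0, 150.0]
        assert classify_hrv_pattern(_uniform_series(gamma))[0] == "gamma"

    def test_too_short(self):
        with pytest.raises(ValueError):
            classify_hrv_pattern(_uniform_series([1.0, 2.0, 3.0, 4.0]))

    def test_generator_recovery_sample(self):
        for i, cls in enumerate(["Pk1", "Pk2", "Pk3"] * 50):
            series = generate_hrv_series(cls, n_points=20, seed=i)
            pattern, _ = classify_hrv_pattern(series)
            assert pattern == {"Pk1": "alpha", "Pk2": "beta", "Pk3": "gamma"}[cls]

    def test_matches_independent_matcher(self):
        g = np.random.default_rng(9)
        for _ in range(1000):
            v = np.abs(np.cumprod(1 + g.uniform(-0.2, 0.4, size=10))) * 100
            got = classify_hrv_pattern(_uniform_series(v), 0.05, 0.25)
            want = independent_pattern_matcher(v, 0.05, 0.25)
            assert got == want, (v, got, want)

    def test_vote_order_invariance(self):
        g = np.random.default_rng(10)
        base = {k: np.abs(np.cumprod(1 + g.uniform(-0.1, 0.35, 12))) * 50
                for k in ("Lmax", "SDNN", "LF_HF", "MeanHR", "pNN50")}
        s1 = _series(base)
        s2 = _series(dict(reversed(list(base.items()))))
        assert classify_hrv_pattern(s1) == classify_hrv_pattern(s2)


class TestStageRisk:
    def test_alpha_dominates_anfis(self):
        assert stage_risk(0.05, "alpha").risk_class == "Pk1"

    def test_gamma_forces_low(self):
        assert stage_risk(0.95, "gamma").risk_class == "Pk3"

    def test_fallback_tiers(self):
        assert stage_risk(0.9, "none").risk_class == "Pk1"
        assert stage_risk(0.5, "none").risk_class == "Pk2"
        assert stage_risk(0.1, "none").risk_class == "Pk3"

    def test_anfis_predict_classes(self):
        model = ANFISModel()
        model.consequents = np.zeros((27, 4))
        model.consequents[:, 0] = 1.0
        model.output_min, model.output_max = 0.0, 1.0
        out, classes = anfis_predict(model, np.array([[0.5, 0.5, 0.5]]))
        assert classes == ["Pk1"]


class TestLocalizeSPH:
    def test_worked_example(self):
        start, alarm, sph = localize_preictal_sph(
            np.array([100.0, 102.0, 140.0, 200.0, 210.0]),
            seizure_onset_s=300.0,
            delta_large=0.25,
            times=np.array([0.0, 60.0, 120.0, 180.0, 240.0]),
        )
        assert (start, alarm, sph) == (0.0, 0.0, 300.0)

    def test_flat_series_null(self):
        assert localize_preictal_sph(
            np.array([100.0, 100.5, 101.0, 100.8, 101.0]), 400.0
        ) == (None, None, None)

    def test_sph_nonnegative_and_k0_clamped(self):
        start, alarm, sph = localize_preictal_sph(
            np.array([100.0, 140.0, 200.0, 205.0, 210.0]), 500.0,
            times=np.array([10.0, 70.0, 130.0, 190.0, 250.0]),
        )
        assert start == 10.0  # k=0 clamps to series start
        assert sph == 490.0 and sph >= 0

    def test_hrv_series_input(self):
        series = generate_hrv_series("Pk1", 15, seed=3)
        start, alarm, sph = localize_preictal_sph(series, series.times[-1] + 60.0)
        assert sph is None or sph >= 0
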