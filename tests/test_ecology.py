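"""VAR/VIR/validation statistics and the synthetic detection study."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avisep.ecology import (
    StudyConfig,
    compute_var,
    compute_vir,
    fit_poly_response,
    precision_recall,
    simulate_detection_study,
    stratified_sample,
    threshold_detections,
)


def make_inventory(n_per_hour=4, hours=range(24)):
    rows = []
    for h in hours:
        for i in range(n_per_hour):
            rows.append({"clip_id": f"c{h:02d}_{i}",
                         "timestamp": f"2023-10-01T{h:02d}:{i % 60:02d}:{i // 60:02d}",
                         "site": "E1"})
    return pd.DataFrame(rows)


class TestThreshold:
    def test_boundary_inclusive(self):
        scores = pd.DataFrame({"clip_id": list("abc"),
                               "confidence": [0.69, 0.70, 0.71]})
        assert len(threshold_detections(scores, 0.7)) == 2

    def test_extremes(self):
        scores = pd.DataFrame({"clip_id": list("ab"), "confidence": [0.1, 0.9]})
        assert len(threshold_detections(scores, 0.0)) == 2
        assert len(threshold_detections(scores, 1.01)) == 0

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            threshold_detections(pd.DataFrame({"confidence": [1.5]}), 0.7)


class TestVar:
    def test_proportion(self):
        inv = make_inventory(n_per_hour=12, hours=[5])
        det = pd.DataFrame({
            "clip_id": ["c05_0", "c05_1", "c05_2"],
            "timestamp": ["2023-10-01T05:00:00"] * 3,
            "species": "wagtail", "confidence": 0.9, "strategy": "raw"})
        series = compute_var(det, inv, "hour", "wagtail")
        assert series.table.loc[series.table["hour"] == 5, "var"].item() == 0.25

    def test_no_positives_zero(self):
        inv = make_inventory(n_per_hour=3, hours=[2])
        det = pd.DataFrame(columns=["clip_id", "timestamp", "species",
                                    "confidence", "strategy"])
        series = compute_var(det, inv, "hour", "wagtail")
        assert (series.table["var"] == 0.0).all()

    def test_unknown_clip_rejected(self):
        inv = make_inventory(n_per_hour=2, hours=[1])
        det = pd.DataFrame({"clip_id": ["nope"], "timestamp": ["2023-10-01T01:00:00"],
                            "species": "wagtail"})
        with pytest.raises(ValueError):
            compute_var(det, inv, "hour", "wagtail")


class TestStratifiedSample:
    def test_exact_per_stratum_counts(self):
        inv = make_inventory(n_per_hour=100)
        sample = stratified_sample(inv, fraction=0.3, seed=0)
        assert len(sample) == 720
        hours = pd.to_datetime(sample["timestamp"]).dt.hour.value_counts()
        assert (hours == 30).all()

    def test_full_fraction_is_identity(self):
        inv = make_inventory(n_per_hour=5)
        sample = stratified_sample(inv, fraction=1.0, seed=1)
        assert set(sample["clip_id"]) == set(inv["clip_id"])

    def test_deterministic(self):
        inv = make_inventory(n_per_hour=10)
        a = stratified_sample(inv, 0.3, seed=5)
        b = stratified_sample(inv, 0.3, seed=5)
        assert a.equals(b)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            stratified_sample(make_inventory(), fraction=0.0)


class TestPrecisionRecall:
    def test_hand_case(self):
        det = pd.DataFrame({"clip_id": [f"c{i}" for i in range(10)],
                            "species": "sp"})
        truth = pd.DataFrame({
            "clip_id": [f"c{i}" for i in range(14)],
            "species": "sp",
            "present": [True] * 8 + [False, False] + [True, True, False, False]})
        summary = precision_recall(det, truth, "sp")
        assert summary.precision == pytest.approx(0.8)
        assert summary.recall == pytest.approx(0.8)

    def test_no_detections(self):
        det = pd.DataFrame(columns=["clip_id", "species"])
        truth = pd.DataFrame({"clip_id": ["a"], "species": "sp", "present": [True]})
        summary = precision_recall(det, truth, "sp")
        assert summary.precision is None
        assert summary.recall == 0.0


class TestVir:
    def test_hand_case(self):
        raw = pd.DataFrame({"clip_id": [], "species": []})
        sep = pd.DataFrame({"clip_id": [f"c{i}" for i in range(10)], "species": "sp"})
        truth = pd.DataFrame({"clip_id": [f"c{i}" for i in range(10)],
                              "species": "sp",
                              "present": [True] * 8 + [False] * 2})
        assert compute_vir(raw, sep, truth) == pytest.approx(0.8)

    def test_no_new_detections_undefined(self):
        det = pd.DataFrame({"clip_id": ["a"], "species": ["sp"]})
        truth = pd.DataFrame({"clip_id": ["a"], "species": ["sp"], "present": [True]})
        assert compute_vir(det, det, truth) is None

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        clips = [f"c{i}" for i in range(12)]
        raw_mask = rng.random(12) < 0.4
        sep_mask = np.logical_or(raw_mask, rng.random(12) < 0.4)
        present = rng.random(12) < 0.5
        raw = pd.DataFrame({"clip_id": np.array(clips)[raw_mask], "species": "sp"})
        sep = pd.DataFrame({"clip_id": np.array(clips)[sep_mask], "species": "sp"})
        truth = pd.DataFrame({"clip_id": clips, "species": "sp", "present": present})
        new = [c for c, r, s in zip(clips, raw_mask, sep_mask) if s and not r]
        expected = (np.mean([present[clips.index(c)] for c in new])
                    if new else None)
        got = compute_vir(raw, sep, truth)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestPolyFit:
    def test_exact_cubic(self):
        x = np.linspace(-1, 2, 40)
        y = 1.0 - 0.5 * x + 0.2 * x ** 2 + 0.1 * x ** 3
        fit = fit_poly_response(y, x)
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.coefficients, [1.0, -0.5, 0.2, 0.1],
                                   atol=1e-10)

    def test_constant_response(self):
        fit = fit_poly_response(np.full(20, 0.3), np.linspace(0, 1, 20))
        assert fit.r_squared == 0.0

    def test_truth_inside_ci_with_noise(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, 200)
        truth_coef = [0.3, -0.1, 0.05, -0.02]
        y_true = np.polyval(truth_coef[::-1], x)
        fit = fit_poly_response(y_true + rng.normal(0, 0.05, 200), x)
        grid_truth = np.polyval(truth_coef[::-1], fit.grid["x"])
        inside = ((grid_truth >= fit.grid["ci_low"])
                  & (grid_truth <= fit.grid["ci_high"]))
        assert inside.mean() >= 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_poly_response(np.ones(3), np.arange(3))  # too few points
        with pytest.raises(ValueError):
            fit_poly_response(np.ones(10), np.ones(10))  # constant covariate


@pytest.fixture(scope="module")
def study():
    return simulate_detection_study(seed=0)


class TestDetectionStudy:
    def test_degenerate_config_equals_truth(self):
        cfg = StudyConfig(days=1)
        for sp in cfg.masking_raw:
            cfg.masking_raw[sp] = np.zeros(24)
            cfg.fp_raw[sp] = np.zeros(24)
        cfg.new_false_fraction = 1e-9
        out = simulate_detection_study(cfg, seed=1)
        truth_pos = out["truth"].loc[out["truth"]["present"]]
        for det in (out["raw"], out["separated"]):
            got = set(zip(det["clip_id"], det["species"]))
            want = set(zip(truth_pos["clip_id"], truth_pos["species"]))
            assert got == want
        assert compute_vir(out["raw"], out["separated"], out["truth"]) is None

    def test_evening_false_peak_removed(self, study):
        inv = study["inventory"]
        raw_curve = compute_var(study["raw"], inv, "hour", "white_wagtail").curve()
        sep_curve = compute_var(study["separated"], inv, "hour",
                                "white_wagtail").curve()
        assert raw_curve.idxmax() in (16, 17, 18)
        truth = study["truth"]
        tmerged = truth.loc[truth["species"] == "white_wagtail"].merge(
            inv, on="clip_id")
        truth_curve = tmerged.groupby(
            pd.to_datetime(tmerged["timestamp"]).dt.hour)["present"].mean()
        assert sep_curve.idxmax() == truth_curve.idxmax()

    def test_dawn_masking_recovered(self, study):
        # nocturnal species: separated recall beats raw in the 04-05 h stratum
        inv = study["inventory"].copy()
        hours = pd.to_datetime(inv["timestamp"]).dt.hour
        dawn_clips = inv.loc[hours.isin([4, 5]), "clip_id"]
        recalls = {}
        for name in ("raw", "separated"):
            det = study[name]
            summary = precision_recall(det, study["truth"], "night_heron",
                                       sample_clips=dawn_clips)
            recalls[name] = summary.recall
        assert recalls["separated"] > recalls["raw"]

    def test_recall_gap_tracks_masking_and_recovery(self, study):
        # gap = E[masking] * recovery_rate over the positive clips
        cfg = study["config"]
        truth = study["truth"]
        inv = study["inventory"]
        hours = pd.to_datetime(inv["timestamp"]).dt.hour.to_numpy()
        for sp in ("night_heron", "white_wagtail"):
            pos = truth.loc[(truth["species"] == sp) & truth["present"]]
            idx = inv["clip_id"].searchsorted(pos["clip_id"])
            mask_rate = np.mean(np.asarray(cfg.masking_raw[sp])[hours[idx]])
            expected_gap = mask_rate * cfg.recovery_rate
            raw_r = precision_recall(study["raw"], truth, sp).recall
            sep_r = precision_recall(study["separated"], truth, sp).recall
            se = 3 * np.sqrt(0.25 / len(pos))  # conservative binomial error
            assert abs((sep_r - raw_r) - expected_gap) < se + 0.01

    def test_invalid_profile_rejected(self):
        cfg = StudyConfig()
        cfg.activity["night_heron"] = np.full(24, 1.5)
        with pytest.raises(ValueError):
            simulate_detection_study(cfg, seed=0)
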