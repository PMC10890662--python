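"""Four-step identification: step filters, spectral similarity, pipeline."""

import numpy as np
import pytest

from glcga.identify import (
    records_to_frame,
    replay_worked_examples,
    run_pipeline,
    spectral_similarity,
    step2_fragmentation_consistent,
    step3_ri_filter,
    step4_standard_check,
)
from glcga.lcms_io import MS2Spectrum
from glcga.screen import AringInference
from glcga.synth_data import (
    compound_spectrum,
    default_config,
    simulate_run,
    standard_spectrum,
)


def spec(mz, inten, precursor=500.0):
    return MS2Spectrum(precursor, 10.0, np.asarray(mz, float), np.asarray(inten, float))


# --- step 2 ----------------------------------------------------------------


def test_step2_keeps_compatible_annotations(registry):
    inference = AringInference(lactone=1, hydroxyls=1, anchor_mz=356.19)
    kept = step2_fragmentation_consistent(["GA7", "GA11", "GA5", "GA31"], inference, registry)
    assert kept == ["GA7"]  # lactone+hydroxyl; GA11/GA5 lack the hydroxyl, GA31 the lactone


def test_step2_requires_enough_hydroxyls(registry):
    inference = AringInference(lactone=1, hydroxyls=2, anchor_mz=374.20)
    kept = step2_fragmentation_consistent(["GA1", "GA34", "GA16", "GA58"], inference, registry)
    assert kept == ["GA34", "GA16"]


def test_step2_compound12_narrowing(registry):
    """Only one candidate of the m/z 611.3174 channel has lactone + 2 OH."""
    channel = ["GA13", "GA17", "GA23", "GA46", "GA52", "GA66", "GA99", "GA102", "GA125", "GA129"]
    inference = AringInference(lactone=1, hydroxyls=2, anchor_mz=404.21)
    assert step2_fragmentation_consistent(channel, inference, registry) == ["GA52"]


# --- step 3 ----------------------------------------------------------------

PREDICTIONS = {
    "GA105": 535.52, "GA62": 685.27, "GA104": 716.94, "GA106": 796.48,
    "GA107": 826.57, "GA7": 840.94, "GA88": 865.36,
}
SEVEN = ["GA7", "GA62", "GA88", "GA104", "GA105", "GA106", "GA107"]


def test_step3_compound1_removes_only_ga105():
    kept = step3_ri_filter(SEVEN, 718.97, PREDICTIONS)
    assert kept == ["GA7", "GA62", "GA88", "GA104", "GA106", "GA107"]


def test_step3_compound2_removes_ga105_and_ga62():
    kept = step3_ri_filter(SEVEN, 760.66, PREDICTIONS)
    assert kept == ["GA7", "GA88", "GA104", "GA106", "GA107"]


def test_step3_missing_predictions_retained_with_warning():
    with pytest.warns(UserWarning, match="no predicted RI"):
        kept = step3_ri_filter(["GA2", "GA82"], 682.35, {})
    assert kept == ["GA2", "GA82"]


# --- spectral similarity ---------------------------------------------------


def test_similarity_identical_and_disjoint():
    a = spec([100.0, 200.0, 300.0], [10.0, 40.0, 90.0])
    assert spectral_similarity(a, a) == pytest.approx(1.0)
    b = spec([150.0, 250.0], [10.0, 10.0])
    assert spectral_similarity(a, b) == 0.0


def _brute_force_cosine(a, b, tol):
    # exhaustive greedy match, sqrt weighting — independent reimplementation
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    cand = sorted(
        (abs(ma - mb), i, j)
        for i, ma in enumerate(a.mz)
        for j, mb in enumerate(b.mz)
        if abs(ma - mb) <= tol
    )
    ua, ub, s = set(), set(), 0.0
    for _, i, j in cand:
        if i not in ua and j not in ub:
            ua.add(i)
            ub.add(j)
            s += wa[i] * wb[j]
    return s / (np.linalg.norm(wa) * np.linalg.norm(wb))


def test_similarity_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        mza = np.sort(rng.choice(np.arange(100, 500, 0.35), size=12, replace=False))
        mzb = np.sort(rng.choice(np.arange(100, 500, 0.35), size=9, replace=False))
        a = spec(mza, rng.uniform(10, 1000, 12))
        b = spec(mzb, rng.uniform(10, 1000, 9))
        assert spectral_similarity(a, b, tol=0.01) == pytest.approx(
            _brute_force_cosine(a, b, 0.01), abs=1e-12
        )


def test_similarity_matches_matchms_cross_check():
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    rng = np.random.default_rng(4)
    mza = np.sort(rng.choice(np.arange(100, 500, 0.5), size=10, replace=False))
    mzb = np.concatenate([mza[:6], mza[6:] + 20.0])
    a = spec(mza, rng.uniform(10, 1000, 10))
    b = spec(np.sort(mzb), rng.uniform(10, 1000, 10))
    sa = matchms.Spectrum(mz=a.mz, intensities=a.intensity, metadata={}, metadata_harmonization=False)
    sb = matchms.Spectrum(mz=b.mz, intensities=b.intensity, metadata={}, metadata_harmonization=False)
    expected = CosineGreedy(tolerance=0.01, intensity_power=0.5).pair(sa, sb)["score"]
    assert spectral_similarity(a, b, tol=0.01) == pytest.approx(float(expected), abs=1e-6)


# --- step 4 ----------------------------------------------------------------


def test_step4_rejects_dissimilar_standard_and_supports_similar():
    c1 = compound_spectrum(1)
    c10 = compound_spectrum(10)
    standards = {"GA7": standard_spectrum("GA7"), "GA34": standard_spectrum("GA34")}
    kept, scores = step4_standard_check(["GA7", "GA62"], c1, standards)
    assert kept == ["GA62"] and scores["GA7"] < 0.5
    kept10, scores10 = step4_standard_check(["GA16", "GA34"], c10, standards)
    assert kept10 == ["GA16", "GA34"] and scores10["GA34"] > 0.8
    # no standards -> untouched
    kept_none, _ = step4_standard_check(["GA7"], c1, {})
    assert kept_none == ["GA7"]


# --- pipeline --------------------------------------------------------------


def test_pipeline_recovers_spikes_and_rejects_decoys(channels, pipeline_config):
    run, truth = simulate_run(default_config(123))
    records = run_pipeline(run, channels, pipeline_config)
    true_spikes = [s for s in truth.spikes if not s.decoy]
    assert len(records) == len(true_spikes)
    for s in true_spikes:
        rec = [r for r in records
               if abs(r.light_mz - s.light_mz) < 0.01 and abs(r.rt - s.rt_light) < 0.05]
        assert len(rec) == 1
    decoy_rts = [(s.light_mz, s.rt_light) for s in truth.spikes if s.decoy]
    for mz, rt in decoy_rts:
        assert not any(abs(r.light_mz - mz) < 0.01 and abs(r.rt - rt) < 0.05 for r in records)


def test_pipeline_candidate_sets_are_nested(channels, pipeline_config):
    run, _ = simulate_run(default_config(7))
    for r in run_pipeline(run, channels, pipeline_config):
        assert set(r.step4) <= set(r.step3) <= set(r.step2) <= set(r.assigned)


def test_pipeline_without_ms2_yields_no_records(channels, pipeline_config):
    run, _ = simulate_run(default_config(5))
    run.ms2 = []
    assert run_pipeline(run, channels, pipeline_config) == []


def test_pipeline_deterministic_report(channels, pipeline_config):
    run1, _ = simulate_run(default_config(77))
    run2, _ = simulate_run(default_config(77))
    f1 = records_to_frame(run_pipeline(run1, channels, pipeline_config))
    f2 = records_to_frame(run_pipeline(run2, channels, pipeline_config))
    assert f1.to_csv() == f2.to_csv()


def test_yaml_config_overrides(pipeline_config, tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        "rt_delta: [0.0, 0.02]\nintensity_ratio: [0.5, 2.0]\n"
        "mandatory_classes: [5]\neq1_threshold: 50.0\nms2_tol_ppm: 5.0\n"
    )
    cfg = pipeline_config.with_yaml_overrides(p)
    assert cfg.criteria.rt_delta == (0.0, 0.02)
    assert cfg.criteria.intensity_ratio == (0.5, 2.0)
    assert cfg.policy.mandatory == (5,)
    assert cfg.eq1_threshold == 50.0 and cfg.ms2_tol_ppm == 5.0
    # original untouched
    assert pipeline_config.criteria.rt_delta == (0.0, 0.013)


# --- worked-example replay -------------------------------------------------


def test_replay_reproduces_reported_identifications():
    recs = replay_worked_examples()
    assert recs[1].step4 == ["GA62", "GA88", "GA104", "GA106", "GA107"]
    assert recs[2].step4 == ["GA88", "GA104", "GA106", "GA107"]
    assert recs[11].step4 == ["GA2", "GA82"]
    assert recs[12].step4 == ["GA52"]
    assert recs[1].ri == pytest.approx(718.97, abs=0.01)
    assert recs[2].ri == pytest.approx(760.66, abs=0.01)
    assert "GA34" in recs[10].supported
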