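"""Run model, mzML round-trip, XIC extraction and peak picking."""

import numpy as np
import pytest

from glcga.lcms_io import (
    MS1Spectrum,
    MS2Spectrum,
    Run,
    XICTrace,
    detect_peaks,
    extract_xic,
    ms2_near,
    read_run,
    write_mzml,
)
from glcga.synth_data import SimConfig, Spike, simulate_run


def _gaussian_trace(center=10.0, sigma=0.05, height=1e5, noise_sd=0.0, seed=0, n=600):
    rng = np.random.default_rng(seed)
    rt = np.linspace(center - 2.5, center + 2.5, n)
    y = height * np.exp(-0.5 * ((rt - center) / sigma) ** 2)
    if noise_sd:
        y = np.abs(y + rng.normal(0, noise_sd, size=n))
    return XICTrace(target_mz=500.0, tol_ppm=10, rt=rt, intensity=y)


@pytest.fixture(scope="module")
def small_run():
    cfg = SimConfig(seed=11, gradient_min=2.0, noise_peaks_per_scan=10,
                    spikes=[Spike("GA3", rt=1.0)])
    return simulate_run(cfg)


def test_mzml_roundtrip(tmp_path, small_run):
    run, _truth = small_run
    path = tmp_path / "run.mzML"
    write_mzml(run, path)
    back = read_run(path)
    assert len(back.ms1) == len(run.ms1)
    assert len(back.ms2) == len(run.ms2)
    mid = len(run.ms1) // 2
    assert np.allclose(back.ms1[mid].mz, run.ms1[mid].mz)
    assert np.allclose(back.ms1[mid].intensity, run.ms1[mid].intensity)
    assert back.ms2[0].precursor_mz == pytest.approx(run.ms2[0].precursor_mz, abs=1e-5)
    assert [s.rt for s in back.ms1] == pytest.approx([s.rt for s in run.ms1], abs=1e-6)


def test_read_truncated_mzml_errors(tmp_path, small_run):
    run, _ = small_run
    path = tmp_path / "run.mzML"
    write_mzml(run, path)
    (tmp_path / "trunc.mzML").write_text(path.read_text()[:4000])
    with pytest.raises(ValueError):
        read_run(tmp_path / "trunc.mzML")


def test_read_ms1_only_mzml(tmp_path, small_run):
    run, _ = small_run
    path = tmp_path / "ms1only.mzML"
    write_mzml(Run(ms1=run.ms1[:50], ms2=[]), path)
    back = read_run(path)
    assert len(back.ms1) == 50 and back.ms2 == []


def test_spectrum_validation():
    with pytest.raises(ValueError):
        MS1Spectrum(1.0, np.array([1.0, 2.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        MS1Spectrum(1.0, np.array([1.0, 2.0]), np.array([1.0, -5.0]))
    # unsorted input is sorted rather than rejected
    s = MS1Spectrum(1.0, np.array([2.0, 1.0]), np.array([10.0, 20.0]))
    assert list(s.mz) == [1.0, 2.0] and list(s.intensity) == [20.0, 10.0]


def test_xic_apex_matches_spiked_rt(small_run):
    run, truth = small_run
    spike = truth.spikes[0]
    trace = extract_xic(run, spike.light_mz, tol_ppm=10)
    apex = trace.rt[np.argmax(trace.intensity)]
    assert apex == pytest.approx(spike.rt_light, abs=0.02)


def test_xic_no_signal_is_zero(small_run):
    run, _ = small_run
    trace = extract_xic(run, 699.9, tol_ppm=5)
    assert trace.intensity.max() == pytest.approx(0.0, abs=1e4)


def test_xic_windows_conserve_total_ion_current():
    # disjoint absolute windows covering all points must sum to the TIC
    rng = np.random.default_rng(3)
    scans = []
    for i in range(20):
        mz = np.sort(rng.uniform(300, 700, size=30))
        scans.append(MS1Spectrum(i * 0.01, mz, rng.uniform(10, 100, size=30)))
    run = Run(ms1=scans, ms2=[])
    centers = np.arange(302, 700, 4.0)  # ppm tol chosen so windows abut: 4 Th each
    total = np.zeros(20)
    for c in centers:
        tol_ppm = 2.0 / c * 1e6  # half-width 2 Th
        total += extract_xic(run, c, tol_ppm).intensity
    tic = np.array([s.intensity.sum() for s in scans])
    assert total == pytest.approx(tic, rel=1e-9)


def test_single_noiseless_gaussian_yields_one_peak():
    trace = _gaussian_trace()
    peaks = detect_peaks(trace)
    assert len(peaks) == 1
    assert peaks[0].rt == pytest.approx(10.0, abs=0.01)
    assert peaks[0].left <= peaks[0].rt <= peaks[0].right


def test_flat_noise_yields_no_peaks():
    rng = np.random.default_rng(5)
    trace = XICTrace(500.0, 10, np.linspace(0, 5, 1000), rng.normal(100, 10, 1000))
    assert detect_peaks(trace) == []


def test_two_resolved_gaussians_detected_in_order():
    rt = np.linspace(8, 12, 800)
    y = 1e5 * np.exp(-0.5 * ((rt - 9.0) / 0.05) ** 2)
    y += 5e4 * np.exp(-0.5 * ((rt - 11.0) / 0.05) ** 2)
    peaks = detect_peaks(XICTrace(500.0, 10, rt, y))
    assert len(peaks) == 2
    assert peaks[0].rt == pytest.approx(9.0, abs=0.01)
    assert peaks[1].rt == pytest.approx(11.0, abs=0.01)


def test_peak_recovery_rate_at_snr_10():
    """>=99% of simulated peaks with SNR >= 10 and width >= 5 scans recovered."""
    recovered = 0
    n_runs = 100
    for seed in range(n_runs):
        rng = np.random.default_rng(seed)
        center = rng.uniform(9, 11)
        noise_sd = 100.0
        height = rng.uniform(10, 30) * noise_sd
        trace = _gaussian_trace(center=center, sigma=0.06, height=height,
                                noise_sd=noise_sd, seed=seed)
        peaks = detect_peaks(trace, min_snr=3, min_points=5)
        if any(abs(p.rt - center) < 0.05 for p in peaks):
            recovered += 1
    assert recovered >= 0.99 * n_runs


def test_ms2_near_selection_and_tie_breaks():
    frag = np.array([100.0, 200.0])
    a = MS2Spectrum(500.0, 10.00, frag, np.array([10.0, 10.0]))
    b = MS2Spectrum(500.0, 10.05, frag, np.array([50.0, 50.0]))
    c = MS2Spectrum(600.0, 10.00, frag, np.array([10.0, 10.0]))
    run = Run(ms1=[], ms2=[a, b, c])
    assert ms2_near(run, 500.0, 10.01, rt_window=0.2) is a
    # outside window
    assert ms2_near(run, 500.0, 12.0, rt_window=0.2) is None
    # precursor mismatch
    assert ms2_near(run, 550.0, 10.0, rt_window=0.2) is None
    # exact RT tie: higher TIC wins
    d = MS2Spectrum(500.0, 10.10, frag, np.array([5.0, 5.0]))
    e = MS2Spectrum(500.0, 9.90, frag, np.array([500.0, 500.0]))
    run2 = Run(ms1=[], ms2=[d, e])
    assert ms2_near(run2, 500.0, 10.0, rt_window=0.2) is e
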