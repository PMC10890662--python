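"""Peak-pair matching and five-class MS/MS rule screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glcga.chem_mass import cation_mz, parse_formula
from glcga.lcms_io import ChromPeak, MS2Spectrum
from glcga.screen import (
    DMA_LOSS,
    GLUCOSE_LOSS,
    PairCriteria,
    annotate_losses,
    detect_skeleton_series,
    infer_a_ring,
    match_pairs,
    screen_spectrum,
)


def peak(rt, height=1e5):
    return ChromPeak(rt=rt, height=height, area=height, left=rt - 0.1, right=rt + 0.1, snr=100)


def spectrum(mz_values, precursor=563.2963, intensities=None):
    mz = np.array(sorted(mz_values))
    inten = np.ones_like(mz) * 100.0 if intensities is None else np.asarray(intensities)
    return MS2Spectrum(precursor_mz=precursor, rt=10.0, mz=mz, intensity=inten)


# --- pair matching ---------------------------------------------------------


@pytest.mark.parametrize(
    "delta,ratio,expected",
    [
        (0.005, 1.00, 1),   # interior of both windows
        (0.020, 1.00, 0),   # RT delta beyond 0.013 min
        (0.005, 0.50, 0),   # ratio below 0.76
        (-0.002, 1.00, 0),  # heavy eluting after light
        (0.000, 0.76, 1),   # boundary values accepted
        (0.013, 1.50, 1),
    ],
)
def test_pair_criteria_bounds(delta, ratio, expected):
    light = [peak(10.0 + delta, height=1e5 * ratio)]
    heavy = [peak(10.0, height=1e5)]
    assert len(match_pairs(light, heavy)) == expected


def test_greedy_assignment_prefers_smallest_rt_delta():
    light = [peak(10.000), peak(10.010)]
    heavy = [peak(9.998)]
    pairs = match_pairs(light, heavy)
    assert len(pairs) == 1
    assert pairs[0].light.rt == pytest.approx(10.000)


def test_each_peak_used_once():
    light = [peak(10.000), peak(10.001)]
    heavy = [peak(9.995), peak(9.996)]
    pairs = match_pairs(light, heavy)
    assert len(pairs) == 2
    assert len({id(p.light) for p in pairs}) == 2
    assert len({id(p.heavy) for p in pairs}) == 2


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(8.0, 12.0), min_size=1, max_size=5, unique=True),
    st.randoms(use_true_random=False),
)
def test_matching_invariant_under_input_permutation(rts, rnd):
    light = [peak(rt + 0.004) for rt in rts]
    heavy = [peak(rt) for rt in rts]
    baseline = {(p.light.rt, p.heavy.rt) for p in match_pairs(light, heavy)}
    light2, heavy2 = list(light), list(heavy)
    rnd.shuffle(light2)
    rnd.shuffle(heavy2)
    assert {(p.light.rt, p.heavy.rt) for p in match_pairs(light2, heavy2)} == baseline


def test_widening_criteria_never_shrinks_matches():
    rng = np.random.default_rng(0)
    light = [peak(rt, height=1e5 * rng.uniform(0.5, 2)) for rt in rng.uniform(8, 12, 8)]
    heavy = [peak(rt, height=1e5) for rt in rng.uniform(8, 12, 8)]
    narrow = match_pairs(light, heavy, PairCriteria((0.0, 0.013), (0.76, 1.50)))
    wide = match_pairs(light, heavy, PairCriteria((-0.05, 0.05), (0.3, 3.0)))
    assert len(wide) >= len(narrow)


# --- loss annotation -------------------------------------------------------


def test_glucose_loss_hit():
    ms2 = spectrum([579.2912, 417.2384], precursor=579.2912)
    ev = annotate_losses(ms2, 579.2912)
    assert any(abs(h.mz - 417.2384) < 0.01 for h in ev.class_hits(5))


def test_worked_ladder_hits_all_classes():
    # precursor -Glc, -Glc-DMA (anchor), anchor-H2O, anchor-HCOOH
    ms2 = spectrum([563.2963, 401.2435, 356.1857, 338.1751, 310.1802])
    ev = annotate_losses(ms2, 563.2963)
    assert any(abs(h.mz - 401.2435) < 0.01 for h in ev.class_hits(5))
    assert any(abs(h.mz - 356.1857) < 0.01 for h in ev.class_hits(1))
    class2 = {round(h.mz, 4) for h in ev.class_hits(2)}
    assert 338.1751 in class2  # anchor - H2O
    assert 310.1802 in class2  # anchor - HCOOH


def test_empty_loss_spectrum_no_hits():
    ms2 = spectrum([563.2963, 250.0, 260.0])
    ev = screen_spectrum(ms2, 563.2963)
    assert not ev.overall
    assert not ev.class_hits(5)


def test_hit_mass_errors_within_tolerance():
    ms2 = spectrum([563.2963, 401.2435, 356.1857, 338.1751, 310.1802, 91.0542])
    ev = annotate_losses(ms2, 563.2963, tol_ppm=10)
    for cls in range(1, 6):
        for hit in ev.class_hits(cls):
            assert abs(hit.ppm_error) <= 10.0


# --- skeleton series -------------------------------------------------------


@pytest.mark.parametrize(
    "mz,assignment",
    [(91.0542, "C7H7"), (105.0699, "C8H9"), (131.0855, "C10H11")],
)
def test_skeleton_assignments(mz, assignment):
    out = detect_skeleton_series(spectrum([mz]))
    assert out and out[0][1] == assignment
    assert out[0][0] == pytest.approx(cation_mz(parse_formula(assignment)), abs=0.01)


def test_skeleton_unassignable_and_window():
    assert detect_skeleton_series(spectrum([85.0000])) == []   # no CxHy within tol
    assert detect_skeleton_series(spectrum([300.0])) == []     # outside window


# --- overall screen --------------------------------------------------------


def full_ladder(precursor=563.2963):
    anchor = precursor - GLUCOSE_LOSS - DMA_LOSS
    return [
        precursor,
        precursor - GLUCOSE_LOSS,
        anchor,
        anchor - 18.0106,
        anchor - 18.0106 - 46.0055,
        anchor - 28.0313,
        72.0808,
        91.0542,
        105.0699,
    ]


def test_full_ladder_passes():
    ev = screen_spectrum(spectrum(full_ladder()), 563.2963)
    assert ev.overall
    assert all(ev.flags[c] for c in (1, 2, 3, 5))


def test_missing_glucose_loss_fails():
    frags = [m for m in full_ladder() if abs(m - (563.2963 - GLUCOSE_LOSS)) > 0.01]
    # also remove the anchor-derived hits seeded from the precursor glucose branch
    ev = screen_spectrum(spectrum(frags), 563.2963)
    assert not ev.flags[5]
    assert not ev.overall


def test_class2_only_decoy_fails():
    ev = screen_spectrum(
        spectrum([563.2963, 563.2963 - 18.0106, 563.2963 - 36.0211]), 563.2963
    )
    assert not ev.overall


# --- A-ring inference ------------------------------------------------------


def test_a_ring_one_lactone_one_hydroxyl():
    """Ladder pattern of the m/z 583.3225 worked example."""
    p = 583.3225
    anchor = p - GLUCOSE_LOSS - DMA_LOSS  # 376.2118
    assert anchor == pytest.approx(376.2119, abs=5e-4)
    ms2 = spectrum([p, 421.2697, anchor, anchor - 18.0106, anchor - 46.0055], precursor=p)
    inf = infer_a_ring(ms2, p)
    assert (inf.lactone, inf.hydroxyls) == (1, 1)


def test_a_ring_one_lactone_two_hydroxyls_with_combined_loss():
    """Pattern of the m/z 581.3068 worked example: H2O, HCOOH, CO2+2H2O."""
    p = 581.3068
    anchor = p - GLUCOSE_LOSS - DMA_LOSS  # 374.1962
    assert anchor == pytest.approx(374.1962, abs=5e-4)
    comb = 43.9898 + 2 * 18.0106
    ms2 = spectrum(
        [p, anchor, anchor - 18.0106, anchor - 18.0106 - 46.0055,
         anchor - 18.0106 - 46.0055 - comb],
        precursor=p,
    )
    inf = infer_a_ring(ms2, p)
    assert (inf.lactone, inf.hydroxyls) == (1, 2)


def test_a_ring_two_sequential_waters():
    """Pattern of the m/z 611.3174 worked example: 2xH2O then HCOOH."""
    p = 611.3174
    anchor = p - GLUCOSE_LOSS - DMA_LOSS  # 404.2068
    assert anchor == pytest.approx(404.2068, abs=5e-4)
    ms2 = spectrum(
        [p, anchor, anchor - 18.0106, anchor - 36.0211, anchor - 36.0211 - 46.0055],
        precursor=p,
    )
    inf = infer_a_ring(ms2, p)
    assert (inf.lactone, inf.hydroxyls) == (1, 2)


def test_a_ring_without_anchor_errors():
    ms2 = spectrum([563.2963, 401.2435])
    with pytest.raises(ValueError, match="no anchor"):
        infer_a_ring(ms2, 563.2963)
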