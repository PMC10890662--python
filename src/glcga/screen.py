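"""Light/heavy peak-pair matching and five-class MS/MS rule screening.

The screen implements the two-stage logic of the workflow:

1.  **Peak-pair matching.**  A derivatized Glc-GA appears in both the DMED
    (light) and d4-DMED (heavy) channels.  Because the two labeled aliquots
    are mixed 1:1 and deuteration barely perturbs retention, a genuine
    compound gives co-eluting peaks with RT(light) - RT(heavy) in
    [0, 0.013] min and height ratio light/heavy in [0.76, 1.50].

2.  **Five-class fragmentation rules.**  The HCD spectrum of a labeled
    Glc-GA shows: (1) DMED-related losses/fragments (loss of (CH3)2NH
    45.0578; cations C4H10N+ 72.0808 and C3H6ON+ 72.0444); (2) A-ring
    losses (H2O 18.0106, HCOOH 46.0055, CO2 43.9898); (3) C/D-ring loss of
    C2H4 (28.0313); (4) odd-numbered hydrocarbon cations CxHy+ in m/z
    80-230; (5) loss of the glucosyl unit (162.0528).  Neutral-loss ladders
    are chained from the precursor and from the
    [M - glucose - (CH3)2NH]+ anchor fragment.

The A-ring inference reads lactone/hydroxyl features from the loss ladder
below the anchor: each sequential H2O loss marks one hydroxyl, an HCOOH
(or combined CO2+2H2O) loss marks the 19,10-lactone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .chem_mass import cation_mz, monoisotopic_mass, parse_formula
from .lcms_io import ChromPeak, MS2Spectrum

__all__ = [
    "PairCriteria",
    "PeakPair",
    "LossLibrary",
    "default_loss_library",
    "RuleEvidence",
    "AringInference",
    "match_pairs",
    "annotate_losses",
    "detect_skeleton_series",
    "screen_spectrum",
    "infer_a_ring",
    "ScreenPolicy",
]

_MASS = {
    name: monoisotopic_mass(parse_formula(f))
    for name, f in {
        "H2O": "H2O",
        "HCOOH": "CH2O2",
        "CO2": "CO2",
        "C2H4": "C2H4",
        "(CH3)2NH": "C2H7N",
        "glucose": "C6H10O5",
    }.items()
}
_MASS["CO2+2H2O"] = _MASS["CO2"] + 2 * _MASS["H2O"]

GLUCOSE_LOSS = _MASS["glucose"]  # 162.0528
DMA_LOSS = _MASS["(CH3)2NH"]  # 45.0578


@dataclass(frozen=True)
class PairCriteria:
    """Acceptance window for a light/heavy peak pair."""

    rt_delta: Tuple[float, float] = (0.0, 0.013)  # light - heavy, minutes
    intensity_ratio: Tuple[float, float] = (0.76, 1.50)  # light / heavy

    def __post_init__(self) -> None:
        if self.rt_delta[0] > self.rt_delta[1]:
            raise ValueError("rt_delta bounds out of order")
        if self.intensity_ratio[0] > self.intensity_ratio[1]:
            raise ValueError("intensity_ratio bounds out of order")

    def accepts(self, rt_delta: float, ratio: float) -> bool:
        return (
            self.rt_delta[0] <= rt_delta <= self.rt_delta[1]
            and self.intensity_ratio[0] <= ratio <= self.intensity_ratio[1]
        )


@dataclass
class PeakPair:
    """A matched light/heavy chromatographic peak pair on one channel."""

    light_mz: float
    heavy_mz: float
    light: ChromPeak
    heavy: ChromPeak
    rt_delta: float
    intensity_ratio: float


def match_pairs(
    light_peaks: Sequence[ChromPeak],
    heavy_peaks: Sequence[ChromPeak],
    criteria: PairCriteria = PairCriteria(),
    light_mz: float = 0.0,
    heavy_mz: float = 0.0,
) -> List[PeakPair]:
    """Greedy 1:1 matching of criteria-satisfying (light, heavy) combinations.

    Candidate combinations are ranked by |RT delta|, ties by ratio closest
    to 1; each peak is used at most once.  The result is independent of the
    input ordering of the peak lists.
    """
    combos = []
    for li, lp in enumerate(light_peaks):
        for hi, hp in enumerate(heavy_peaks):
            if hp.height <= 0:
                continue
            delta = lp.rt - hp.rt
            ratio = lp.height / hp.height
            if criteria.accepts(delta, ratio):
                combos.append((abs(delta), abs(ratio - 1.0), lp.rt, hp.rt, li, hi, delta, ratio))
    combos.sort()
    used_light: Set[int] = set()
    used_heavy: Set[int] = set()
    pairs: List[PeakPair] = []
    for _, _, _, _, li, hi, delta, ratio in combos:
        if li in used_light or hi in used_heavy:
            continue
        used_light.add(li)
        used_heavy.add(hi)
        pairs.append(
            PeakPair(
                light_mz=light_mz,
                heavy_mz=heavy_mz,
                light=light_peaks[li],
                heavy=heavy_peaks[hi],
                rt_delta=delta,
                intensity_ratio=ratio,
            )
        )
    pairs.sort(key=lambda p: p.light.rt)
    return pairs


@dataclass(frozen=True)
class LossLibrary:
    """Neutral losses and fragment cations per rule class.

    ``classN_losses`` are neutral-loss masses chained into ladders;
    ``class1_fragments`` are directly observed cations; class 4 is the
    hydrocarbon-skeleton window handled by :func:`detect_skeleton_series`.
    """

    class1_losses: Dict[str, float] = field(
        default_factory=lambda: {"(CH3)2NH": _MASS["(CH3)2NH"]}
    )
    class1_fragments: Dict[str, float] = field(
        default_factory=lambda: {
            "C4H10N+": cation_mz(parse_formula("C4H10N")),
            "C3H6ON+": cation_mz(parse_formula("C3H6ON")),
        }
    )
    class2_losses: Dict[str, float] = field(
        default_factory=lambda: {
            "H2O": _MASS["H2O"],
            "HCOOH": _MASS["HCOOH"],
            "CO2": _MASS["CO2"],
        }
    )
    class3_losses: Dict[str, float] = field(default_factory=lambda: {"C2H4": _MASS["C2H4"]})
    class4_window: Tuple[float, float] = (80.0, 230.0)
    class5_losses: Dict[str, float] = field(default_factory=lambda: {"glucose": _MASS["glucose"]})


def default_loss_library() -> LossLibrary:
    return LossLibrary()


@dataclass
class LossHit:
    """One matched fragment: observed m/z, the loss path that explains it."""

    mz: float
    loss_name: str
    expected_mz: float
    ppm_error: float
    rule_class: int


@dataclass
class RuleEvidence:
    """Per-class fragment evidence for one spectrum."""

    hits: Dict[int, List[LossHit]] = field(default_factory=lambda: {k: [] for k in range(1, 6)})
    flags: Dict[int, bool] = field(default_factory=dict)
    overall: bool = False

    def class_hits(self, rule_class: int) -> List[LossHit]:
        return self.hits.get(rule_class, [])


@dataclass(frozen=True)
class ScreenPolicy:
    """Which rule classes are mandatory, and which form an any-of group."""

    mandatory: Tuple[int, ...] = (5, 1, 2)
    any_of: Tuple[int, ...] = (3, 4)
    min_skeleton_hits: int = 2


def _find_fragment(ms2: MS2Spectrum, target: float, tol_ppm: float) -> Optional[float]:
    half = target * tol_ppm * 1e-6
    idx = np.searchsorted(ms2.mz, target)
    best = None
    for j in (idx - 1, idx):
        if 0 <= j < ms2.mz.size and abs(ms2.mz[j] - target) <= half:
            if best is None or abs(ms2.mz[j] - target) < abs(best - target):
                best = float(ms2.mz[j])
    return best


def annotate_losses(
    ms2: MS2Spectrum,
    precursor_mz: float,
    library: LossLibrary = LossLibrary(),
    tol_ppm: float = 10.0,
    max_depth: int = 4,
) -> RuleEvidence:
    """Annotate a spectrum against the loss library.

    Loss ladders (classes 1, 2, 3, 5 neutral losses) are chained up to
    ``max_depth`` steps, seeded both at the precursor and at the anchor
    fragment [M - glucose - (CH3)2NH]+.  Class-1 fragment cations are
    matched directly; class-4 skeleton fragments via
    :func:`detect_skeleton_series`.
    """
    losses: List[Tuple[str, float, int]] = []
    for name, m in library.class5_losses.items():
        losses.append((name, m, 5))
    for name, m in library.class1_losses.items():
        losses.append((name, m, 1))
    for name, m in library.class2_losses.items():
        losses.append((name, m, 2))
    for name, m in library.class3_losses.items():
        losses.append((name, m, 3))

    anchor = precursor_mz - GLUCOSE_LOSS - DMA_LOSS
    evidence = RuleEvidence()
    seen: Set[int] = set()  # rounded node masses already expanded

    def expand(mass: float, depth: int, path: str) -> None:
        if depth >= max_depth:
            return
        for name, loss_mass, rule_class in losses:
            target = mass - loss_mass
            if target < 40.0:
                continue
            label = f"{path}-{name}" if path else f"-{name}"
            key = int(round(target * 2000))
            observed = _find_fragment(ms2, target, tol_ppm)
            if observed is not None and key not in seen:
                seen.add(key)
                evidence.hits[rule_class].append(
                    LossHit(
                        mz=observed,
                        loss_name=label,
                        expected_mz=target,
                        ppm_error=(observed - target) / target * 1e6,
                        rule_class=rule_class,
                    )
                )
            # chain regardless of whether this intermediate was sampled
            if depth + 1 < max_depth:
                expand(target, depth + 1, label)

    expand(precursor_mz, 0, "[M+H]+")
    expand(anchor, 0, "[M-Glc-(CH3)2NH]+")

    for name, frag_mz in library.class1_fragments.items():
        observed = _find_fragment(ms2, frag_mz, tol_ppm)
        if observed is not None:
            evidence.hits[1].append(
                LossHit(
                    mz=observed,
                    loss_name=name,
                    expected_mz=frag_mz,
                    ppm_error=(observed - frag_mz) / frag_mz * 1e6,
                    rule_class=1,
                )
            )

    for mz, assignment in detect_skeleton_series(ms2, library.class4_window, tol_ppm):
        expected = cation_mz(parse_formula(assignment))
        evidence.hits[4].append(
            LossHit(
                mz=mz,
                loss_name=assignment,
                expected_mz=expected,
                ppm_error=(mz - expected) / expected * 1e6,
                rule_class=4,
            )
        )
    return evidence


def detect_skeleton_series(
    ms2: MS2Spectrum,
    window: Tuple[float, float] = (80.0, 230.0),
    tol_ppm: float = 10.0,
) -> List[Tuple[float, str]]:
    """Annotate fragments in the window as odd-numbered CxHy+ cations.

    "Odd-numbered" is taken as an odd hydrogen count (even-electron
    hydrocarbon cation, odd nominal mass); x ranges 5-18 and y <= 2x+1.
    Returns (observed m/z, "CxHy") for every annotatable fragment.
    """
    out: List[Tuple[float, str]] = []
    lo, hi = window
    for mz in ms2.mz:
        if mz < lo or mz > hi:
            continue
        best: Optional[Tuple[float, str]] = None
        for x in range(5, 19):
            for y in range(1, 2 * x + 2, 2):  # odd hydrogen counts
                expected = cation_mz(parse_formula(f"C{x}H{y}"))
                err = abs(mz - expected)
                if err <= mz * tol_ppm * 1e-6 and (best is None or err < best[0]):
                    best = (err, f"C{x}H{y}")
        if best is not None:
            out.append((float(mz), best[1]))
    return out


def screen_spectrum(
    ms2: MS2Spectrum,
    precursor_mz: float,
    library: LossLibrary = LossLibrary(),
    policy: ScreenPolicy = ScreenPolicy(),
    tol_ppm: float = 10.0,
) -> RuleEvidence:
    """Apply the five-class screen; overall pass per the configured policy.

    Default policy: classes 5 (glucose loss), 1 (DMED) and 2 (A-ring) are
    mandatory; at least one of classes 3 (C/D-ring) or 4 (skeleton) must
    also fire.
    """
    evidence = annotate_losses(ms2, precursor_mz, library, tol_ppm)
    for rule_class in range(1, 6):
        n = len(evidence.hits[rule_class])
        if rule_class == 4:
            evidence.flags[rule_class] = n >= policy.min_skeleton_hits
        else:
            evidence.flags[rule_class] = n >= 1
    ok_mandatory = all(evidence.flags[c] for c in policy.mandatory)
    ok_any = (not policy.any_of) or any(evidence.flags[c] for c in policy.any_of)
    evidence.overall = ok_mandatory and ok_any
    return evidence


@dataclass
class AringInference:
    """Lactone / hydroxyl features read from the anchor loss ladder."""

    lactone: int
    hydroxyls: int
    anchor_mz: float
    fragments: List[Tuple[str, float]] = field(default_factory=list)


def infer_a_ring(
    ms2: MS2Spectrum,
    precursor_mz: float,
    tol_ppm: float = 10.0,
) -> AringInference:
    """Infer A-ring lactone and hydroxyl counts below the anchor fragment.

    The anchor is [M - glucose - (CH3)2NH]+.  Candidate loss combinations
    (up to 3 H2O, one HCOOH, one combined CO2+2H2O, one CO2; <= 4 steps)
    are searched in the spectrum.  Hydroxyls = max H2O units lost counting
    the combined loss as one; lactone = 1 if an HCOOH, combined, or
    CO2-with-water loss is present.
    """
    anchor = precursor_mz - GLUCOSE_LOSS - DMA_LOSS
    if _find_fragment(ms2, anchor, tol_ppm) is None:
        raise ValueError("no anchor: [M-Glc-(CH3)2NH]+ fragment absent from spectrum")
    hydroxyls = 0
    lactone = 0
    found: List[Tuple[str, float]] = [("anchor", anchor)]
    for n_h2o, n_hcooh, n_comb, n_co2 in itertools.product(
        range(0, 4), range(0, 2), range(0, 2), range(0, 2)
    ):
        steps = n_h2o + n_hcooh + n_comb + n_co2
        if steps < 1 or steps > 4:
            continue
        target = (
            anchor
            - n_h2o * _MASS["H2O"]
            - n_hcooh * _MASS["HCOOH"]
            - n_comb * _MASS["CO2+2H2O"]
            - n_co2 * _MASS["CO2"]
        )
        if target < 40.0:
            continue
        observed = _find_fragment(ms2, target, tol_ppm)
        if observed is None:
            continue
        label = "-".join(
            ["H2O"] * n_h2o + ["HCOOH"] * n_hcooh + ["CO2+2H2O"] * n_comb + ["CO2"] * n_co2
        )
        found.append((label, observed))
        hydroxyls = max(hydroxyls, n_h2o + n_comb)
        if n_hcooh or n_comb or (n_co2 and n_h2o):
            lactone = 1
    return AringInference(lactone=lactone, hydroxyls=hydroxyls, anchor_mz=anchor, fragments=found)
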