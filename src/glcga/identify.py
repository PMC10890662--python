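"""Four-step structural identification of screened Glc-GA peak pairs.

After a peak pair passes the five-class MS/MS screen, candidates are
narrowed in four steps:

1.  **Assignment** — all registry candidates on the pair's mass channel.
2.  **Fragmentation consistency** — the A-ring lactone/hydroxyl features
    inferred from the anchor loss ladder must be compatible with each
    candidate's structural annotation (lactone flags equal; annotated
    hydroxyls >= inferred).
3.  **Retention-index filter** — candidates with a predicted RI for the
    DMED-labeled parent GA are retained only if
    RI(exp) < RI(pred) + threshold; candidates without a prediction are
    retained with a warning.
4.  **Standard check** — where a reference MS2 spectrum of the parent GA's
    DMED product exists, a low spectral similarity removes the candidate
    and a high one flags it as supported.

The surviving sets are nested by construction and reported per compound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .candidate_db import CandidateChannel, GARecord
from .lcms_io import MS2Spectrum, Run, detect_peaks, extract_xic, ms2_near
from .qsrr import EQ1_THRESHOLD, CalibrationSeries, eq1_filter, rt_to_ri
from .screen import (
    AringInference,
    LossLibrary,
    PairCriteria,
    PeakPair,
    RuleEvidence,
    ScreenPolicy,
    infer_a_ring,
    match_pairs,
    screen_spectrum,
)

__all__ = [
    "StandardSpectrum",
    "IdentificationRecord",
    "PipelineConfig",
    "step2_fragmentation_consistent",
    "step3_ri_filter",
    "spectral_similarity",
    "step4_standard_check",
    "run_pipeline",
    "identify_candidates",
    "records_to_frame",
    "replay_worked_examples",
]


@dataclass
class StandardSpectrum:
    """Reference MS2 spectrum of a derivatized GA standard."""

    name: str
    spectrum: MS2Spectrum


@dataclass
class IdentificationRecord:
    """One screened compound and its nested candidate sets after each step."""

    compound_id: int
    light_mz: float
    heavy_mz: float
    rt: float
    ri: float
    assigned: List[str]
    step2: List[str]
    step3: List[str]
    step4: List[str]
    supported: List[str] = field(default_factory=list)
    inference: Optional[AringInference] = None
    evidence: Optional[RuleEvidence] = None
    pair: Optional[PeakPair] = None


def step2_fragmentation_consistent(
    candidates: Sequence[str],
    inference: AringInference,
    registry: Mapping[str, GARecord],
) -> List[str]:
    """Keep candidates whose A-ring annotation matches the inference.

    Compatibility: the annotated lactone flag equals the inferred one, and
    the annotated A-ring hydroxyl count is at least the inferred count.
    """
    kept = []
    for name in candidates:
        rec = registry.get(name)
        if rec is None:
            warnings.warn(f"candidate {name} missing from registry; kept")
            kept.append(name)
            continue
        if bool(rec.lactone) == bool(inference.lactone) and rec.hydroxyls >= inference.hydroxyls:
            kept.append(name)
    return kept


def step3_ri_filter(
    candidates: Sequence[str],
    ri_exp: float,
    predictions: Mapping[str, float],
    threshold: float = EQ1_THRESHOLD,
) -> List[str]:
    """Apply the retention filter per candidate; missing predictions retain."""
    kept = []
    for name in candidates:
        if name not in predictions:
            warnings.warn(f"no predicted RI for {name}; retained")
            kept.append(name)
        elif eq1_filter(ri_exp, predictions[name], threshold):
            kept.append(name)
    return kept


def spectral_similarity(a: MS2Spectrum, b: MS2Spectrum, tol: float = 0.01) -> float:
    """Cosine similarity over tolerance-matched fragments, sqrt intensities.

    Fragments are greedily matched by closeness within an absolute m/z
    tolerance (Da); the score is the matched dot product over the product of
    the full-spectrum norms, so it lies in [0, 1]: 1 for identical spectra,
    0 for disjoint fragment sets.
    """
    if a.mz.size == 0 or b.mz.size == 0:
        raise ValueError("spectra must be non-empty")
    wa = np.sqrt(np.maximum(a.intensity, 0.0))
    wb = np.sqrt(np.maximum(b.intensity, 0.0))
    na = float(np.linalg.norm(wa))
    nb = float(np.linalg.norm(wb))
    if na == 0.0 or nb == 0.0:
        return 0.0
    # all in-tolerance pairs, closest first, each fragment used once
    pairs: List[Tuple[float, int, int]] = []
    for i, mz in enumerate(a.mz):
        lo = np.searchsorted(b.mz, mz - tol, side="left")
        hi = np.searchsorted(b.mz, mz + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(mz - b.mz[j]), i, j))
    pairs.sort()
    used_a, used_b = set(), set()
    score = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += wa[i] * wb[j]
    return float(score / (na * nb))


def step4_standard_check(
    candidates: Sequence[str],
    compound_ms2: Optional[MS2Spectrum],
    standards: Mapping[str, MS2Spectrum],
    reject_below: float = 0.5,
    support_above: float = 0.8,
    tol: float = 0.01,
) -> Tuple[List[str], Dict[str, float]]:
    """Compare against available GA-standard spectra.

    A candidate whose parent standard scores below ``reject_below`` is
    removed; above ``support_above`` it is flagged as supported; candidates
    without a standard (or without a compound spectrum) are untouched.
    Returns (kept candidates, name -> score for candidates with standards).
    """
    if compound_ms2 is None or not standards:
        return list(candidates), {}
    kept = []
    scores: Dict[str, float] = {}
    for name in candidates:
        std = standards.get(name)
        if std is None:
            kept.append(name)
            continue
        score = spectral_similarity(compound_ms2, std, tol)
        scores[name] = score
        if score >= reject_below:
            kept.append(name)
    return kept, scores


@dataclass
class PipelineConfig:
    """Everything the four-step pipeline needs besides the run itself."""

    registry: Mapping[str, GARecord]
    calibration: CalibrationSeries
    predictions: Mapping[str, float] = field(default_factory=dict)
    standards: Mapping[str, MS2Spectrum] = field(default_factory=dict)
    criteria: PairCriteria = field(default_factory=PairCriteria)
    library: LossLibrary = field(default_factory=LossLibrary)
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)
    ms1_tol_ppm: float = 10.0
    ms2_tol_ppm: float = 10.0
    rt_window: float = 0.2
    min_snr: float = 3.0
    min_points: int = 5
    eq1_threshold: float = EQ1_THRESHOLD
    reject_below: float = 0.5
    support_above: float = 0.8
    similarity_tol: float = 0.01

    def with_yaml_overrides(self, path) -> "PipelineConfig":
        """Return a copy with criteria/policy/tolerances overridden from YAML.

        Recognized keys: rt_delta [lo, hi], intensity_ratio [lo, hi],
        mandatory_classes, any_of_classes, and any scalar field name
        (ms1_tol_ppm, eq1_threshold, min_snr, ...).
        """
        import dataclasses

        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        updates = {}
        if "rt_delta" in raw or "intensity_ratio" in raw:
            updates["criteria"] = PairCriteria(
                rt_delta=tuple(raw.get("rt_delta", self.criteria.rt_delta)),
                intensity_ratio=tuple(raw.get("intensity_ratio", self.criteria.intensity_ratio)),
            )
        if "mandatory_classes" in raw or "any_of_classes" in raw:
            updates["policy"] = ScreenPolicy(
                mandatory=tuple(raw.get("mandatory_classes", self.policy.mandatory)),
                any_of=tuple(raw.get("any_of_classes", self.policy.any_of)),
                min_skeleton_hits=raw.get("min_skeleton_hits", self.policy.min_skeleton_hits),
            )
        scalar_fields = {
            f.name for f in dataclasses.fields(self) if f.name not in updates
        }
        for key, value in raw.items():
            if key in scalar_fields and not isinstance(value, (dict, list)):
                updates[key] = value
        return dataclasses.replace(self, **updates)


def identify_candidates(
    assigned: Sequence[str],
    inference: AringInference,
    ri_exp: float,
    config: PipelineConfig,
    compound_ms2: Optional[MS2Spectrum] = None,
) -> Tuple[List[str], List[str], List[str], List[str]]:
    """Steps 2-4 for one compound; returns the nested candidate sets."""
    step2 = step2_fragmentation_consistent(assigned, inference, config.registry)
    step3 = step3_ri_filter(step2, ri_exp, config.predictions, config.eq1_threshold)
    step4, scores = step4_standard_check(
        step3,
        compound_ms2,
        config.standards,
        config.reject_below,
        config.support_above,
        config.similarity_tol,
    )
    supported = [n for n, s in scores.items() if s >= config.support_above and n in step4]
    return step2, step3, step4, supported


def run_pipeline(
    run: Run,
    channels: Sequence[CandidateChannel],
    config: PipelineConfig,
) -> List[IdentificationRecord]:
    """Peak pairs -> five-class MS2 screen -> four-step identification.

    Deterministic given identical inputs.  Pairs without a matching MS2,
    failing the screen, or lacking the anchor fragment yield no record.
    """
    accepted: List[Tuple[float, CandidateChannel, PeakPair, RuleEvidence, AringInference, MS2Spectrum]] = []
    for channel in channels:
        light_trace = extract_xic(run, channel.light_mz, config.ms1_tol_ppm)
        heavy_trace = extract_xic(run, channel.heavy_mz, config.ms1_tol_ppm)
        light_peaks = detect_peaks(light_trace, config.min_snr, config.min_points)
        heavy_peaks = detect_peaks(heavy_trace, config.min_snr, config.min_points)
        pairs = match_pairs(
            light_peaks, heavy_peaks, config.criteria, channel.light_mz, channel.heavy_mz
        )
        for pair in pairs:
            ms2 = ms2_near(
                run, channel.light_mz, pair.light.rt, config.ms2_tol_ppm, config.rt_window
            )
            if ms2 is None:
                continue
            evidence = screen_spectrum(
                ms2, channel.light_mz, config.library, config.policy, config.ms2_tol_ppm
            )
            if not evidence.overall:
                continue
            inference = infer_a_ring(ms2, channel.light_mz, config.ms2_tol_ppm)
            accepted.append((pair.light.rt, channel, pair, evidence, inference, ms2))

    accepted.sort(key=lambda t: (t[0], t[1].light_mz))
    records: List[IdentificationRecord] = []
    for compound_id, (rt, channel, pair, evidence, inference, ms2) in enumerate(accepted, 1):
        ri_exp = rt_to_ri(rt, config.calibration)
        assigned = channel.parent_names
        step2, step3, step4, supported = identify_candidates(
            assigned, inference, ri_exp, config, ms2
        )
        records.append(
            IdentificationRecord(
                compound_id=compound_id,
                light_mz=channel.light_mz,
                heavy_mz=channel.heavy_mz,
                rt=rt,
                ri=ri_exp,
                assigned=list(assigned),
                step2=step2,
                step3=step3,
                step4=step4,
                supported=supported,
                inference=inference,
                evidence=evidence,
                pair=pair,
            )
        )
    return records


def replay_worked_examples(
    compound_ids: Sequence[int] = (1, 2, 10, 11, 12),
) -> Dict[int, IdentificationRecord]:
    """Re-run steps 1-4 on the worked-example fixtures.

    Inputs are the fixture tables (registry, calibration anchors, predicted
    RIs) and the worked-example MS2 spectra; each compound's channel is
    assigned from its spectrum's precursor m/z, the A-ring features are
    inferred from the spectrum, the RI comes from the calibration series,
    and the GA7/GA34 standard fixtures drive the step-4 comparison.
    """
    from . import synth_data
    from .candidate_db import build_channels, candidates_for_mz
    from .chem_mass import DMED_TAG
    from .screen import infer_a_ring as _infer

    registry = {r.name: r for r in synth_data.builtin_registry()}
    channels = build_channels(list(registry.values()))
    config = PipelineConfig(
        registry=registry,
        calibration=synth_data.reference_calibration(),
        predictions=synth_data.predicted_ri_table(),
        standards={name: synth_data.standard_spectrum(name) for name in ("GA7", "GA34")},
    )
    records: Dict[int, IdentificationRecord] = {}
    for cid in compound_ids:
        ms2 = synth_data.compound_spectrum(cid)
        assigned = [c.parent for c in candidates_for_mz(channels, ms2.precursor_mz)]
        inference = _infer(ms2, ms2.precursor_mz, config.ms2_tol_ppm)
        ri_exp = rt_to_ri(ms2.rt, config.calibration)
        step2, step3, step4, supported = identify_candidates(
            assigned, inference, ri_exp, config, ms2
        )
        records[cid] = IdentificationRecord(
            compound_id=cid,
            light_mz=ms2.precursor_mz,
            heavy_mz=ms2.precursor_mz + DMED_TAG.mass_shift,
            rt=ms2.rt,
            ri=ri_exp,
            assigned=assigned,
            step2=step2,
            step3=step3,
            step4=step4,
            supported=supported,
            inference=inference,
        )
    return records


def records_to_frame(records: Sequence[IdentificationRecord]) -> pd.DataFrame:
    """Report table mirroring the candidate-summary layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.compound_id,
                "light_mz": round(r.light_mz, 4),
                "heavy_mz": round(r.heavy_mz, 4),
                "rt_min": round(r.rt, 2),
                "ri": round(r.ri, 2),
                "assigned": ",".join(r.assigned),
                "fragmentation_consistent": ",".join(r.step2),
                "ri_retained": ",".join(r.step3),
                "identification": ",".join(r.step4),
                "supported_by_standard": ",".join(r.supported),
                "rt_delta_min": None if r.pair is None else round(r.pair.rt_delta, 4),
                "intensity_ratio": None if r.pair is None else round(r.pair.intensity_ratio, 3),
                "aring_lactone": None if r.inference is None else r.inference.lactone,
                "aring_hydroxyls": None if r.inference is None else r.inference.hydroxyls,
            }
        )
    return pd.DataFrame(rows)
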