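"""Ground-truthed synthetic LC-MS/MS runs and fixture tables.

The simulator emulates the acquisition the screen was designed for: a
40-min reversed-phase gradient, positive-mode full scans over m/z 300-700,
and DDA MS2 spectra.  Each spiked Glc-GA appears as a pair of Gaussian
elution profiles on its light/heavy channel (heavy = light + 4.0251 Th)
with a small light-minus-heavy RT offset and ~1:1 intensity ratio, plus one
DDA MS2 near the apex containing the candidate's neutral-loss ladder.
Decoys probe each screening criterion independently: intensity-ratio
violations, RT-offset violations, and spectra lacking the glucose loss.

The fixture tables (candidate registry with A-ring annotations, the
(RT, RI) calibration series, predicted retention indices, and worked
example spectra with a matching/non-matching standard) make the four-step
identification replayable end to end without external data.  A-ring
annotations for candidates are synthetic: they encode the structural
classes the published filtering narrative implies, since the full conjugate
registry is not deposited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .candidate_db import GARecord, GlcGACandidate, build_channels, make_candidate
from .chem_mass import DMED_AMIDATION, DMED_TAG, apply_delta, cation_mz, mz_protonated, parse_formula
from .lcms_io import MS1Spectrum, MS2Spectrum, Run, write_mzml
from .qsrr import CalibrationSeries
from .screen import DMA_LOSS, GLUCOSE_LOSS, _MASS

__all__ = [
    "Spike",
    "SimConfig",
    "SpikeTruth",
    "GroundTruth",
    "simulate_run",
    "default_config",
    "builtin_registry",
    "registry_frame",
    "reference_calibration",
    "predicted_ri_table",
    "build_ms2_ladder",
    "compound_spectrum",
    "standard_spectrum",
    "make_fixtures",
]

# ---------------------------------------------------------------------------
# Fixture registry
#
# (name, parent formula, A-ring lactone, A-ring hydroxyls).  Grouped by the
# isobaric channels of the candidate table; annotations are synthetic but
# consistent with the published structural-filtering narrative.

_REGISTRY_ROWS: List[Tuple[str, str, int, int]] = [
    # channel 563.2963 / 567.3214  (parent C19H22O5)
    ("GA5", "C19H22O5", 1, 0),
    ("GA7", "C19H22O5", 1, 1),
    ("GA11", "C19H22O5", 1, 0),
    ("GA31", "C19H22O5", 0, 1),
    ("GA62", "C19H22O5", 1, 1),
    ("GA88", "C19H22O5", 1, 1),
    ("GA95", "C19H22O5", 0, 0),
    ("GA96", "C19H22O5", 0, 1),
    ("GA104", "C19H22O5", 1, 1),
    ("GA105", "C19H22O5", 1, 1),
    ("GA106", "C19H22O5", 1, 1),
    ("GA107", "C19H22O5", 1, 1),
    ("GA108", "C19H22O5", 0, 0),
    ("GA109", "C19H22O5", 0, 1),
    ("GA117", "C19H22O5", 0, 1),
    ("GA121", "C19H22O5", 1, 0),
    ("GA122", "C19H22O5", 0, 0),
    # channel 565.3119 / 569.3370  (parent C19H24O5)
    ("GA4", "C19H24O5", 1, 1),
    ("GA12", "C19H24O5", 0, 0),
    ("GA20", "C19H24O5", 1, 0),
    ("GA40", "C19H24O5", 1, 1),
    ("GA45", "C19H24O5", 0, 1),
    ("GA51", "C19H24O5", 1, 1),
    ("GA61", "C19H24O5", 1, 1),
    ("GA69", "C19H24O5", 0, 1),
    ("GA70", "C19H24O5", 0, 0),
    ("GA84", "C19H24O5", 1, 0),
    ("GA119", "C19H24O5", 1, 1),
    # channel 579.2912 / 583.3163  (parent C19H22O6)
    ("GA3", "C19H22O6", 1, 1),
    ("GA6", "C19H22O6", 1, 1),
    ("GA22", "C19H22O6", 0, 0),
    ("GA30", "C19H22O6", 1, 1),
    ("GA68", "C19H22O6", 1, 1),
    ("GA80", "C19H22O6", 1, 1),
    ("GA92", "C19H22O6", 1, 1),
    ("GA94", "C19H22O6", 0, 1),
    ("GA126", "C19H22O6", 1, 0),
    # channel 581.3068 / 585.3320  (parent C19H24O6)
    ("GA1", "C19H24O6", 1, 1),
    ("GA16", "C19H24O6", 1, 2),
    ("GA29", "C19H24O6", 1, 1),
    ("GA34", "C19H24O6", 1, 2),
    ("GA35", "C19H24O6", 1, 1),
    ("GA47", "C19H24O6", 1, 2),
    ("GA54", "C19H24O6", 1, 2),
    ("GA58", "C19H24O6", 0, 1),
    ("GA60", "C19H24O6", 0, 2),
    ("GA63", "C19H24O6", 0, 1),
    ("GA67", "C19H24O6", 1, 1),
    ("GA71", "C19H24O6", 0, 0),
    ("GA77", "C19H24O6", 1, 1),
    ("GA81", "C19H24O6", 1, 1),
    ("GA90", "C19H24O6", 1, 2),
    ("GA118", "C19H24O6", 0, 1),
    ("GA130", "C19H24O6", 1, 1),
    ("GA131", "C19H24O6", 0, 2),
    ("GA136", "C19H24O6", 1, 1),
    # channel 583.3225 / 587.3476  (parent C19H26O6)
    ("GA2", "C19H26O6", 1, 1),
    ("GA82", "C19H26O6", 1, 1),
    # channel 611.3174 / 615.3425  (parent C20H26O7)
    ("GA13", "C20H26O7", 0, 1),
    ("GA17", "C20H26O7", 0, 1),
    ("GA23", "C20H26O7", 0, 2),
    ("GA46", "C20H26O7", 1, 1),
    ("GA52", "C20H26O7", 1, 2),
    ("GA66", "C20H26O7", 1, 1),
    ("GA99", "C20H26O7", 0, 0),
    ("GA102", "C20H26O7", 1, 1),
    ("GA125", "C20H26O7", 0, 1),
    ("GA129", "C20H26O7", 1, 0),
    # a few additional well-known free GAs outside the reported channels
    ("GA8", "C19H24O7", 1, 2),
    ("GA9", "C19H24O4", 1, 0),
]

#: Predicted retention indices of DMED-labeled parent GAs (fixture table).
_PREDICTED_RI: Dict[str, float] = {
    "GA105": 535.52,
    "GA62": 685.27,
    "GA104": 716.94,
    "GA106": 796.48,
    "GA107": 826.57,
    "GA7": 840.94,
    "GA88": 865.36,
}

#: (RT min, RI) calibration anchors reproducing the reported compound table.
_CALIBRATION: List[Tuple[float, float]] = [
    (7.47, 655.56),
    (8.20, 671.46),
    (8.70, 682.35),
    (8.94, 687.58),
    (9.55, 700.94),
    (10.32, 718.97),
    (10.77, 729.51),
    (10.79, 729.98),
    (11.12, 737.70),
    (12.10, 760.66),
    (13.01, 781.97),
]


def builtin_registry() -> List[GARecord]:
    """The fixture GA registry (one free carboxyl each, predicted RIs where known)."""
    return [
        GARecord(
            name=name,
            formula=parse_formula(f),
            lactone=bool(lactone),
            hydroxyls=oh,
            carboxyls=1,
            predicted_ri=_PREDICTED_RI.get(name),
        )
        for name, f, lactone, oh in _REGISTRY_ROWS
    ]


def registry_frame() -> pd.DataFrame:
    rows = [
        {
            "name": name,
            "formula": f,
            "lactone": lactone,
            "hydroxyls": oh,
            "carboxyls": 1,
            "predicted_ri": _PREDICTED_RI.get(name, ""),
        }
        for name, f, lactone, oh in _REGISTRY_ROWS
    ]
    return pd.DataFrame(rows)


def reference_calibration() -> CalibrationSeries:
    rt, ri = zip(*_CALIBRATION)
    return CalibrationSeries(np.array(rt), np.array(ri))


def predicted_ri_table() -> Dict[str, float]:
    return dict(_PREDICTED_RI)


# ---------------------------------------------------------------------------
# MS2 ladder construction

_SKELETON_CATIONS = ["C7H7", "C8H9", "C10H11", "C11H13"]


def build_ms2_ladder(
    record: GARecord,
    candidate: Optional[GlcGACandidate] = None,
    include_glucose_loss: bool = True,
) -> List[Tuple[float, str, int]]:
    """Theoretical fragment list (m/z, label, rule class) for one candidate.

    Mirrors the characteristic fragmentation of a DMED-labeled Glc-GA:
    glucose loss (class 5), dimethylamine loss and DMED cations (class 1),
    sequential A-ring H2O/HCOOH losses from the anchor per the annotated
    hydroxyl/lactone features (class 2), C2H4 loss (class 3), and
    hydrocarbon skeleton cations (class 4).
    """
    cand = candidate or make_candidate(record)
    precursor = cand.light_mz
    frags: List[Tuple[float, str, int]] = [(precursor, "[M+H]+", 0)]  # residual precursor
    anchor = precursor - GLUCOSE_LOSS - DMA_LOSS
    if include_glucose_loss:
        frags.append((precursor - GLUCOSE_LOSS, "[M+H-Glc]+", 5))
        frags.append((anchor, "[M+H-Glc-(CH3)2NH]+", 1))
        node = anchor
        for k in range(record.hydroxyls):
            node -= _MASS["H2O"]
            frags.append((node, f"anchor-{k + 1}xH2O", 2))
        if record.lactone:
            frags.append((node - _MASS["HCOOH"], "anchor-nH2O-HCOOH", 2))
        frags.append((anchor - _MASS["C2H4"], "anchor-C2H4", 3))
    else:
        # decoy ladder: water losses from the precursor only
        frags.append((precursor - _MASS["H2O"], "[M+H-H2O]+", 2))
        frags.append((precursor - 2 * _MASS["H2O"], "[M+H-2H2O]+", 2))
    frags.append((cation_mz(parse_formula("C4H10N")), "C4H10N+", 1))
    for symbol in _SKELETON_CATIONS:
        frags.append((cation_mz(parse_formula(symbol)), symbol + "+", 4))
    return frags


# ---------------------------------------------------------------------------
# Simulator


@dataclass(frozen=True)
class Spike:
    """One spiked compound (or decoy) in a simulated run."""

    parent: str  # registry GA name
    rt: float  # light-channel apex, minutes
    height: float = 2.0e5
    width: float = 0.05  # Gaussian sigma, minutes
    rt_offset: float = 0.005  # light - heavy apex offset, minutes
    ratio: float = 1.0  # light/heavy height ratio
    decoy: str = ""  # "", "ratio", "rt", or "ladder"


@dataclass
class SimConfig:
    """Synthetic-run settings; defaults mirror the acquisition conditions
    the method targets (40-min gradient, m/z 300-700 full scans)."""

    seed: int
    gradient_min: float = 40.0
    scan_rate_hz: float = 2.0
    mz_range: Tuple[float, float] = (300.0, 700.0)
    noise_peaks_per_scan: int = 40
    noise_mean_intensity: float = 500.0
    mz_jitter_ppm: float = 2.0
    ms2_base_intensity: float = 1.0e4
    ms2_decay: float = 0.75
    spikes: List[Spike] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for s in self.spikes:
            if not (0 < s.rt < self.gradient_min):
                raise ValueError(f"spike {s.parent}: RT {s.rt} outside gradient")
            if s.width <= 0:
                raise ValueError(f"spike {s.parent}: width must be > 0")


@dataclass
class SpikeTruth:
    """Ground truth for one spike, consistent with the written run."""

    parent: str
    decoy: str
    light_mz: float
    heavy_mz: float
    rt_light: float
    rt_heavy: float
    ratio: float
    fragments: List[Tuple[float, str, int]]


@dataclass
class GroundTruth:
    spikes: List[SpikeTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.spikes], fh, indent=1)


def default_config(seed: int) -> SimConfig:
    """Study conditions: 3 true Glc-GA spikes plus 5 decoys per run.

    Spike RTs sit inside the calibration range; decoys cover the three
    failure modes (intensity ratio, RT offset, missing glucose ladder) on
    channels distinct in RT from the true spikes.
    """
    return SimConfig(
        seed=seed,
        spikes=[
            Spike("GA3", rt=7.47),
            Spike("GA4", rt=8.70),
            Spike("GA52", rt=9.55),
            Spike("GA7", rt=10.32, ratio=3.0, decoy="ratio"),
            Spike("GA34", rt=10.77, rt_offset=0.05, decoy="rt"),
            Spike("GA2", rt=8.70, decoy="ladder"),
            Spike("GA62", rt=12.10, ratio=0.4, decoy="ratio"),
            Spike("GA16", rt=12.50, decoy="ladder"),
        ],
    )


def simulate_run(config: SimConfig) -> Tuple[Run, GroundTruth]:
    """Simulate one LC-MS/MS run; reproducible from the seed.

    MS1 scans carry Gaussian light/heavy elution profiles with Poisson
    counting noise plus uniform random noise peaks; one DDA MS2 is placed
    at the scan nearest each spike apex (fragment ladder per the spike's
    registry annotations; decoy type "ladder" omits the glucose-loss
    branch).
    """
    rng = np.random.default_rng(config.seed)
    registry = {r.name: r for r in builtin_registry()}
    n_scans = int(round(config.gradient_min * 60.0 * config.scan_rate_hz))
    rts = np.arange(n_scans) / (60.0 * config.scan_rate_hz)
    lo, hi = config.mz_range

    truth = GroundTruth()
    signals = []  # (mz, per-scan expected intensity array)
    for spike in config.spikes:
        record = registry[spike.parent]
        cand = make_candidate(record)
        rt_heavy = spike.rt - spike.rt_offset
        heavy_height = spike.height / spike.ratio
        light_profile = spike.height * np.exp(-0.5 * ((rts - spike.rt) / spike.width) ** 2)
        heavy_profile = heavy_height * np.exp(-0.5 * ((rts - rt_heavy) / spike.width) ** 2)
        signals.append((cand.light_mz, light_profile))
        signals.append((cand.heavy_mz, heavy_profile))
        fragments = build_ms2_ladder(record, cand, include_glucose_loss=spike.decoy != "ladder")
        truth.spikes.append(
            SpikeTruth(
                parent=spike.parent,
                decoy=spike.decoy,
                light_mz=cand.light_mz,
                heavy_mz=cand.heavy_mz,
                rt_light=spike.rt,
                rt_heavy=rt_heavy,
                ratio=spike.ratio,
                fragments=fragments,
            )
        )

    ms1: List[MS1Spectrum] = []
    jitter_sd = config.mz_jitter_ppm * 1e-6
    for i in range(n_scans):
        mzs: List[float] = []
        intens: List[float] = []
        if config.noise_peaks_per_scan:
            noise_mz = rng.uniform(lo, hi, size=config.noise_peaks_per_scan)
            noise_int = rng.exponential(config.noise_mean_intensity, size=config.noise_peaks_per_scan)
            mzs.extend(noise_mz)
            intens.extend(noise_int)
        for mz, profile in signals:
            expected = profile[i]
            if expected < 1.0:
                continue
            observed = float(rng.poisson(expected))
            if observed <= 0:
                continue
            mzs.append(mz * (1.0 + rng.normal(0.0, jitter_sd)))
            intens.append(observed)
        order = np.argsort(mzs)
        ms1.append(MS1Spectrum(float(rts[i]), np.asarray(mzs)[order], np.asarray(intens)[order]))

    ms2: List[MS2Spectrum] = []
    for spike_truth in truth.spikes:
        apex_scan = int(np.argmin(np.abs(rts - spike_truth.rt_light)))
        frag_mz = []
        frag_int = []
        for k, (mz, _label, _cls) in enumerate(spike_truth.fragments):
            frag_mz.append(mz * (1.0 + rng.normal(0.0, jitter_sd)))
            frag_int.append(config.ms2_base_intensity * config.ms2_decay**k)
        # a little fragment noise outside the annotation windows
        frag_mz.extend(rng.uniform(240.0, 290.0, size=3))
        frag_int.extend(rng.exponential(100.0, size=3))
        order = np.argsort(frag_mz)
        ms2.append(
            MS2Spectrum(
                precursor_mz=spike_truth.light_mz,
                rt=float(rts[apex_scan]) + 0.25 / (60.0 * config.scan_rate_hz),
                mz=np.asarray(frag_mz)[order],
                intensity=np.asarray(frag_int)[order],
            )
        )
    return Run(ms1=ms1, ms2=ms2), truth


# ---------------------------------------------------------------------------
# Worked-example spectra (replay fixtures)


def _spectrum_from(frag_list: Sequence[Tuple[float, float]], precursor: float, rt: float) -> MS2Spectrum:
    mz, inten = zip(*sorted(frag_list))
    return MS2Spectrum(precursor_mz=precursor, rt=rt, mz=np.array(mz), intensity=np.array(inten))


def compound_spectrum(compound_id: int) -> MS2Spectrum:
    """Theoretical MS2 spectra of worked examples (compounds 1, 2, 10, 11, 12).

    Fragment m/z values are computed from formula arithmetic; intensities
    follow a decreasing profile with the anchor-ladder region dominant so
    the spectra exercise the same inference paths as the published
    examples.
    """
    registry = {r.name: r for r in builtin_registry()}
    h2o, hcooh, comb = _MASS["H2O"], _MASS["HCOOH"], _MASS["CO2+2H2O"]

    def base(parent: str, rt: float, hydroxyl_steps: int, extra: Sequence[Tuple[float, float]] = ()):
        cand = make_candidate(registry[parent])
        p = cand.light_mz
        anchor = p - GLUCOSE_LOSS - DMA_LOSS
        frags = [
            (p, 150.0),
            (p - GLUCOSE_LOSS, 600.0),
            (anchor, 1000.0),
            (anchor - _MASS["C2H4"], 250.0),
            (cation_mz(parse_formula("C4H10N")), 400.0),
            (cation_mz(parse_formula("C7H7")), 350.0),
            (cation_mz(parse_formula("C8H9")), 300.0),
            (cation_mz(parse_formula("C10H11")), 200.0),
        ]
        node = anchor
        for k in range(hydroxyl_steps):
            node -= h2o
            frags.append((node, 800.0 - 100.0 * k))
        frags.append((anchor - hcooh, 500.0))  # parallel lactone loss
        frags.append((node - hcooh, 700.0))
        frags.extend(extra)
        return _spectrum_from(frags, p, rt)

    if compound_id == 1:
        return base("GA104", 10.32, hydroxyl_steps=1)
    if compound_id == 2:
        return base("GA104", 12.10, hydroxyl_steps=1)
    if compound_id == 10:
        cand = make_candidate(registry["GA34"])
        anchor = cand.light_mz - GLUCOSE_LOSS - DMA_LOSS
        extra = [(anchor - h2o - hcooh - comb, 300.0)]
        return base("GA34", 10.77, hydroxyl_steps=1, extra=extra)
    if compound_id == 11:
        return base("GA2", 8.70, hydroxyl_steps=1)
    if compound_id == 12:
        return base("GA52", 9.55, hydroxyl_steps=2)
    raise ValueError(f"no worked-example spectrum for compound {compound_id}")


def standard_spectrum(name: str) -> MS2Spectrum:
    """Reference spectra of derivatized GA standards (fixtures).

    ``GA7``: fragment population disjoint from the worked-example Glc-GA
    spectra (distinct losses and skeleton ions), so similarity scores fall
    below the rejection threshold — a stand-in constructed for the real
    standard, which is not deposited.  ``GA34``: shares the anchor-ladder
    fragments of compound 10, scoring above the support threshold.
    """
    registry = {r.name: r for r in builtin_registry()}
    h2o, hcooh, co2 = _MASS["H2O"], _MASS["HCOOH"], _MASS["CO2"]
    if name == "GA7":
        deriv = apply_delta(registry["GA7"].formula, DMED_AMIDATION)
        p = mz_protonated(deriv)
        frags = [
            (p, 1000.0),
            (p - h2o - co2, 800.0),
            (p - 2 * h2o - co2, 600.0),
            (cation_mz(parse_formula("C7H9")), 500.0),
            (cation_mz(parse_formula("C9H11")), 400.0),
            (cation_mz(parse_formula("C12H15")), 300.0),
        ]
        return _spectrum_from(frags, p, 0.0)
    if name == "GA34":
        compound10 = compound_spectrum(10)
        deriv = apply_delta(registry["GA34"].formula, DMED_AMIDATION)
        p = mz_protonated(deriv)
        keep = compound10.mz <= p + 0.5  # shared sub-precursor fragment region
        frags = list(zip(compound10.mz[keep], compound10.intensity[keep]))
        frags.append((p - _MASS["H2O"], 120.0))
        return _spectrum_from(frags, p, 0.0)
    raise ValueError(f"no standard spectrum fixture for {name}")


def make_fixtures(outdir) -> Dict[str, Path]:
    """Write the fixture bundle (registry, calibration, predicted RIs,
    worked-example spectra, standards) as CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["registry"] = outdir / "ga_registry.csv"
    registry_frame().to_csv(paths["registry"], index=False)

    paths["calibration"] = outdir / "ri_calibration.csv"
    pd.DataFrame(_CALIBRATION, columns=["rt", "ri"]).to_csv(paths["calibration"], index=False)

    paths["predicted_ri"] = outdir / "predicted_ri.csv"
    pd.DataFrame(
        sorted(_PREDICTED_RI.items()), columns=["ga_name", "ri_pred"]
    ).to_csv(paths["predicted_ri"], index=False)

    for cid in (1, 2, 10, 11, 12):
        spec = compound_spectrum(cid)
        p = outdir / f"compound{cid}_ms2.csv"
        pd.DataFrame({"mz": np.round(spec.mz, 4), "intensity": spec.intensity}).to_csv(
            p, index=False
        )
        paths[f"compound{cid}"] = p
    for name in ("GA7", "GA34"):
        spec = standard_spectrum(name)
        p = outdir / f"standard_{name}_ms2.csv"
        pd.DataFrame({"mz": np.round(spec.mz, 4), "intensity": spec.intensity}).to_csv(
            p, index=False
        )
        paths[f"standard_{name}"] = p

    channels = build_channels(builtin_registry())
    from .candidate_db import channels_to_frame
    from .chem_mass import export_element_masses

    paths["channels"] = outdir / "channels.tsv"
    channels_to_frame(channels).to_csv(paths["channels"], sep="\t", index=False)
    paths["element_masses"] = outdir / "element_masses.csv"
    export_element_masses(paths["element_masses"])
    return paths
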