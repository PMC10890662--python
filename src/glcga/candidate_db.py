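"""Candidate-channel table for glucose-conjugated gibberellins.

Every registered GA yields one Glc-GA candidate: the parent formula gains a
glucosyl unit (+C6H10O5), the free carboxyl is amidated by DMED
(+C4H12N2 -H2O), and the protonated ion plus its d4-labeled twin define a
(light m/z, heavy m/z) extraction channel.  GAs with identical formulas are
isobaric and merge into a single channel whose member list mirrors a row of
the candidate table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .chem_mass import (
    DMED_AMIDATION,
    DMED_TAG,
    GLUCOSYLATION,
    Formula,
    IsotopeTagPair,
    apply_delta,
    heavy_mz,
    mz_protonated,
    parse_formula,
)

__all__ = [
    "GARecord",
    "GlcGACandidate",
    "CandidateChannel",
    "load_registry",
    "build_channels",
    "candidates_for_mz",
    "channels_to_frame",
]

_REQUIRED_COLUMNS = ("name", "formula", "lactone", "hydroxyls", "carboxyls")


@dataclass(frozen=True)
class GARecord:
    """A registry entry for one free gibberellin.

    ``lactone`` and ``hydroxyls`` annotate the A-ring (19,10-lactone present;
    number of A-ring hydroxyl groups) and drive the fragmentation-consistency
    filter.  ``carboxyls`` counts free carboxyls available for derivatization;
    a GA whose only carboxyl is blocked (e.g. a glucosyl ester) has 0 and is
    excluded from derivatized channels.
    """

    name: str
    formula: Formula
    lactone: bool
    hydroxyls: int
    carboxyls: int = 1
    predicted_ri: Optional[float] = None

    def __post_init__(self) -> None:
        if self.formula.is_empty:
            raise ValueError(f"{self.name}: empty formula")
        if self.hydroxyls < 0:
            raise ValueError(f"{self.name}: hydroxyl count must be >= 0")
        if self.carboxyls < 0:
            raise ValueError(f"{self.name}: carboxyl count must be >= 0")


@dataclass(frozen=True)
class GlcGACandidate:
    """One glucosylated, DMED-derivatized candidate and its mass channel."""

    parent: str
    native_formula: Formula  # parent + C6H10O5
    derivatized_formula: Formula  # native + C4H12N2 - H2O
    light_mz: float
    heavy_mz: float


@dataclass
class CandidateChannel:
    """An isobaric group of candidates sharing one (light, heavy) channel."""

    light_mz: float
    heavy_mz: float
    members: List[GlcGACandidate] = field(default_factory=list)

    @property
    def parent_names(self) -> List[str]:
        return [m.parent for m in self.members]


def _ga_sort_key(name: str):
    m = re.fullmatch(r"([A-Za-z]+)(\d+)([A-Za-z0-9-]*)", name)
    if m:
        return (m.group(1), int(m.group(2)), m.group(3))
    return (name, 0, "")


def load_registry(path) -> List[GARecord]:
    """Load a GA registry CSV.

    Required columns: name, formula, lactone, hydroxyls, carboxyls; optional
    column predicted_ri.  Duplicate names and unparsable formulas are errors;
    an empty file yields an empty registry with a warning.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"registry {path}: missing column(s) {missing}")
    if frame.empty:
        warnings.warn(f"registry {path} is empty")
        return []
    dupes = frame["name"][frame["name"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"registry {path}: duplicate name(s) {sorted(set(dupes))}")
    records = []
    for row in frame.itertuples(index=False):
        ri = getattr(row, "predicted_ri", None)
        ri = None if ri is None or pd.isna(ri) else float(ri)
        records.append(
            GARecord(
                name=str(row.name),
                formula=parse_formula(str(row.formula)),
                lactone=bool(int(row.lactone)),
                hydroxyls=int(row.hydroxyls),
                carboxyls=int(row.carboxyls),
                predicted_ri=ri,
            )
        )
    return records


def make_candidate(record: GARecord, tag: IsotopeTagPair = DMED_TAG) -> GlcGACandidate:
    """Glucosylate -> derivatize -> protonate -> heavy-shift one GA."""
    native = apply_delta(record.formula, GLUCOSYLATION)
    derivatized = apply_delta(native, DMED_AMIDATION)
    light = mz_protonated(derivatized)
    return GlcGACandidate(
        parent=record.name,
        native_formula=native,
        derivatized_formula=derivatized,
        light_mz=light,
        heavy_mz=heavy_mz(light, tag),
    )


def build_channels(
    registry: Sequence[GARecord],
    tag: IsotopeTagPair = DMED_TAG,
    group_tol: float = 0.001,
) -> List[CandidateChannel]:
    """Build sorted candidate channels, merging isobaric candidates.

    Records without a free carboxyl (``carboxyls == 0``) cannot be
    derivatized and are skipped.
    """
    if not registry:
        raise ValueError("registry is empty")
    candidates = [make_candidate(r, tag) for r in registry if r.carboxyls >= 1]
    candidates.sort(key=lambda c: c.light_mz)
    channels: List[CandidateChannel] = []
    for cand in candidates:
        if channels and cand.light_mz - channels[-1].members[-1].light_mz <= group_tol:
            channels[-1].members.append(cand)
        else:
            channels.append(
                CandidateChannel(light_mz=cand.light_mz, heavy_mz=cand.heavy_mz, members=[cand])
            )
    for ch in channels:
        ch.members.sort(key=lambda c: _ga_sort_key(c.parent))
    return channels


def candidates_for_mz(
    channels: Iterable[CandidateChannel],
    observed_light_mz: float,
    tol_ppm: float = 10.0,
) -> List[GlcGACandidate]:
    """All candidates whose channel matches an observed light m/z within tol."""
    out: List[GlcGACandidate] = []
    for ch in channels:
        if abs(ch.light_mz - observed_light_mz) <= ch.light_mz * tol_ppm * 1e-6:
            out.extend(ch.members)
    return out


def channels_to_frame(channels: Iterable[CandidateChannel]) -> pd.DataFrame:
    """Channel table as a DataFrame (exportable as TSV)."""
    rows = [
        {
            "light_mz": round(ch.light_mz, 4),
            "heavy_mz": round(ch.heavy_mz, 4),
            "members": ",".join(ch.parent_names),
            "native_formula": str(ch.members[0].native_formula),
            "derivatized_formula": str(ch.members[0].derivatized_formula),
        }
        for ch in channels
    ]
    return pd.DataFrame(rows)
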