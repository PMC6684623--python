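"""Chemotype fractions from raw cannabinoid quantification records.

Per-plant fresh-weight contents (mg/g) of the eight fraction-relevant
cannabinoids (CBDVA, THCVA, CBDA, THCA and their decarboxylated forms)
are converted into four percentages of the total cannabinoid fraction:

* ``F_C3`` / ``F_C5`` — propyl vs pentyl alkyl side-chain fraction
  (they sum to 100);
* ``F_dicyclic`` / ``F_tricyclic`` — CBD-type vs THC-type ring fraction
  (they sum to 100).

Neutral cannabinoids are first expressed as their carboxylic-acid
precursors by multiplying by the acid/neutral molecular-weight ratio
(decarboxylation correction), so that post-harvest decarboxylation does
not distort the composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    ANALYTE_PAIRS,
    ANALYTES,
    C3_ACIDS,
    C3_NEUTRALS,
    C5_ACIDS,
    C5_NEUTRALS,
    DICYCLIC_ACIDS,
    DICYCLIC_NEUTRALS,
    TRICYCLIC_ACIDS,
    TRICYCLIC_NEUTRALS,
    AnalytePair,
)

__all__ = [
    "CannabinoidProfile",
    "ChemotypeFractions",
    "ReplicateSummary",
    "acid_equivalent",
    "compute_fractions",
    "average_replicates",
    "replicate_r2",
    "midparent",
]


@dataclass(frozen=True)
class CannabinoidProfile:
    """Fresh-weight cannabinoid content (mg/g) of a single plant (or replicate)."""

    plant_id: str
    generation: str
    content: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.content.items():
            if name not in ANALYTES:
                raise ValueError(f"unknown analyte {name!r}; expected one of {ANALYTES}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"content of {name} must be finite and >= 0, got {value}")

    def get(self, analyte: str) -> float:
        return float(self.content.get(analyte, 0.0))

    @property
    def total(self) -> float:
        return float(sum(self.content.values()))


@dataclass(frozen=True)
class ChemotypeFractions:
    """The four chemotype fractions, in percent of the total cannabinoid fraction."""

    F_C3: float
    F_C5: float
    F_dicyclic: float
    F_tricyclic: float

    def __post_init__(self) -> None:
        for name in ("F_C3", "F_C5", "F_dicyclic", "F_tricyclic"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name} = {v} outside [0, 100]")
        if abs(self.F_C3 + self.F_C5 - 100.0) > 1e-9:
            raise ValueError("F_C3 + F_C5 must equal 100")
        if abs(self.F_dicyclic + self.F_tricyclic - 100.0) > 1e-9:
            raise ValueError("F_dicyclic + F_tricyclic must equal 100")


@dataclass
class ReplicateSummary:
    """Replicate-averaged profile for one plant, plus repeatability diagnostics."""

    plant_id: str
    mean_profile: CannabinoidProfile
    n_replicates: int
    #: per-replicate fractions, used for the population-level r² check
    replicate_fractions: list[ChemotypeFractions] = field(default_factory=list)


def acid_equivalent(neutral_content: float, pair: AnalytePair) -> float:
    """Express a neutral cannabinoid content as its carboxylated acid equivalent.

    Multiplies by acid_mw/neutral_mw (> 1), compensating for the CO2 lost
    on decarboxylation.
    """
    if neutral_content < 0 or not np.isfinite(neutral_content):
        raise ValueError(f"neutral content must be finite and >= 0, got {neutral_content}")
    return neutral_content * pair.correction_factor


def _pools(profile: CannabinoidProfile) -> tuple[float, float, float, float]:
    def eq(name: str) -> float:
        return acid_equivalent(profile.get(name), ANALYTE_PAIRS[name])

    c3 = sum(profile.get(a) for a in C3_ACIDS) + sum(eq(n) for n in C3_NEUTRALS)
    c5 = sum(profile.get(a) for a in C5_ACIDS) + sum(eq(n) for n in C5_NEUTRALS)
    di = sum(profile.get(a) for a in DICYCLIC_ACIDS) + sum(eq(n) for n in DICYCLIC_NEUTRALS)
    tri = sum(profile.get(a) for a in TRICYCLIC_ACIDS) + sum(eq(n) for n in TRICYCLIC_NEUTRALS)
    return c3, c5, di, tri


def compute_fractions(profile: CannabinoidProfile) -> ChemotypeFractions:
    """Compute F_C3/F_C5 and F_dicyclic/F_tricyclic from one profile.

    All contents are pooled as acid equivalents; each fraction is
    100 × pool / total. Raises ``ValueError`` on an all-zero profile,
    whose chemotype is undefined.
    """
    c3, c5, di, tri = _pools(profile)
    total = c3 + c5
    if total <= 0:
        raise ValueError(
            f"plant {profile.plant_id}: all analyte contents are zero; chemotype undefined"
        )
    f_c3 = min(max(100.0 * c3 / total, 0.0), 100.0)
    f_di = min(max(100.0 * di / total, 0.0), 100.0)
    return ChemotypeFractions(
        F_C3=f_c3,
        F_C5=100.0 - f_c3,
        F_dicyclic=f_di,
        F_tricyclic=100.0 - f_di,
    )


def average_replicates(records: Sequence[CannabinoidProfile]) -> ReplicateSummary:
    """Analyte-wise arithmetic mean of extraction replicates for one plant.

    Contents are averaged first and fractions derived from the mean
    profile; per-replicate fractions are retained for the repeatability
    (r²) check across the plant set.
    """
    if len(records) == 0:
        raise ValueError("at least one replicate record is required")
    ids = {r.plant_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"mixed plant_ids in replicate set: {sorted(ids)}")
    mean_content = {
        a: float(np.mean([r.get(a) for r in records]))
        for a in ANALYTES
        if any(a in r.content for r in records)
    }
    mean_profile = CannabinoidProfile(records[0].plant_id, records[0].generation, mean_content)
    rep_fracs = []
    for r in records:
        try:
            rep_fracs.append(compute_fractions(r))
        except ValueError:
            warnings.warn(f"plant {r.plant_id}: zero-total replicate skipped in r2 check")
    return ReplicateSummary(records[0].plant_id, mean_profile, len(records), rep_fracs)


def replicate_r2(summaries: Iterable[ReplicateSummary], axis: str = "F_C3") -> float:
    """Coefficient of determination between duplicate extractions across plants.

    Requires exactly two replicates per plant; ``axis`` is one of the four
    fraction names. Returns r² of replicate 1 vs replicate 2 over the
    plant set.
    """
    first, second = [], []
    for s in summaries:
        if len(s.replicate_fractions) != 2:
            raise ValueError(
                f"plant {s.plant_id}: r2 requires exactly 2 replicates, got "
                f"{len(s.replicate_fractions)}"
            )
        first.append(getattr(s.replicate_fractions[0], axis))
        second.append(getattr(s.replicate_fractions[1], axis))
    if len(first) < 2:
        raise ValueError("r2 requires at least two plants")
    r = np.corrcoef(first, second)[0, 1]
    return float(r * r)


def midparent(p1: float, p2: float) -> float:
    """Mid-parent value: the additive-inheritance expectation for hybrids."""
    for p in (p1, p2):
        if not (0 <= p <= 100):
            raise ValueError(f"parent value {p} outside [0, 100]")
    return (p1 + p2) / 2.0
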