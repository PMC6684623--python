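"""Analyte tables: molecular weights and neutral/acid cannabinoid pairs.

Average molecular weights are derived from molecular formulas using
IUPAC 2021 standard atomic weights, so the decarboxylation-correction
factors are reproducible from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: Molecular formulas of the eight fraction-relevant cannabinoids.
MOLECULAR_FORMULAS: dict[str, dict[str, int]] = {
    # pentyl (C5) series
    "CBD": {"C": 21, "H": 30, "O": 2},
    "CBDA": {"C": 22, "H": 30, "O": 4},
    "THC": {"C": 21, "H": 30, "O": 2},
    "THCA": {"C": 22, "H": 30, "O": 4},
    # propyl (C3) series
    "CBDV": {"C": 19, "H": 26, "O": 2},
    "CBDVA": {"C": 20, "H": 26, "O": 4},
    "THCV": {"C": 19, "H": 26, "O": 2},
    "THCVA": {"C": 20, "H": 26, "O": 4},
}


def molecular_weight(formula: dict[str, int]) -> float:
    """Average molecular weight (g/mol) of a molecular formula."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


MOLECULAR_WEIGHTS = {name: molecular_weight(f) for name, f in MOLECULAR_FORMULAS.items()}

MW_CO2 = molecular_weight({"C": 1, "O": 2})


@dataclass(frozen=True)
class AnalytePair:
    """A neutral cannabinoid and its carboxylated acid precursor.

    Carboxylation adds one CO2, so ``acid_mw - neutral_mw`` must equal
    MW(CO2) to within rounding of the atomic weights.
    """

    neutral_name: str
    acid_name: str
    neutral_mw: float
    acid_mw: float

    def __post_init__(self) -> None:
        if abs((self.acid_mw - self.neutral_mw) - MW_CO2) > 0.02:
            raise ValueError(
                f"{self.acid_name} is not {self.neutral_name} + CO2: "
                f"ΔMW = {self.acid_mw - self.neutral_mw:.3f}, expected {MW_CO2:.3f}"
            )

    @property
    def correction_factor(self) -> float:
        return self.acid_mw / self.neutral_mw


def _pair(neutral: str, acid: str) -> AnalytePair:
    return AnalytePair(neutral, acid, MOLECULAR_WEIGHTS[neutral], MOLECULAR_WEIGHTS[acid])


#: The four neutral→acid pairs used for decarboxylation correction.
ANALYTE_PAIRS: dict[str, AnalytePair] = {
    "CBD": _pair("CBD", "CBDA"),
    "THC": _pair("THC", "THCA"),
    "CBDV": _pair("CBDV", "CBDVA"),
    "THCV": _pair("THCV", "THCVA"),
}

#: Canonical analyte order for the eight fraction-relevant cannabinoids.
ANALYTES = ("CBDVA", "THCVA", "CBDA", "THCA", "CBDV", "THCV", "CBD", "THC")

#: Analytes accepted in input files but excluded from all four pools.
OTHER_ANALYTES = ("CBN", "CBG", "CBGA", "CBC")

# acid-equivalent pool membership
C3_ACIDS = ("CBDVA", "THCVA")
C5_ACIDS = ("CBDA", "THCA")
C3_NEUTRALS = ("CBDV", "THCV")
C5_NEUTRALS = ("CBD", "THC")
DICYCLIC_ACIDS = ("CBDVA", "CBDA")
TRICYCLIC_ACIDS = ("THCVA", "THCA")
DICYCLIC_NEUTRALS = ("CBDV", "CBD")
TRICYCLIC_NEUTRALS = ("THCV", "THC")
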