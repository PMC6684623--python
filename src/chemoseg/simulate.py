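"""Synthetic F2 cross simulator for chemotype-inheritance studies.

Simulates a biparental cross between two plants divergent for alkyl
(C3 vs C5 side-chain) and cyclic (CBD- vs THC-type) cannabinoid
composition: homozygous parents, an F1 hybrid family, and an F2
population from a single F1×F1 cross. Plants segregate at two
alkyl-determining loci (A1, A2) and the codominant cannabinoid-synthase
locus B, with configurable gene action (additive 1:4:6:4:1, digenic
dominant 9:3:3:1, or the recessive-epistatic 7:6:3 model), pairwise
linkage, and Gaussian phenotype noise. A SCAR-style marker locus linked
to B at a configurable recombination fraction provides the genotype
calls, so marker/locus discordance can be studied.

The emitted dataset has the statistical structure the analysis pipeline
assumes: multimodal F_C3 distributions (pentapartite under the additive
model) and a tripartite F_dicyclic distribution governed by the B locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from .fractions import ChemotypeFractions

__all__ = [
    "LocusSpec",
    "PlantGenotype",
    "GeneActionModel",
    "StudyConfig",
    "SimPlant",
    "SimulatedStudy",
    "default_loci",
    "make_gamete",
    "cross",
    "phenotype_class",
    "enumerate_class_probabilities",
    "phenotype",
    "scar_genotype",
    "simulate_f2_study",
]

#: allele labels per locus: (C3-type / CBDAS-type first is NOT implied;
#: conventions are per-locus, see default_loci)
A1_C3, A1_C5 = "A1_C3", "A1_C5"
A2_C3, A2_C5 = "A2_C3", "A2_C5"
B_THCAS, B_CBDAS = "THCAS", "CBDAS"
M_THCAS, M_CBDAS = "m_THCAS", "m_CBDAS"


@dataclass(frozen=True)
class LocusSpec:
    """A biallelic locus with its linkage relation to the previous locus."""

    name: str
    alleles: tuple[str, str]
    linkage_group: str = "0"
    recomb_to_prev: float = 0.5  # r to the previous locus in the ordered list

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_to_prev <= 0.5:
            raise ValueError(f"recombination fraction must be in [0, 0.5], got {self.recomb_to_prev}")


def default_loci(
    r_a1_a2: float = 0.5, r_a1_b: float = 0.5, marker_r: float = 0.0
) -> list[LocusSpec]:
    """Ordered locus chain A2 — A1 — B — marker with pairwise recombination.

    ``r_a1_a2`` links the two alkyl loci, ``r_a1_b`` links A1 to the
    synthase locus B, and ``marker_r`` is the SCAR-marker distance to B.
    An r of 0.5 means unlinked (the default for all but the marker).
    """
    return [
        LocusSpec("A2", (A2_C3, A2_C5), "g1"),
        LocusSpec("A1", (A1_C3, A1_C5), "g1", r_a1_a2),
        LocusSpec("B", (B_THCAS, B_CBDAS), "g1", r_a1_b),
        LocusSpec("marker", (M_THCAS, M_CBDAS), "g1", marker_r),
    ]


@dataclass(frozen=True)
class PlantGenotype:
    """Phased genotype: one maternal and one paternal haplotype over the loci."""

    plant_id: str
    maternal_haplotype: tuple[str, ...]
    paternal_haplotype: tuple[str, ...]
    sex: str = "unknown"  # recorded, no genetic effect

    def __post_init__(self) -> None:
        if len(self.maternal_haplotype) != len(self.paternal_haplotype):
            raise ValueError("haplotypes must cover the same loci")

    def alleles_at(self, locus_index: int) -> tuple[str, str]:
        return (self.maternal_haplotype[locus_index], self.paternal_haplotype[locus_index])


def make_gamete(
    genotype: PlantGenotype, loci: Sequence[LocusSpec], rng: np.random.Generator
) -> tuple[str, ...]:
    """One meiotic gamete by two-point recombination without interference.

    The first locus comes from either haplotype with probability 1/2; each
    subsequent locus switches source haplotype with probability equal to
    its recombination fraction to the previous locus (loci on different
    linkage groups behave as r = 0.5).
    """
    haplos = (genotype.maternal_haplotype, genotype.paternal_haplotype)
    source = int(rng.integers(2))
    gamete = [haplos[source][0]]
    for i, locus in enumerate(loci[1:], start=1):
        r = locus.recomb_to_prev if locus.linkage_group == loci[i - 1].linkage_group else 0.5
        if rng.random() < r:
            source = 1 - source
        gamete.append(haplos[source][i])
    return tuple(gamete)


def cross(
    mother: PlantGenotype,
    father: PlantGenotype,
    n_offspring: int,
    loci: Sequence[LocusSpec],
    rng: np.random.Generator,
    id_prefix: str = "X",
) -> list[PlantGenotype]:
    """Produce offspring genotypes: one maternal and one paternal gamete each."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    offspring = []
    for i in range(1, n_offspring + 1):
        egg = make_gamete(mother, loci, rng)
        pollen = make_gamete(father, loci, rng)
        sex = "female" if rng.random() < 0.5 else "male"
        offspring.append(PlantGenotype(f"{id_prefix}-{i:03d}", egg, pollen, sex))
    return offspring


@dataclass(frozen=True)
class GeneActionModel:
    """Genotype→phenotype map for the alkyl (A1, A2) and synthase (B) loci.

    ``class_means_FC3`` gives the mean F_C3 per phenotype class (percent,
    strictly increasing): 5 classes for additive gene action, 4 for
    digenic dominant, 3 for the epistatic 7:6:3 model.
    ``b_class_means_Fdi`` gives mean F_dicyclic for the B genotypes
    (THCAS/THCAS, THCAS/CBDAS, CBDAS/CBDAS). ``logit_skew`` applies the
    within-class noise on the logit scale instead, producing fraction
    distributions skewed away from 50.
    """

    kind: str
    class_means_FC3: tuple[float, ...]
    noise_sd: float
    b_class_means_Fdi: tuple[float, float, float]
    b_noise_sd: float
    logit_skew: bool = False

    _N_CLASSES = {"additive": 5, "digenic_dominant": 4, "epistatic_7_6_3": 3}

    def __post_init__(self) -> None:
        if self.kind not in self._N_CLASSES:
            raise ValueError(f"unknown gene action kind {self.kind!r}")
        k = self._N_CLASSES[self.kind]
        if len(self.class_means_FC3) != k:
            raise ValueError(f"{self.kind} gene action needs {k} class means")
        means = self.class_means_FC3
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("class means must be strictly increasing")
        for m in list(means) + list(self.b_class_means_Fdi):
            if not 0 <= m <= 100:
                raise ValueError("class means must lie in [0, 100]")

    @property
    def n_classes(self) -> int:
        return self._N_CLASSES[self.kind]


def _c3_dosage(genotype: PlantGenotype, locus_index: int, c3_allele: str) -> int:
    return sum(1 for a in genotype.alleles_at(locus_index) if a == c3_allele)


def phenotype_class(
    genotype: PlantGenotype,
    model: GeneActionModel,
    loci: Sequence[LocusSpec] | None = None,
) -> int:
    """Phenotype class index (ordered by increasing mean F_C3) for a genotype.

    * additive — the count of C3 alleles across A1 and A2 (0–4);
    * digenic dominant — C5 alleles dominant at both loci, so any plant
      carrying a C5 allele at a locus expresses C5 there; the double
      C3-homozygote (class 3) is the F_C3 maximum (F2 expectation 9:3:3:1);
    * epistatic 7:6:3 — the C3 allele is dominant at A1 and partially
      dominant at A2; a plant homozygous for the recessive C5 allele at
      A1 is forced into the lowest class regardless of A2 (recessive
      epistasis), otherwise the class is the A2 C3-allele dosage
      (F2 expectation 7:6:3).
    """
    loci = loci if loci is not None else default_loci()
    idx = {locus.name: i for i, locus in enumerate(loci)}
    a1 = _c3_dosage(genotype, idx["A1"], A1_C3)
    a2 = _c3_dosage(genotype, idx["A2"], A2_C3)
    if model.kind == "additive":
        return a1 + a2
    if model.kind == "digenic_dominant":
        # C5 dominant: dominant phenotype at a locus unless C3-homozygous
        a1_rec, a2_rec = a1 == 2, a2 == 2
        return {(False, False): 0, (False, True): 1, (True, False): 2, (True, True): 3}[
            (a1_rec, a2_rec)
        ]
    if model.kind == "epistatic_7_6_3":
        if a1 == 0:  # homozygous recessive at A1 is epistatic to A2
            return 0
        return {0: 0, 1: 1, 2: 2}[a2]
    raise ValueError(f"unknown gene action kind {model.kind!r}")


def enumerate_class_probabilities(kind: str):
    """Exact F2 class probabilities by brute force over all 16 gamete combinations.

    Both F1 parents are heterozygous at A1 and A2; each transmits one of
    four equally likely two-locus gametes (linkage does not alter the
    16-combination enumeration when both parents carry coupling
    haplotypes in identical phase — the per-gamete marginal allele
    probabilities stay 1/2 each; unlinked loci are assumed here).
    Returns a list of :class:`fractions.Fraction` summing to 1, ordered
    by class index.
    """
    from fractions import Fraction

    model = GeneActionModel(
        kind,
        tuple(np.linspace(1, 99, GeneActionModel._N_CLASSES[kind])),
        0.0,
        (1.0, 50.0, 99.0),
        0.0,
    )
    loci = default_loci()
    gametes = [
        (a1, a2) for a1 in (A1_C3, A1_C5) for a2 in (A2_C3, A2_C5)
    ]
    counts = [0] * model.n_classes
    for egg_a1, egg_a2 in gametes:
        for pol_a1, pol_a2 in gametes:
            egg = (egg_a2, egg_a1, B_THCAS, M_THCAS)
            pollen = (pol_a2, pol_a1, B_THCAS, M_THCAS)
            cls = phenotype_class(PlantGenotype("enum", egg, pollen), model, loci)
            counts[cls] += 1
    return [Fraction(c, 16) for c in counts]


def _b_class(genotype: PlantGenotype, loci: Sequence[LocusSpec]) -> int:
    idx = {locus.name: i for i, locus in enumerate(loci)}
    return sum(1 for a in genotype.alleles_at(idx["B"]) if a == B_CBDAS)


def phenotype(
    genotype: PlantGenotype,
    model: GeneActionModel,
    rng: np.random.Generator,
    loci: Sequence[LocusSpec] | None = None,
) -> ChemotypeFractions:
    """Draw chemotype fractions for a genotype under the gene-action model.

    F_C3 is the class mean plus Gaussian noise (sd ``noise_sd``), truncated
    to [0, 100]; F_dicyclic analogously from the B genotype. With
    ``logit_skew`` the noise is applied on the logit scale (sd scaled so
    it matches ``noise_sd`` percent at a 50% mean), which skews classes
    near the boundaries toward them.
    """
    loci = loci if loci is not None else default_loci()
    f_c3_mean = model.class_means_FC3[phenotype_class(genotype, model, loci)]
    f_di_mean = model.b_class_means_Fdi[_b_class(genotype, loci)]

    def draw(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        if model.logit_skew:
            p = np.clip(mean / 100.0, 1e-6, 1 - 1e-6)
            return float(100.0 * expit(logit(p) + rng.normal(0.0, sd / 25.0)))
        # truncated normal on [0, 100]: fractions have no atoms at the
        # boundaries (clipping would put point masses at 0/100)
        lo, hi = ndtr((0.0 - mean) / sd), ndtr((100.0 - mean) / sd)
        return float(mean + sd * ndtri(lo + rng.uniform() * (hi - lo)))

    f_c3 = draw(f_c3_mean, model.noise_sd)
    f_di = draw(f_di_mean, model.b_noise_sd)
    return ChemotypeFractions(f_c3, 100.0 - f_c3, f_di, 100.0 - f_di)


def scar_genotype(
    genotype: PlantGenotype,
    marker_r: float,
    rng: np.random.Generator,
    loci: Sequence[LocusSpec] | None = None,
) -> str:
    """SCAR-marker genotype call for the B locus.

    If the genotype carries an explicit marker locus the call reads it
    directly (the marker was co-inherited through the pedigree). Otherwise
    a marker allele is co-simulated per haplotype: it equals that
    haplotype's B allele with probability 1−``marker_r`` and the plant's
    other B allele with probability ``marker_r`` (one meiosis of
    marker–B recombination); for a B-homozygote the call is therefore
    unambiguous whatever ``marker_r``.
    """
    if not 0.0 <= marker_r <= 0.5:
        raise ValueError("marker_r must be in [0, 0.5]")
    loci = loci if loci is not None else default_loci()
    idx = {locus.name: i for i, locus in enumerate(loci)}
    if "marker" in idx and len(genotype.maternal_haplotype) > idx["marker"]:
        alleles = [a.removeprefix("m_") for a in genotype.alleles_at(idx["marker"])]
    else:
        b = genotype.alleles_at(idx["B"])
        alleles = [
            b[1 - i] if rng.random() < marker_r else b[i] for i in range(2)
        ]
    n_cbdas = sum(a == B_CBDAS for a in alleles)
    return ("THCAS/THCAS", "THCAS/CBDAS", "CBDAS/CBDAS")[n_cbdas]


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass(frozen=True)
class StudyConfig:
    """Study-level simulation parameters.

    Defaults emulate the design of a 210-plant F2 from a single F1×F1
    cross between parents divergent at both locus complexes: parental
    F_C3 anchors 0.8 and 88.3 percent, B-genotype F_dicyclic means
    anchored at the parental values 0.9 and 96.1 with the heterozygote at
    the mid-parent 48.5.
    """

    gene_action: str = "additive"
    n_f1: int = 35
    n_f2: int = 210
    class_mean_low: float = 0.8
    class_mean_high: float = 88.3
    class_means: tuple[float, ...] | None = None  # overrides the low/high anchors
    noise_sd: float = 4.5
    b_class_means: tuple[float, float, float] = (0.9, 48.5, 96.1)
    b_noise_sd: float = 4.5
    logit_skew: bool = False
    r_a1_a2: float = 0.5
    r_a1_b: float = 0.5
    marker_r: float = 0.0
    n_replicates: int = 2
    replicate_cv: float = 0.02
    total_content_range: tuple[float, float] = (15.0, 25.0)

    def build_model(self) -> GeneActionModel:
        k = GeneActionModel._N_CLASSES.get(self.gene_action)
        if k is None:
            raise ValueError(f"unknown gene action kind {self.gene_action!r}")
        means = self.class_means
        if means is None:
            means = tuple(np.linspace(self.class_mean_low, self.class_mean_high, k))
        return GeneActionModel(
            self.gene_action,
            tuple(float(m) for m in means),
            self.noise_sd,
            self.b_class_means,
            self.b_noise_sd,
            self.logit_skew,
        )

    def validate(self) -> None:
        errors = []
        if self.n_f1 < 1:
            errors.append("n_f1 must be >= 1")
        if self.n_f2 < 1:
            errors.append("n_f2 must be >= 1")
        for name in ("r_a1_a2", "r_a1_b", "marker_r"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                errors.append(f"{name} must be in [0, 0.5]")
        if self.noise_sd < 0 or self.b_noise_sd < 0:
            errors.append("noise sds must be >= 0")
        if self.n_replicates < 1:
            errors.append("n_replicates must be >= 1")
        try:
            self.build_model()
        except ValueError as err:
            errors.append(str(err))
        if errors:
            raise ValueError("invalid study config: " + "; ".join(errors))


@dataclass
class SimPlant:
    """A simulated plant: genotype, true phenotype class, fractions, SCAR call."""

    genotype: PlantGenotype
    generation: str
    true_class: int
    fractions: ChemotypeFractions
    scar_call: str


@dataclass
class SimulatedStudy:
    """Parents, F1 and F2 of one simulated cross, plus the generating config."""

    parents: list[SimPlant]
    f1: list[SimPlant]
    f2: list[SimPlant]
    seed: int
    config: StudyConfig
    loci: list[LocusSpec] = field(default_factory=default_loci)

    @property
    def all_plants(self) -> list[SimPlant]:
        return self.parents + self.f1 + self.f2

    def to_dataframe(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Emit the per-plant (× replicate) analyte table the pipeline ingests.

        Fractions are realised as the four acid cannabinoids (the
        decarboxylation correction is then the identity):
        CBDVA = T·fc3·fdi, THCVA = T·fc3·(1−fdi), CBDA = T·(1−fc3)·fdi,
        THCA = T·(1−fc3)·(1−fdi), with T the total content (mg/g) and the
        fractions as proportions. Replicates get multiplicative noise of
        cv ``replicate_cv`` per analyte.
        """
        rng = rng if rng is not None else np.random.default_rng(self.seed + 1)
        lo, hi = self.config.total_content_range
        rows = []
        for plant in self.all_plants:
            total = float(rng.uniform(lo, hi))
            fc3 = plant.fractions.F_C3 / 100.0
            fdi = plant.fractions.F_dicyclic / 100.0
            base = {
                "CBDVA": total * fc3 * fdi,
                "THCVA": total * fc3 * (1 - fdi),
                "CBDA": total * (1 - fc3) * fdi,
                "THCA": total * (1 - fc3) * (1 - fdi),
                "CBDV": 0.0,
                "THCV": 0.0,
                "CBD": 0.0,
                "THC": 0.0,
            }
            for rep in range(1, self.config.n_replicates + 1):
                noisy = {
                    k: (v * float(np.exp(rng.normal(0.0, self.config.replicate_cv))) if v > 0 else 0.0)
                    for k, v in base.items()
                }
                rows.append(
                    {
                        "plant_id": plant.genotype.plant_id,
                        "generation": plant.generation,
                        "replicate": rep,
                        "b_genotype": plant.scar_call,
                        **noisy,
                    }
                )
        return pd.DataFrame(rows)


def simulate_f2_study(config: StudyConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Simulate the full study: homozygous divergent parents, F1, and F2.

    P1 is the C3/tricyclic extreme (all C3 alleles, THCAS homozygote);
    P2 the C5/dicyclic extreme (all C5 alleles, CBDAS homozygote). The F1
    family comes from P1×P2; a single male and female F1 plant are crossed
    to give the F2. Deterministic for a fixed seed.
    """
    config = config if config is not None else StudyConfig()
    config.validate()
    model = config.build_model()
    loci = default_loci(config.r_a1_a2, config.r_a1_b, config.marker_r)
    rng = np.random.default_rng(seed)

    p1_hap = (A2_C3, A1_C3, B_THCAS, M_THCAS)
    p2_hap = (A2_C5, A1_C5, B_CBDAS, M_CBDAS)
    p1 = PlantGenotype("P1", p1_hap, p1_hap, "female")
    p2 = PlantGenotype("P2", p2_hap, p2_hap, "male")

    def realise(genotype: PlantGenotype, generation: str) -> SimPlant:
        return SimPlant(
            genotype=genotype,
            generation=generation,
            true_class=phenotype_class(genotype, model, loci),
            fractions=phenotype(genotype, model, rng, loci),
            scar_call=scar_genotype(genotype, config.marker_r, rng, loci),
        )

    parents = [realise(p1, "P1"), realise(p2, "P2")]
    f1_genotypes = cross(p1, p2, config.n_f1, loci, rng, id_prefix="F1")
    f1 = [realise(g, "F1") for g in f1_genotypes]
    # a single female and male F1 plant serve as the F2 parents
    mother = next((p for p in f1 if p.genotype.sex == "female"), f1[0])
    father = next(
        (p for p in f1 if p.genotype.sex == "male" and p is not mother),
        next((p for p in f1 if p is not mother), mother),
    )
    f2_genotypes = cross(mother.genotype, father.genotype, config.n_f2, loci, rng, id_prefix="F2")
    f2 = [realise(g, "F2") for g in f2_genotypes]
    return SimulatedStudy(parents=parents, f1=f1, f2=f2, seed=seed, config=config, loci=loci)
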