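"""Goodness-of-fit tests for Mendelian chemotype segregation ratios.

Observed chemotype category counts are tested against named genetic
ratios (monogenic codominant 1:2:1, digenic additive 1:4:6:4:1, digenic
dominant 9:3:3:1, and the dominant + partially dominant epistatic 7:6:3)
with Pearson's χ² at df = k−1 and no continuity correction. Variance
homogeneity across families is tested with Bartlett's statistic computed
from summary statistics (per-group variance and df), as printed in
breeding tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SegregationRatio",
    "RATIO_REGISTRY",
    "GoodnessOfFitResult",
    "VarianceSummary",
    "B_GENOTYPES",
    "chi_square_gof",
    "chi_square_critical",
    "bartlett_from_summaries",
    "b_locus_monogenic_test",
    "genotype_conditioned_segregation",
]


@dataclass(frozen=True)
class SegregationRatio:
    """A named Mendelian segregation ratio, e.g. 9:3:3:1."""

    name: str
    terms: tuple[int, ...]
    n_loci: int
    gene_effect: str

    def __post_init__(self) -> None:
        if not self.terms or any(t <= 0 for t in self.terms):
            raise ValueError("ratio terms must be a nonempty tuple of positive integers")

    @property
    def k(self) -> int:
        return len(self.terms)

    def __str__(self) -> str:
        return ":".join(str(t) for t in self.terms)


#: The four gene-action models under test.
RATIO_REGISTRY: dict[str, SegregationRatio] = {
    "monogenic_codominant": SegregationRatio(
        "monogenic_codominant", (1, 2, 1), 1, "codominant"
    ),
    "digenic_additive": SegregationRatio(
        "digenic_additive", (1, 4, 6, 4, 1), 2, "additive"
    ),
    "digenic_dominant": SegregationRatio("digenic_dominant", (9, 3, 3, 1), 2, "dominant"),
    "epistatic_7_6_3": SegregationRatio(
        "epistatic_7_6_3", (7, 6, 3), 2, "dominant, partially dominant"
    ),
}

#: Codominant B-locus genotypes, ordered by increasing F_dicyclic expectation.
B_GENOTYPES = ("THCAS/THCAS", "THCAS/CBDAS", "CBDAS/CBDAS")


@dataclass
class GoodnessOfFitResult:
    """Pearson χ² goodness-of-fit of observed counts to a segregation ratio."""

    ratio: SegregationRatio
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    alpha: float
    critical_value: float
    p_value: float
    h0_accepted: bool


def chi_square_critical(df: int, alpha: float) -> float:
    """Upper-tail χ² quantile: the H0-acceptance threshold at significance alpha."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def chi_square_gof(
    observed: Sequence[float],
    ratio: SegregationRatio,
    alpha: float = 0.05,
) -> GoodnessOfFitResult:
    """Pearson χ² goodness-of-fit of category counts against a genetic ratio.

    Expected counts are N·term/Σterms; the statistic is Σ(O−E)²/E with no
    continuity correction and df = k−1. H0 (the ratio fits) is accepted
    when χ² does not exceed the upper-tail critical value at ``alpha``.
    """
    obs = np.asarray(observed, dtype=float)
    if len(obs) != ratio.k:
        raise ValueError(
            f"{len(obs)} observed categories cannot be tested against the "
            f"{ratio} ratio ({ratio.k} classes); categories are not aggregated silently"
        )
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be nonnegative with a positive total")
    n = obs.sum()
    terms = np.asarray(ratio.terms, dtype=float)
    expected = n * terms / terms.sum()
    if np.any(expected < 5):
        warnings.warn(
            f"expected count below 5 (min {expected.min():.2f}); the χ² approximation "
            "is questionable by the classical E >= 5 guideline"
        )
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = ratio.k - 1
    crit = chi_square_critical(df, alpha)
    p = float(stats.chi2.sf(chi2, df))
    return GoodnessOfFitResult(
        ratio=ratio,
        observed=tuple(int(round(o)) for o in obs),
        expected=tuple(float(e) for e in expected),
        chi2=chi2,
        df=df,
        alpha=alpha,
        critical_value=crit,
        p_value=p,
        h0_accepted=chi2 <= crit,
    )


@dataclass(frozen=True)
class VarianceSummary:
    """Per-group variance summary (sample variance of F_C3 and its df = n−1)."""

    group: str
    variance: float
    df: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")


def bartlett_from_summaries(
    groups: Sequence[VarianceSummary],
) -> tuple[float, int, float]:
    """Bartlett's homogeneity-of-variances test from per-group summaries.

    Uses the pooled variance s_p² = Σ df_i s_i² / Σ df_i and the statistic
    [(Σdf_i)·ln s_p² − Σ df_i·ln s_i²] / C with the usual correction
    C = 1 + (Σ 1/df_i − 1/Σdf_i) / (3(k−1)). Returns (χ², df, p).
    """
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least 2 groups")
    variances = np.array([g.variance for g in groups], dtype=float)
    dfs = np.array([g.df for g in groups], dtype=float)
    if np.any(variances == 0):
        if np.all(variances == 0):
            return 0.0, len(groups) - 1, 1.0
        raise ValueError("a zero variance alongside nonzero ones makes ln s² undefined")
    k = len(groups)
    total_df = dfs.sum()
    sp2 = float((dfs * variances).sum() / total_df)
    raw = total_df * math.log(sp2) - float((dfs * np.log(variances)).sum())
    c = 1.0 + ((1.0 / dfs).sum() - 1.0 / total_df) / (3.0 * (k - 1))
    chi2 = raw / c
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def b_locus_monogenic_test(
    genotype_counts: Sequence[int], alpha: float = 0.05
) -> GoodnessOfFitResult:
    """Test B-locus genotype counts [CBDAS/CBDAS, THCAS/CBDAS, THCAS/THCAS] against 1:2:1."""
    if len(genotype_counts) != 3:
        raise ValueError("exactly three genotype counts are required")
    return chi_square_gof(genotype_counts, RATIO_REGISTRY["monogenic_codominant"], alpha)


def genotype_conditioned_segregation(
    fractions: Mapping[str, float],
    genotypes: Mapping[str, str],
    model_plan: Mapping[str, Sequence[SegregationRatio]],
    demarcator_factory: Callable[[], "object"] | None = None,
    alpha: float = 0.05,
    min_group_n: int = 8,
) -> dict[str, list[GoodnessOfFitResult]]:
    """Per-B-genotype KDE demarcation and segregation tests.

    ``fractions`` maps plant id → F_C3 value; ``genotypes`` maps plant id →
    B-locus genotype (plants missing a genotype are excluded with a logged
    count). For each genotype class the F_C3 values are re-demarcated with
    a fresh :class:`~chemoseg.demarcation.ChemotypeDemarcator` and each
    ratio listed in ``model_plan`` is tested on the resulting category
    counts. Classes with fewer than ``min_group_n`` plants are skipped
    (expected counts would be too small).
    """
    from .demarcation import ChemotypeDemarcator

    if demarcator_factory is None:
        demarcator_factory = ChemotypeDemarcator

    unscored = [pid for pid in fractions if pid not in genotypes]
    if unscored:
        warnings.warn(f"{len(unscored)} plants without a B-locus genotype were excluded")

    results: dict[str, list[GoodnessOfFitResult]] = {}
    for genotype, ratios in model_plan.items():
        values = np.array(
            [v for pid, v in fractions.items() if genotypes.get(pid) == genotype]
        )
        if len(values) < min_group_n:
            warnings.warn(
                f"genotype {genotype}: n = {len(values)} < {min_group_n}; tests skipped"
            )
            results[genotype] = []
            continue
        dem = demarcator_factory().fit(values)
        counts = dem.counts_
        geno_results = []
        for ratio in ratios:
            try:
                geno_results.append(chi_square_gof(counts, ratio, alpha))
            except ValueError as err:
                warnings.warn(f"genotype {genotype}: {err}")
        results[genotype] = geno_results
    return results
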