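"""End-to-end analysis pipeline: file I/O, stage orchestration, reporting.

Stages: per-plant chemotype fractions → KDE demarcation of the F_C3 and
F_dicyclic axes → B-locus 1:2:1 genotype test → (optionally
genotype-conditioned) segregation-ratio goodness-of-fit. The report
mirrors the standard breeding-table layout: per-generation fraction
ranges, a variance/Bartlett table, demarcation boundaries and counts,
and the goodness-of-fit table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ANALYTES, OTHER_ANALYTES
from .demarcation import ChemotypeDemarcator
from .fractions import CannabinoidProfile, average_replicates, compute_fractions
from .segregation import (
    B_GENOTYPES,
    RATIO_REGISTRY,
    GoodnessOfFitResult,
    VarianceSummary,
    b_locus_monogenic_test,
    bartlett_from_summaries,
    chi_square_gof,
    genotype_conditioned_segregation,
)
from .simulate import StudyConfig, simulate_f2_study

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "read_plant_table",
    "write_plant_table",
    "fractions_table",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("chemoseg")

_NUMERIC_COLUMNS = ANALYTES + OTHER_ANALYTES


@dataclass
class RunConfig:
    """Configuration for one pipeline run, echoed verbatim into the report."""

    input_path: str | None = None
    simulation: StudyConfig | None = None  # used when input_path is None
    seed: int = 0
    alpha: float = 0.05
    min_support: int = 2
    grid_points: int = 512
    conditioning: str = "per-subset"  # or "global"
    output_dir: str | None = None
    forced_counts: tuple[int, ...] | None = None
    forced_ratio: str | None = None

    def validate(self) -> None:
        errors = []
        if self.input_path is None and self.simulation is None:
            self.simulation = StudyConfig()
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if self.min_support < 1:
            errors.append("min_support must be >= 1")
        if self.grid_points < 64:
            errors.append("grid_points must be >= 64")
        if self.conditioning not in ("per-subset", "global"):
            errors.append("conditioning must be 'per-subset' or 'global'")
        if (self.forced_counts is None) != (self.forced_ratio is None):
            errors.append("forced_counts and forced_ratio must be given together")
        if self.forced_ratio is not None and self.forced_ratio not in RATIO_REGISTRY:
            errors.append(f"unknown ratio {self.forced_ratio!r}")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))


# ---------------------------------------------------------------------------
# file I/O


def read_plant_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited per-plant cannabinoid table (comma- or tab-separated).

    Requires ``plant_id`` and ``generation`` columns plus at least one
    analyte column; ``replicate`` and ``b_genotype`` are optional. Unknown
    columns are preserved. Malformed numeric cells (including comma
    decimal separators) are rejected with their row numbers.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("plant_id", "generation") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    analyte_cols = [c for c in df.columns if c in _NUMERIC_COLUMNS]
    if not analyte_cols:
        raise ValueError(f"{path}: no analyte columns found (expected some of {ANALYTES})")
    for col in analyte_cols + (["replicate"] if "replicate" in df.columns else []):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            cells = ", ".join(f"row {i + 2}: {df.loc[i, col]!r}" for i in bad[:5])
            raise ValueError(
                f"{path}: column {col!r} has malformed numeric cells ({cells}); "
                "note that comma decimal separators are not accepted"
            )
        df[col] = parsed
    key = ["plant_id"] + (["replicate"] if "replicate" in df.columns else [])
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate plant_id/replicate rows: "
            f"{df.loc[dup, 'plant_id'].tolist()[:5]}"
        )
    if "b_genotype" in df.columns:
        valid = set(B_GENOTYPES)
        bad_geno = sorted(set(df["b_genotype"].dropna()) - valid)
        if bad_geno:
            raise ValueError(f"{path}: unknown b_genotype values {bad_geno}; expected {B_GENOTYPES}")
    return df


def write_plant_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(df).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# fractions stage


def fractions_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-plant chemotype fractions from a raw analyte table.

    Replicate rows for a plant are averaged (contents first, then
    fractions). Plants whose analyte contents are all zero have no defined
    chemotype and are excluded with a warning.
    """
    analyte_cols = [c for c in df.columns if c in ANALYTES]
    rows = []
    for plant_id, group in df.groupby("plant_id", sort=False):
        profiles = [
            CannabinoidProfile(
                str(plant_id),
                str(rec["generation"]),
                {a: float(rec[a]) for a in analyte_cols if pd.notna(rec[a])},
            )
            for rec in group.to_dict("records")
        ]
        summary = average_replicates(profiles)
        try:
            fr = compute_fractions(summary.mean_profile)
        except ValueError:
            warnings.warn(f"plant {plant_id}: zero total cannabinoid content; excluded")
            logger.warning("excluded zero-total plant %s", plant_id)
            continue
        row = {
            "plant_id": str(plant_id),
            "generation": str(group["generation"].iloc[0]),
            "n_replicates": len(profiles),
            "F_C3": fr.F_C3,
            "F_C5": fr.F_C5,
            "F_dicyclic": fr.F_dicyclic,
            "F_tricyclic": fr.F_tricyclic,
        }
        if "b_genotype" in group.columns:
            row["b_genotype"] = group["b_genotype"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report


@dataclass
class AnalysisReport:
    """Structured results of one pipeline run."""

    config: dict
    generation_summary: pd.DataFrame
    variance_table: list[VarianceSummary]
    bartlett: tuple[float, int, float] | None
    demarcation: dict  # axis -> {boundaries, counts, bandwidth, unresolved}
    b_locus_test: GoodnessOfFitResult | None
    gof_table: list[dict]
    warnings_log: list[str] = field(default_factory=list)

    def _gof_row_text(self, row: dict) -> str:
        r = row["result"]
        counts = ",".join(str(c) for c in r.observed)
        return (
            f"  {row['subset']:<16} n={sum(r.observed):<4} counts=[{counts}] "
            f"model={r.ratio.name} ({r.ratio}) chi2={r.chi2:.2f} df={r.df} "
            f"crit={r.critical_value:.2f} H0={'accepted' if r.h0_accepted else 'rejected'}"
        )

    def to_text(self) -> str:
        lines = ["# chemoseg analysis report", "", "## Configuration"]
        for k, v in self.config.items():
            lines.append(f"  {k} = {v}")
        lines += ["", "## Generation summary (percent)"]
        if len(self.generation_summary):
            lines.append("  " + self.generation_summary.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        lines += ["", "## F_C3 variance by group"]
        for vs in self.variance_table:
            lines.append(f"  {vs.group:<16} variance={vs.variance:.1f} df={vs.df}")
        if self.bartlett is not None:
            chi2, df, p = self.bartlett
            lines.append(f"  Bartlett chi2={chi2:.2f} df={df} p={p:.3f}")
        lines += ["", "## KDE demarcation"]
        for axis, info in self.demarcation.items():
            bounds = ", ".join(f"{b:.1f}" for b in info["boundaries"])
            counts = ", ".join(f"{lab}:{c}" for lab, c in info["counts"].items())
            h = info["bandwidth"]
            lines.append(
                f"  {axis}: h={h:.3f} boundaries=[{bounds}] counts=({counts})"
                if h is not None
                else f"  {axis}: single category, counts=({counts})"
            )
            if info["unresolved"]:
                unres = ", ".join(f"{u:.1f}" for u in info["unresolved"])
                lines.append(f"    unresolvable valleys (no cut made) near: {unres}")
        lines += ["", "## Goodness of fit"]
        if self.b_locus_test is not None:
            row = {"subset": "B locus 1:2:1", "result": self.b_locus_test}
            lines.append(self._gof_row_text(row))
        for row in self.gof_table:
            lines.append(self._gof_row_text(row))
        if self.warnings_log:
            lines += ["", "## Warnings"]
            lines += [f"  {w}" for w in self.warnings_log]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        def gof_dict(r: GoodnessOfFitResult) -> dict:
            return {
                "ratio": r.ratio.name,
                "terms": list(r.ratio.terms),
                "observed": list(r.observed),
                "expected": list(r.expected),
                "chi2": r.chi2,
                "df": r.df,
                "critical_value": r.critical_value,
                "p_value": r.p_value,
                "h0_accepted": r.h0_accepted,
            }

        payload = {
            "config": self.config,
            "generation_summary": self.generation_summary.to_dict("records"),
            "variance_table": [asdict(v) for v in self.variance_table],
            "bartlett": (
                {"chi2": self.bartlett[0], "df": self.bartlett[1], "p": self.bartlett[2]}
                if self.bartlett
                else None
            ),
            "demarcation": self.demarcation,
            "b_locus_test": gof_dict(self.b_locus_test) if self.b_locus_test else None,
            "gof_table": [
                {"subset": row["subset"], **gof_dict(row["result"])} for row in self.gof_table
            ],
            "warnings": self.warnings_log,
        }
        return json.dumps(payload, indent=2, default=str)


def write_report(report: AnalysisReport, path: str | Path) -> None:
    path = Path(path)
    path.write_text(report.to_text())
    path.with_suffix(".json").write_text(report.to_json())


# ---------------------------------------------------------------------------
# pipeline


def _generation_summary(fr: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gen, g in fr.groupby("generation", sort=False):
        rows.append(
            {
                "generation": gen,
                "n": len(g),
                "F_C3_min": g["F_C3"].min(),
                "F_C3_median": g["F_C3"].median(),
                "F_C3_max": g["F_C3"].max(),
                "F_dicyclic_min": g["F_dicyclic"].min(),
                "F_dicyclic_median": g["F_dicyclic"].median(),
                "F_dicyclic_max": g["F_dicyclic"].max(),
            }
        )
    return pd.DataFrame(rows)


def _demarcate_axis(values: np.ndarray, config: RunConfig) -> tuple[ChemotypeDemarcator, dict]:
    dem = ChemotypeDemarcator(min_support=config.min_support, grid_points=config.grid_points)
    dem.fit(values)
    info = {
        "boundaries": [float(b) for b in dem.boundaries_],
        "counts": dict(zip(dem.category_names_, dem.counts_)),
        "bandwidth": dem.bandwidth_,
        "unresolved": [float(u) for u in dem.categories_.unresolved_valleys],
    }
    if dem.bandwidth_ is not None:
        logger.info("bandwidth %.4f, boundaries %s", dem.bandwidth_, dem.boundaries_)
    return dem, info


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run fractions → demarcation → B-locus test → segregation tests."""
    config.validate()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        report = _run_pipeline_inner(config)
    caught = [str(w.message) for w in wlist]
    report.warnings_log.extend(caught)
    return report


def _run_pipeline_inner(config: RunConfig) -> AnalysisReport:
    if config.input_path is not None:
        raw = read_plant_table(config.input_path)
    else:
        study = simulate_f2_study(config.simulation, seed=config.seed)
        raw = study.to_dataframe()
    fr = fractions_table(raw)

    gen_summary = _generation_summary(fr)

    # variance homogeneity of F_C3 across generation groups with n >= 2
    variance_table = [
        VarianceSummary(str(gen), float(np.var(g["F_C3"], ddof=1)), len(g) - 1)
        for gen, g in fr.groupby("generation", sort=False)
        if len(g) >= 2
    ]
    bartlett = None
    testable = [v for v in variance_table if v.variance > 0]
    if len(testable) >= 2:
        bartlett = bartlett_from_summaries(testable)

    f2 = fr[fr["generation"] == "F2"]
    if len(f2) == 0:
        f2 = fr  # no generation labelled F2: analyse everything
        warnings.warn("no F2-labelled plants; demarcating the full table")

    demarcation: dict[str, dict] = {}
    dem_fc3, demarcation["F_C3"] = _demarcate_axis(f2["F_C3"].to_numpy(), config)
    _, demarcation["F_dicyclic"] = _demarcate_axis(f2["F_dicyclic"].to_numpy(), config)

    # B locus 1:2:1 genotype test (counts ordered CBDAS/CBDAS, het, THCAS/THCAS)
    b_locus_result = None
    gof_table: list[dict] = []
    has_genotype = "b_genotype" in f2.columns and f2["b_genotype"].notna().any()
    if has_genotype:
        geno_counts = [int((f2["b_genotype"] == g).sum()) for g in reversed(B_GENOTYPES)]
        b_locus_result = b_locus_monogenic_test(geno_counts, config.alpha)

    # unconditioned F_C3 segregation: every registry ratio matching the category count
    counts = dem_fc3.counts_
    for ratio in RATIO_REGISTRY.values():
        if ratio.k == len(counts):
            gof_table.append(
                {"subset": "All", "result": chi_square_gof(counts, ratio, config.alpha)}
            )

    if has_genotype:
        fractions_map = dict(zip(f2["plant_id"], f2["F_C3"]))
        genotype_map = {
            pid: g for pid, g in zip(f2["plant_id"], f2["b_genotype"]) if pd.notna(g)
        }
        if config.conditioning == "per-subset":
            plan = {g: list(RATIO_REGISTRY.values()) for g in B_GENOTYPES}
            per_geno = genotype_conditioned_segregation(
                fractions_map,
                genotype_map,
                plan,
                demarcator_factory=lambda: ChemotypeDemarcator(
                    min_support=config.min_support, grid_points=config.grid_points
                ),
                alpha=config.alpha,
            )
            for genotype, results in per_geno.items():
                for res in results:
                    if res.ratio.k == len(res.observed):
                        gof_table.append({"subset": genotype, "result": res})
        else:  # global boundaries, per-genotype counts
            for genotype in B_GENOTYPES:
                values = f2.loc[f2["b_genotype"] == genotype, "F_C3"].to_numpy()
                if len(values) < 8:
                    warnings.warn(f"genotype {genotype}: n = {len(values)} < 8; tests skipped")
                    continue
                labels = dem_fc3.predict(values)
                sub_counts = [int((labels == i).sum()) for i in range(dem_fc3.n_categories_)]
                for ratio in RATIO_REGISTRY.values():
                    if ratio.k == len(sub_counts):
                        gof_table.append(
                            {
                                "subset": genotype,
                                "result": chi_square_gof(sub_counts, ratio, config.alpha),
                            }
                        )

    if config.forced_counts is not None:
        gof_table.append(
            {
                "subset": "forced",
                "result": chi_square_gof(
                    config.forced_counts, RATIO_REGISTRY[config.forced_ratio], config.alpha
                ),
            }
        )

    cfg_echo = {k: v for k, v in asdict(config).items()}
    return AnalysisReport(
        config=cfg_echo,
        generation_summary=gen_summary,
        variance_table=variance_table,
        bartlett=bartlett,
        demarcation=demarcation,
        b_locus_test=b_locus_result,
        gof_table=gof_table,
    )
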