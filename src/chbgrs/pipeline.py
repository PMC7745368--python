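"""End-to-end analysis pipeline: summary -> association -> conditional -> LD -> GRS.

Given a cohort (loaded from files or built in memory), the pipeline writes a
bundle of TSV report tables mirroring the structure of a candidate-gene
case-control study:

* ``summary.tsv`` — per SNP per group: MAF, HWE P (chi-square and exact), n;
* ``association_<comparison>.tsv`` — allele test and additive logistic model
  per SNP, with display columns (2-decimal OR/CI by truncation, scientific P)
  alongside full-precision companions;
* ``conditional.tsv`` — the focal SNP re-tested conditioning on each known
  marker in turn;
* ``ld.tsv`` — long-format pairwise LD plus the r^2 <= threshold
  independence verdict for the focal SNP;
* ``grs_model.tsv``, ``grs_profiles.tsv``, ``grs_bins.tsv``,
  ``grs_summary.tsv`` — the risk-score model, per-individual cumulative
  scores, binned odds ratios and the range/group-comparison summary.

Outputs are deterministic for a fixed config and seed; a stage failure
removes the partial outputs of this run and aborts with a stage-named error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import association as assoc
from . import linkage, risk_score
from .cohort_model import CohortDataset, counts_from_dataset, read_cohort
from .rounding import trunc2
from .synthetic_data import published_counts_fixture

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for :func:`run_pipeline`."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    input_format: str = "tsv"
    use_published_counts_fixture: bool = False
    comparisons: Sequence[str] = ("CHB_vs_PC",)
    covariates: Sequence[str] = ()
    bonferroni_m: int = 40
    focal_snp: str = "rs12614"
    known_markers: Sequence[str] = ()
    ld_threshold: float = 0.15
    grs_bin_edges: Sequence[float] = risk_score.DEFAULT_BIN_EDGES
    grs_reference_bin: str | None = None
    grs_missing_policy: str = "skip"
    out_dir: str = "chbgrs_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ld_threshold <= 1:
            raise ValueError("LD threshold must lie in (0, 1]")
        for c in self.comparisons:
            if c not in assoc.COMPARISONS:
                raise ValueError(f"unknown comparison {c!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a flat YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _load_dataset(cfg: PipelineConfig) -> CohortDataset:
    if cfg.use_published_counts_fixture:
        return published_counts_fixture()
    if not cfg.genotype_path or not cfg.phenotype_path:
        raise ValueError("genotype_path and phenotype_path required unless using the fixture")
    return read_cohort(cfg.genotype_path, cfg.phenotype_path, format=cfg.input_format)


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def _result_row(ds_snp_gene: str, r: assoc.AssociationResult) -> dict:
    return {
        "snp_id": r.snp_id,
        "gene": ds_snp_gene,
        "comparison": r.comparison,
        "method": r.method,
        "OR": f"{trunc2(r.or_point):.2f}",
        "CI95": f"{trunc2(r.ci_low):.2f}-{trunc2(r.ci_high):.2f}",
        "P": _fmt_p(r.p_value),
        "P_corr": _fmt_p(r.p_corrected),
        "or_full": r.or_point,
        "ci_low_full": r.ci_low,
        "ci_high_full": r.ci_high,
        "p_full": r.p_value,
        "p_corr_full": r.p_corrected,
        "n_case": r.n_case,
        "n_control": r.n_control,
        "flags": ";".join(r.flags),
    }


def run_pipeline(cfg: PipelineConfig, ds: CohortDataset | None = None) -> dict[str, pd.DataFrame]:
    """Run all stages and write report TSVs to ``cfg.out_dir``.

    Returns the report tables as DataFrames keyed by stage name.  Any stage
    error removes files written during this run and re-raises with the stage
    named in the message.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables: dict[str, pd.DataFrame] = {}
    stage = "load"

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        tables[name] = df
        logger.info("stage %s: wrote %s (%d rows)", stage, path, len(df))

    try:
        if ds is None:
            ds = _load_dataset(cfg)
        genes = {s.snp_id: s.gene for s in ds.snps}
        logger.info("loaded cohort: %d individuals, %d SNPs", ds.n_individuals, len(ds.snps))

        stage = "summary"
        rows = []
        for sid in ds.snp_ids:
            for group in ("all", "case", "control"):
                counts = counts_from_dataset(ds, sid, group)
                if counts.total == 0:
                    logger.info("summary: %s has no genotypes in group %s; skipped", sid, group)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rows.append({
                        "snp_id": sid, "gene": genes[sid], "group": group,
                        "n_genotyped": counts.total,
                        "n_major_hom": counts.n_major_hom,
                        "n_het": counts.n_het,
                        "n_minor_hom": counts.n_minor_hom,
                        "MAF": round(assoc.compute_maf(counts), 3),
                        "maf_full": assoc.compute_maf(counts),
                        "hwe_p_chi2": assoc.hwe_test(counts, "chi_square"),
                        "hwe_p_exact": assoc.hwe_test(counts, "exact"),
                    })
        emit("summary", pd.DataFrame(rows))

        stage = "association"
        for comparison in cfg.comparisons:
            rows = []
            g1, g0 = assoc.COMPARISONS[comparison]
            for sid in ds.snp_ids:
                case_counts = counts_from_dataset(ds, sid, g1)
                ctrl_counts = counts_from_dataset(ds, sid, g0)
                res_allele = assoc.allele_test(case_counts, ctrl_counts,
                                               snp_id=sid, comparison=comparison)
                res_allele = replace(
                    res_allele,
                    p_corrected=assoc.bonferroni(res_allele.p_value, cfg.bonferroni_m),
                )
                rows.append(_result_row(genes[sid], res_allele))
                try:
                    res_add = assoc.additive_assoc(
                        ds, sid, comparison=comparison,
                        covariates=cfg.covariates, m=cfg.bonferroni_m,
                    )
                    rows.append(_result_row(genes[sid], res_add))
                except ValueError as exc:
                    logger.info("association: additive model skipped for %s (%s): %s",
                                sid, comparison, exc)
            emit(f"association_{comparison}", pd.DataFrame(rows))

        stage = "conditional"
        markers = [m for m in cfg.known_markers if m != cfg.focal_snp]
        if markers:
            rows = []
            for marker in markers:
                res = assoc.conditional_assoc(
                    ds, cfg.focal_snp, marker, covariates=cfg.covariates,
                    m=cfg.bonferroni_m,
                )
                row = _result_row(genes[cfg.focal_snp], res)
                row["conditioning_marker"] = marker
                rows.append(row)
            emit("conditional", pd.DataFrame(rows))

        stage = "ld"
        if len(ds.snps) >= 2:
            ld_results = linkage.ld_matrix(ds)
            ld_df = linkage.ld_long_frame(ld_results)
            screen_ids = markers or [s for s in ds.snp_ids if s != cfg.focal_snp]
            screen = linkage.r2_screen(ds, cfg.focal_snp, screen_ids,
                                       threshold=cfg.ld_threshold)
            ld_df["below_threshold"] = [
                r.r2 <= cfg.ld_threshold for r in ld_results
            ]
            emit("ld", ld_df)
            emit("ld_screen", screen)

        stage = "grs"
        ors = {}
        for sid in ds.snp_ids:
            res = assoc.allele_test(
                counts_from_dataset(ds, sid, "case"),
                counts_from_dataset(ds, sid, "control"),
                snp_id=sid,
            )
            ors[sid] = trunc2(res.or_point)
        model = risk_score.RiskScoreModel.from_odds_ratios(ors)
        emit("grs_model", model.score_frame())
        profiles = risk_score.cumulative_grs(ds, model, missing_policy=cfg.grs_missing_policy)
        emit("grs_profiles", pd.DataFrame(
            {"individual_id": [p.individual_id for p in profiles],
             "cumulative_grs": [p.cumulative_grs for p in profiles],
             "n_loci_used": [p.n_loci_used for p in profiles]}
        ))
        bins = risk_score.binned_or(profiles, ds.phenotypes,
                                    bin_edges=cfg.grs_bin_edges,
                                    reference_bin=cfg.grs_reference_bin)
        emit("grs_bins", pd.DataFrame(
            {"bin": [b.bin_label for b in bins],
             "n_case": [b.n_case for b in bins],
             "n_control": [b.n_control for b in bins],
             "OR": [b.or_vs_reference for b in bins],
             "ci_low": [b.ci_low for b in bins],
             "ci_high": [b.ci_high for b in bins],
             "log10_OR": [b.log10_or for b in bins],
             "reference": [b.is_reference for b in bins]}
        ))
        lo, hi = risk_score.grs_range(model)
        comparison = risk_score.compare_grs_groups(profiles, ds.phenotypes)
        emit("grs_summary", pd.DataFrame([{
            "grs_min": lo, "grs_max": hi,
            "group_test": comparison["test"],
            "group_p": comparison["p_value"],
            "case_mean": comparison["case"]["mean"],
            "case_median": comparison["case"]["median"],
            "control_mean": comparison["control"]["mean"],
            "control_median": comparison["control"]["median"],
        }]))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return tables
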