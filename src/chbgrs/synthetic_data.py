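"""Synthetic inputs: the published count-table fixture and simulated cohorts.

Two generators live here:

* :func:`published_counts_fixture` — a deterministic expansion of the published
  per-SNP case/control genotype counts for the 11 chronic-hepatitis-B
  susceptibility loci (955 cases, 761 population controls) into an
  individual-level dataset.  Per-SNP shortfalls against the group sizes
  (failed assays) become missing genotypes.  Joint genotypes across SNPs
  are an artifact of the fixed per-SNP expansion order — only the per-SNP
  marginals are real, so cross-locus quantities computed on the fixture
  (e.g. joint GRS bin counts) are not published values.
* :func:`simulate_cohort` — fully simulated case-control cohorts with
  configurable per-SNP minor-allele frequencies, per-allele odds ratios,
  optional pairwise LD targets, age/sex covariates and per-SNP missingness.
  Sampling is outcome-dependent (case-control): a population is generated
  from the logistic disease model and fixed numbers of cases and controls
  are drawn from it, under which per-allele odds ratios remain the
  recoverable quantity.

Defaults are the study's conditions: 955 cases vs 761 controls, and (for
the simulator) the 11 loci's pooled minor-allele frequencies and published
allele-test odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .association import allele_test
from .cohort_model import (
    CohortDataset,
    GenotypeCounts,
    Phenotype,
    SnpRecord,
    expand_counts,
)
from .rounding import trunc2

__all__ = [
    "PUBLISHED_COUNTS",
    "PUBLISHED_SNP_IDS",
    "published_counts_fixture",
    "published_odds_ratios",
    "default_mafs",
    "SimulationConfig",
    "simulate_cohort",
    "DEFAULT_SEED",
]

#: Documentation/example seed.
DEFAULT_SEED = 20201217

#: Published per-SNP genotype counts: snp_id -> (gene, major, minor,
#: case (major-hom, het, minor-hom), control triplet).  955 cases and 761
#: controls were genotyped; per-SNP count totals below those sizes reflect
#: assay failures, modelled as missing.
PUBLISHED_COUNTS: dict[str, tuple[str, str, str, tuple[int, int, int], tuple[int, int, int]]] = {
    "rs12614":    ("CFB",        "C", "T", (829, 91, 3),    (550, 142, 7)),
    "rs9277535":  ("HLA-DPB1",   "G", "A", (420, 428, 107), (184, 384, 193)),
    "rs3077":     ("HLA-DPA1",   "G", "A", (489, 382, 84),  (221, 385, 155)),
    "rs2856718":  ("HLA-DQB1",   "C", "T", (226, 418, 311), (263, 373, 125)),
    "rs7453920":  ("HLA-DQB2",   "G", "A", (743, 196, 16),  (461, 275, 25)),
    "rs1419881":  ("TCF19",      "T", "C", (419, 424, 112), (270, 361, 130)),
    "rs652888":   ("EHMT2",      "T", "C", (610, 300, 45),  (565, 188, 8)),
    "rs1265163":  ("OCT4",       "G", "C", (401, 439, 114), (392, 299, 70)),
    "rs35875104": ("EHMT2",      "T", "C", (878, 75, 2),    (650, 108, 3)),
    "rs9394021":  ("VARS2-SFTA", "A", "G", (303, 471, 177), (189, 368, 203)),
    "rs2517459":  ("VARS2-SFTA", "G", "A", (809, 139, 6),   (560, 193, 8)),
}

PUBLISHED_SNP_IDS = tuple(PUBLISHED_COUNTS)

N_CASE = 955
N_CONTROL = 761


def _published_count_specs() -> list[tuple[SnpRecord, GenotypeCounts, GenotypeCounts]]:
    specs = []
    for pos, (sid, (gene, major, minor, case, ctrl)) in enumerate(PUBLISHED_COUNTS.items(), start=1):
        # positions are ordinal placeholders (not used by any statistic)
        rec = SnpRecord(snp_id=sid, chrom="6", pos=pos,
                        major_allele=major, minor_allele=minor, gene=gene)
        specs.append((rec, GenotypeCounts(*case), GenotypeCounts(*ctrl)))
    return specs


def published_counts_fixture() -> CohortDataset:
    """Individual-level dataset expanded from the published genotype counts.

    Deterministic and platform-independent: 1716 individuals (955 cases,
    761 controls), 11 SNP columns, per-SNP missingness equal to each count
    shortfall.  No age/sex (not published at the individual level).
    """
    return expand_counts(_published_count_specs(), n_case=N_CASE, n_control=N_CONTROL)


def published_odds_ratios() -> dict[str, float]:
    """Two-decimal allele-test odds ratios recomputed from the count table."""
    out = {}
    for _, (sid, (gene, major, minor, case, ctrl)) in enumerate(PUBLISHED_COUNTS.items()):
        res = allele_test(GenotypeCounts(*case), GenotypeCounts(*ctrl), snp_id=sid)
        out[sid] = trunc2(res.or_point)
    return out


def default_mafs() -> dict[str, float]:
    """Pooled-sample minor-allele frequencies from the count table."""
    out = {}
    for sid, (gene, major, minor, case, ctrl) in PUBLISHED_COUNTS.items():
        cc, ct = GenotypeCounts(*case), GenotypeCounts(*ctrl)
        out[sid] = (cc.n_minor_alleles + ct.n_minor_alleles) / (
            2 * (cc.total + ct.total)
        )
    return out


@dataclass
class SimulationConfig:
    """Cohort-simulation settings; defaults reproduce the study's structure."""

    n_case: int = N_CASE
    n_control: int = N_CONTROL
    maf: Sequence[float] = ()
    odds_ratio: Sequence[float] = ()
    #: pairwise LD targets: (index_i, index_j) -> target r^2; pairs must be disjoint
    ld_r2: Mapping[tuple[int, int], float] = field(default_factory=dict)
    age_mean_case: float = 50.0
    age_mean_control: float = 50.0
    age_sd: float = 10.0
    female_frac_case: float = 0.3
    female_frac_control: float = 0.5
    missing_rate: float | Sequence[float] = 0.0
    hcc_frac: float = 296 / 955
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.maf:
            self.maf = tuple(default_mafs().values())
        if not self.odds_ratio:
            self.odds_ratio = tuple(published_odds_ratios().values())
        if len(self.maf) != len(self.odds_ratio):
            raise ValueError("maf and odds_ratio lists must have equal length")
        for q in self.maf:
            if not 0 < q <= 0.5:
                raise ValueError(f"MAF must lie in (0, 0.5], got {q}")
        for o in self.odds_ratio:
            if o <= 0:
                raise ValueError(f"odds ratio must be positive, got {o}")
        rates = self.missing_rates()
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("missing rates must lie in [0, 1)")
        seen: set[int] = set()
        for (i, j), r2 in self.ld_r2.items():
            if not 0 <= r2 < 1:
                raise ValueError(f"target r^2 must lie in [0, 1), got {r2}")
            if i == j or i in seen or j in seen:
                raise ValueError("LD pairs must be disjoint and between distinct loci")
            seen.update((i, j))

    @property
    def n_snps(self) -> int:
        return len(self.maf)

    def missing_rates(self) -> list[float]:
        if np.isscalar(self.missing_rate):
            return [float(self.missing_rate)] * self.n_snps
        return [float(r) for r in self.missing_rate]


def _r2_bound(q1: float, q2: float) -> float:
    """Maximum achievable r^2 for positive coupling of the two minor alleles."""
    d_max = min(q1 * (1 - q2), (1 - q1) * q2)
    return d_max**2 / (q1 * (1 - q1) * q2 * (1 - q2))


def _draw_genotypes(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    geno = np.empty((n, cfg.n_snps))
    paired = {i for pair in cfg.ld_r2 for i in pair}
    for j, q in enumerate(cfg.maf):
        if j in paired:
            continue
        geno[:, j] = rng.binomial(2, q, size=n)
    for (i, j), r2 in cfg.ld_r2.items():
        q1, q2 = cfg.maf[i], cfg.maf[j]
        bound = _r2_bound(q1, q2)
        if r2 > bound:
            raise ValueError(
                f"target r^2 {r2} between loci {i},{j} exceeds the theoretical "
                f"bound {bound:.4f} for MAFs {q1}, {q2}"
            )
        D = np.sqrt(r2 * q1 * (1 - q1) * q2 * (1 - q2))
        f = np.array([
            q1 * q2 + D,              # minor-minor
            q1 * (1 - q2) - D,        # minor-major
            (1 - q1) * q2 - D,        # major-minor
            (1 - q1) * (1 - q2) + D,  # major-major
        ])
        f = np.clip(f, 0.0, None)
        f = f / f.sum()
        haps = rng.choice(4, size=(n, 2), p=f)
        geno[:, i] = (haps < 2).sum(axis=1)          # haplotypes 0,1 carry minor at i
        geno[:, j] = np.isin(haps, (0, 2)).sum(axis=1)
    return geno


def simulate_cohort(cfg: SimulationConfig) -> CohortDataset:
    """Simulate a case-control cohort under a logistic disease model.

    A population pool is generated (Hardy-Weinberg genotypes, haplotype-level
    coupling for loci with an LD target), disease status is drawn from a
    logistic model with per-allele log-odds ln(OR) per locus and an intercept
    centred so cases and controls are both plentiful, and the requested
    numbers of cases and controls are sampled from the pool.  Covariates and
    missingness are applied afterwards.  Identical seeds give identical
    datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    beta = np.log(np.asarray(cfg.odds_ratio, dtype=float))
    n_needed = cfg.n_case + cfg.n_control
    pool = max(4 * n_needed, 2000)
    geno_parts, status_parts = [], []
    n_case_seen = n_ctrl_seen = 0
    # intercept centres the linear predictor at 0 => ~50% prevalence in pool
    alpha = -2 * float(np.dot(beta, np.asarray(cfg.maf)))
    for _ in range(20):
        g = _draw_genotypes(cfg, pool, rng)
        eta = alpha + g @ beta
        is_case = rng.random(pool) < 1 / (1 + np.exp(-eta))
        geno_parts.append(g)
        status_parts.append(is_case)
        n_case_seen += int(is_case.sum())
        n_ctrl_seen += int((~is_case).sum())
        if n_case_seen >= cfg.n_case and n_ctrl_seen >= cfg.n_control:
            break
    else:
        raise RuntimeError("could not generate enough cases/controls")
    geno = np.vstack(geno_parts)
    is_case = np.concatenate(status_parts)
    case_rows = np.flatnonzero(is_case)[: cfg.n_case]
    ctrl_rows = np.flatnonzero(~is_case)[: cfg.n_control]
    rows = np.concatenate([case_rows, ctrl_rows])
    dosages = geno[rows].astype(float)

    for j, rate in enumerate(cfg.missing_rates()):
        if rate > 0:
            dosages[rng.random(n_needed) < rate, j] = np.nan

    width = len(str(max(cfg.n_case, cfg.n_control)))
    phenotypes: list[Phenotype] = []
    for i in range(cfg.n_case):
        hcc = rng.random() < cfg.hcc_frac
        phenotypes.append(
            Phenotype(
                individual_id=f"case_{i + 1:0{width}d}",
                status="case",
                subgroup="HCC_pos" if hcc else "HCC_neg",
                age=float(rng.normal(cfg.age_mean_case, cfg.age_sd)),
                sex=int(rng.random() < cfg.female_frac_case),
            )
        )
    for i in range(cfg.n_control):
        phenotypes.append(
            Phenotype(
                individual_id=f"ctrl_{i + 1:0{width}d}",
                status="control",
                age=float(rng.normal(cfg.age_mean_control, cfg.age_sd)),
                sex=int(rng.random() < cfg.female_frac_control),
            )
        )
    snps = [
        SnpRecord(snp_id=f"snp{j + 1:02d}", chrom="6", pos=j + 1,
                  major_allele="A", minor_allele="G")
        for j in range(cfg.n_snps)
    ]
    return CohortDataset(snps=snps, dosages=dosages, phenotypes=phenotypes)
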