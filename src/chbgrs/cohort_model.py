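"""Domain types and I/O for case-control SNP cohorts.

The central container is :class:`CohortDataset`: an individuals x SNPs matrix
of minor-allele dosages (0/1/2, ``nan`` for a failed genotype) paired with a
phenotype record per individual (case/control status, optional hepatocellular
carcinoma subgroup, optional age/sex covariates).

Published candidate-gene tables report per-SNP genotype *counts* per group
rather than individual-level data.  :func:`expand_counts` deterministically
expands such counts into a dataset (any shortfall against the group size
becomes missingness at that SNP) and :func:`counts_from_dataset` inverts it,
so printed tables round-trip losslessly through the individual-level
representation.

Minor alleles are determined once in the pooled sample (cases + controls
together) and never re-determined per subgroup; loaders re-orient dosages so
that the counted allele is the pooled minor allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeCounts",
    "Phenotype",
    "CohortDataset",
    "read_cohort",
    "counts_from_dataset",
    "expand_counts",
    "orient_to_minor_allele",
    "write_genotype_tsv",
    "write_phenotype_tsv",
    "write_vcf",
]

logger = logging.getLogger(__name__)

#: Sentinel for a failed/absent genotype call in the dosage matrix.
MISSING = float("nan")

_BASES = frozenset("ACGT")
_STATUSES = frozenset({"case", "control"})
_SUBGROUPS = frozenset({"HCC_pos", "HCC_neg", "none"})


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic variant; ``minor_allele`` is the counted (effect) allele."""

    snp_id: str
    chrom: str = "."
    pos: int = 1
    major_allele: str = "A"
    minor_allele: str = "G"
    gene: str = ""

    def __post_init__(self) -> None:
        if self.major_allele not in _BASES or self.minor_allele not in _BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases in ACGT, "
                f"got {self.major_allele!r}/{self.minor_allele!r}"
            )
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: major and minor allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")

    def flipped(self) -> "SnpRecord":
        """Swap major/minor allele labels."""
        return replace(self, major_allele=self.minor_allele, minor_allele=self.major_allele)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype count triplet for one SNP in one group (genotyped individuals only)."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        for name in ("n_major_hom", "n_het", "n_minor_hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def n_minor_alleles(self) -> int:
        return self.n_het + 2 * self.n_minor_hom

    @property
    def n_major_alleles(self) -> int:
        return 2 * self.n_major_hom + self.n_het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_major_hom, self.n_het, self.n_minor_hom)


@dataclass(frozen=True)
class Phenotype:
    """Case/control status with optional HCC subgroup and age/sex covariates.

    Sex coding: 0 = male, 1 = female.
    """

    individual_id: str
    status: str
    subgroup: str = "none"
    age: float | None = None
    sex: int | None = None

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"{self.individual_id}: status must be case/control, got {self.status!r}")
        if self.subgroup not in _SUBGROUPS:
            raise ValueError(f"{self.individual_id}: unknown subgroup {self.subgroup!r}")
        if self.subgroup != "none" and self.status != "case":
            raise ValueError(f"{self.individual_id}: HCC subgroup only allowed for cases")
        if self.sex is not None and self.sex not in (0, 1):
            raise ValueError(f"{self.individual_id}: sex must be 0 (male) or 1 (female)")


@dataclass
class CohortDataset:
    """Individual-level dosage matrix plus per-individual phenotypes.

    ``dosages`` is a float matrix of shape (n individuals, n SNPs) with entries
    in {0, 1, 2} or ``nan`` (missing), counting copies of each SNP's minor
    allele.
    """

    snps: list[SnpRecord]
    dosages: np.ndarray
    phenotypes: list[Phenotype]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        n_ind, n_snp = self.dosages.shape
        if n_ind != len(self.phenotypes):
            raise ValueError(
                f"{n_ind} dosage rows but {len(self.phenotypes)} phenotypes"
            )
        if n_snp != len(self.snps):
            raise ValueError(f"{n_snp} dosage columns but {len(self.snps)} SNP records")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad[:5]}")
        self._index = {s.snp_id: j for j, s in enumerate(self.snps)}
        if len(self._index) != len(self.snps):
            raise ValueError("duplicate SNP ids")

    # -- accessors ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self.snp_index(snp_id)]

    def dosage_column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over individuals for a named group selector.

        Selectors: ``case``, ``control``, ``HCC_pos``, ``HCC_neg``, ``all``.
        """
        if group == "all":
            return np.ones(self.n_individuals, dtype=bool)
        if group in _STATUSES:
            return np.array([p.status == group for p in self.phenotypes])
        if group in ("HCC_pos", "HCC_neg"):
            return np.array([p.subgroup == group for p in self.phenotypes])
        raise ValueError(f"unknown group selector {group!r}")

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [p.individual_id for p in self.phenotypes],
                "status": [p.status for p in self.phenotypes],
                "subgroup": [p.subgroup for p in self.phenotypes],
                "age": [p.age for p in self.phenotypes],
                "sex": [p.sex for p in self.phenotypes],
            }
        )


# -- counts <-> individuals -------------------------------------------------


def counts_from_dataset(ds: CohortDataset, snp_id: str, group: str) -> GenotypeCounts:
    """Tabulate genotype counts for one SNP in one group (missing excluded)."""
    mask = ds.group_mask(group)
    if not mask.any():
        raise ValueError(f"group {group!r} selects no individuals")
    col = ds.dosage_column(snp_id)[mask]
    obs = col[~np.isnan(col)]
    return GenotypeCounts(
        n_major_hom=int((obs == 0).sum()),
        n_het=int((obs == 1).sum()),
        n_minor_hom=int((obs == 2).sum()),
    )


def expand_counts(
    snp_specs: Sequence[tuple[SnpRecord, GenotypeCounts, GenotypeCounts]],
    n_case: int,
    n_control: int,
) -> CohortDataset:
    """Expand per-SNP case/control genotype counts into an individual-level dataset.

    Expansion is deterministic and per SNP independent: within each group the
    first ``n_major_hom`` individuals receive dosage 0, the next ``n_het``
    dosage 1, the next ``n_minor_hom`` dosage 2, and any shortfall against the
    group size becomes missing at that SNP.  Joint genotypes across SNPs are
    therefore arbitrary — only the per-SNP marginals are meaningful.

    Round-trip: ``counts_from_dataset`` on the result reproduces the inputs.
    """
    snps = [spec[0] for spec in snp_specs]
    n_snp = len(snps)
    dosages = np.full((n_case + n_control, n_snp), MISSING)
    for j, (rec, case_counts, ctrl_counts) in enumerate(snp_specs):
        for counts, offset, size, label in (
            (case_counts, 0, n_case, "case"),
            (ctrl_counts, n_case, n_control, "control"),
        ):
            if counts.total > size:
                raise ValueError(
                    f"{rec.snp_id}: {label} counts sum to {counts.total} > group size {size}"
                )
            fills = [0.0] * counts.n_major_hom + [1.0] * counts.n_het + [2.0] * counts.n_minor_hom
            dosages[offset : offset + len(fills), j] = fills
    width = len(str(max(n_case, n_control, 1)))
    phenotypes = [
        Phenotype(individual_id=f"case_{i + 1:0{width}d}", status="case") for i in range(n_case)
    ] + [
        Phenotype(individual_id=f"ctrl_{i + 1:0{width}d}", status="control")
        for i in range(n_control)
    ]
    return CohortDataset(snps=snps, dosages=dosages, phenotypes=phenotypes)


def orient_to_minor_allele(ds: CohortDataset) -> CohortDataset:
    """Recode each SNP so dosage counts the pooled-sample minor allele.

    Columns whose counted-allele frequency exceeds 0.5 in the pooled sample
    are flipped (dosage -> 2 - dosage, allele labels swapped).  Applying the
    operation twice changes nothing (involution-safe).
    """
    dosages = ds.dosages.copy()
    snps = list(ds.snps)
    for j, rec in enumerate(snps):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        freq = obs.sum() / (2 * obs.size)
        if freq > 0.5:
            dosages[:, j] = 2.0 - col
            snps[j] = rec.flipped()
            logger.info("recoded %s: counted allele frequency %.3f > 0.5", rec.snp_id, freq)
    return CohortDataset(snps=snps, dosages=dosages, phenotypes=list(ds.phenotypes))


# -- file I/O ---------------------------------------------------------------


def _read_phenotypes(path: str | Path) -> list[Phenotype]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotype table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        sub = getattr(row, "subgroup", "none")
        if pd.isna(sub):
            sub = "none"
        age = getattr(row, "age", None)
        sex = getattr(row, "sex", None)
        out.append(
            Phenotype(
                individual_id=str(row.individual_id),
                status=str(row.status),
                subgroup=str(sub),
                age=None if age is None or pd.isna(age) else float(age),
                sex=None if sex is None or pd.isna(sex) else int(sex),
            )
        )
    return out


def _read_genotype_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if df.columns[0] != "individual_id":
        raise ValueError(f"{path}: first column must be 'individual_id'")
    snp_ids = [str(c) for c in df.columns[1:]]
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = mat[~np.isnan(mat) & ~np.isin(mat, (0.0, 1.0, 2.0))]
    if bad.size:
        # locate first offending line for the error message
        for i in range(mat.shape[0]):
            row = mat[i]
            if (~np.isnan(row) & ~np.isin(row, (0.0, 1.0, 2.0))).any():
                raise ValueError(f"{path}: line {i + 2}: dosage not in 0/1/2/NA")
    return list(df["individual_id"].astype(str)), snp_ids, mat


def _read_genotype_vcf(path: str | Path) -> tuple[list[str], list[SnpRecord], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    records: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNV record %s at %s:%d", var.ID, var.CHROM, var.POS)
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gts = np.asarray(var.gt_types, dtype=float)
        gts[gts == 3] = MISSING
        columns.append(gts)
        records.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                major_allele=str(var.REF),
                minor_allele=str(var.ALT[0]),
            )
        )
    if not records:
        raise ValueError(f"{path}: no usable biallelic SNV records")
    return individuals, records, np.column_stack(columns)


def read_cohort(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    format: str = "tsv",
) -> CohortDataset:
    """Load genotypes (TSV or VCF) and phenotypes into a :class:`CohortDataset`.

    Dosages are re-oriented so the counted allele is the minor allele in the
    pooled sample.  Every genotyped individual must appear in the phenotype
    table; rows are ordered as in the genotype file.
    """
    phenos = {p.individual_id: p for p in _read_phenotypes(phenotype_path)}
    if format == "tsv":
        individuals, snp_ids, mat = _read_genotype_tsv(genotype_path)
        snps = [SnpRecord(snp_id=s) for s in snp_ids]
    elif format == "vcf":
        individuals, snps, mat = _read_genotype_vcf(genotype_path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")
    missing_ids = [i for i in individuals if i not in phenos]
    if missing_ids:
        raise ValueError(
            f"{phenotype_path}: no phenotype for genotyped individuals: {', '.join(missing_ids)}"
        )
    ds = CohortDataset(
        snps=snps,
        dosages=mat,
        phenotypes=[phenos[i] for i in individuals],
    )
    return orient_to_minor_allele(ds)


def write_genotype_tsv(ds: CohortDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.dosages, columns=ds.snp_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "individual_id", [p.individual_id for p in ds.phenotypes])
    df.to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(ds: CohortDataset, path: str | Path) -> None:
    df = ds.phenotype_frame()
    df["age"] = df["age"].map(lambda v: "NA" if v is None else f"{v:g}")
    df["sex"] = df["sex"].map(lambda v: "NA" if v is None else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def write_vcf(ds: CohortDataset, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) with ALT = the minor (counted) allele."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        ids = "\t".join(p.individual_id for p in ds.phenotypes)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        for j, rec in enumerate(ds.snps):
            col = ds.dosages[:, j]
            gts = "\t".join("./." if np.isnan(v) else code[v] for v in col)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.major_allele}\t"
                f"{rec.minor_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )
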