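"""Cumulative genetic risk scores (GRS) from allele-test odds ratios.

The scoring scheme assigns each SNP a three-entry per-genotype table derived
from its two-decimal allele-test odds ratio OR:

    dosage 0 (major homozygote)  ->  1
    dosage 1 (heterozygote)      ->  OR
    dosage 2 (minor homozygote)  ->  2*OR if OR > 1, OR/2 if OR < 1, 1 if OR = 1

All scores are stored rounded to two decimals, half away from zero.  An
individual's cumulative GRS is the sum of their per-SNP genotype scores over
the loci in the model; with L loci all at the neutral genotype the score is
exactly L.  The homozygote rule doubles the score on the risk side and
halves it on the protective side of OR = 1, so the score is monotone in
dosage on either side; OR = 1 maps every genotype to the neutral score 1.

This multiplicative-table scheme is deliberately idiosyncratic — it is the
published scoring convention this package reproduces, not the conventional
log-additive polygenic score (which is a documented non-goal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z95
from .cohort_model import CohortDataset, Phenotype
from .rounding import round2

__all__ = [
    "RiskScoreModel",
    "GrsProfile",
    "BinnedOrResult",
    "genotype_score",
    "cumulative_grs",
    "grs_range",
    "binned_or",
    "compare_grs_groups",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_REFERENCE_BIN",
]

#: Default GRS bin edges: open ends below 7 and above 14, reference interval
#: 9.8-11.2, intermediate bins of width 1.4.
DEFAULT_BIN_EDGES = (-math.inf, 7.0, 8.4, 9.8, 11.2, 12.6, 14.0, math.inf)
DEFAULT_REFERENCE_BIN = "[9.8, 11.2)"


def genotype_score(or_value: float, dosage: int) -> float:
    """Per-genotype score for a SNP with 2-decimal allele-test OR ``or_value``."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1 or 2, got {dosage!r}")
    if dosage == 0:
        return 1.0
    if dosage == 1:
        return round2(or_value)
    if or_value > 1:
        return round2(2 * or_value)
    if or_value < 1:
        return round2(or_value / 2)
    return 1.0


@dataclass(frozen=True)
class RiskScoreModel:
    """Per-SNP odds ratios and the derived per-genotype score tables."""

    odds_ratios: tuple[tuple[str, float], ...]

    @classmethod
    def from_odds_ratios(cls, ors: Mapping[str, float]) -> "RiskScoreModel":
        if not ors:
            raise ValueError("risk score model needs at least one SNP")
        return cls(odds_ratios=tuple((k, float(v)) for k, v in ors.items()))

    @property
    def snp_ids(self) -> list[str]:
        return [sid for sid, _ in self.odds_ratios]

    def scores(self, snp_id: str) -> tuple[float, float, float]:
        for sid, orv in self.odds_ratios:
            if sid == snp_id:
                return tuple(genotype_score(orv, d) for d in (0, 1, 2))
        raise KeyError(f"SNP {snp_id!r} not in risk score model")

    def score_frame(self) -> pd.DataFrame:
        rows = []
        for sid, orv in self.odds_ratios:
            s0, s1, s2 = self.scores(sid)
            rows.append({"snp_id": sid, "odds_ratio": orv,
                         "score_dosage0": s0, "score_dosage1": s1, "score_dosage2": s2})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrsProfile:
    individual_id: str
    cumulative_grs: float
    n_loci_used: int


def cumulative_grs(
    ds: CohortDataset,
    model: RiskScoreModel,
    missing_policy: str = "skip",
) -> list[GrsProfile]:
    """Per-individual cumulative GRS over the model's loci.

    Under ``missing_policy='skip'`` a missing genotype contributes nothing
    and ``n_loci_used`` records coverage; under ``'error'`` any missing
    genotype raises, naming the individual and SNP.
    """
    if missing_policy not in ("skip", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    score_table = {sid: model.scores(sid) for sid in model.snp_ids}
    cols = {sid: ds.dosage_column(sid) for sid in model.snp_ids}
    out = []
    for i, pheno in enumerate(ds.phenotypes):
        total = 0.0
        used = 0
        for sid in model.snp_ids:
            v = cols[sid][i]
            if np.isnan(v):
                if missing_policy == "error":
                    raise ValueError(
                        f"missing genotype for individual {pheno.individual_id!r} at {sid}"
                    )
                continue
            total += score_table[sid][int(v)]
            used += 1
    # round away accumulated binary-float dust; scores have 2 decimals
        out.append(GrsProfile(pheno.individual_id, round(total, 10), used))
    return out


def grs_range(model: RiskScoreModel) -> tuple[float, float]:
    """Theoretical (min, max) cumulative GRS: per-SNP extreme scores summed."""
    lo = sum(min(model.scores(sid)) for sid in model.snp_ids)
    hi = sum(max(model.scores(sid)) for sid in model.snp_ids)
    return (round(lo, 10), round(hi, 10))


@dataclass(frozen=True)
class BinnedOrResult:
    bin_label: str
    n_case: int
    n_control: int
    or_vs_reference: float
    ci_low: float
    ci_high: float
    log10_or: float
    reference_bin: str
    is_reference: bool = False


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        left = "<" if math.isinf(lo) else f"[{lo:g}"
        if math.isinf(lo):
            labels.append(f"<{hi:g}")
        elif math.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g}, {hi:g})")
    return labels


def binned_or(
    profiles: Sequence[GrsProfile],
    phenotypes: Sequence[Phenotype],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    reference_bin: str | None = None,
) -> list[BinnedOrResult]:
    """Odds ratio of case status per GRS bin against a reference bin.

    Each bin's 2x2 table (bin cases/controls vs reference cases/controls)
    yields a cross-product OR with Woolf CI; a zero cell triggers the 0.5
    continuity correction.  The reference bin reports OR = 1 exactly.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(edges) < 3:
        raise ValueError("bin edges must be increasing with at least 2 bins")
    labels = _bin_labels(edges)
    if reference_bin is None:
        reference_bin = DEFAULT_REFERENCE_BIN if DEFAULT_REFERENCE_BIN in labels else labels[len(labels) // 2]
    if reference_bin not in labels:
        raise ValueError(f"reference bin {reference_bin!r} not among {labels}")
    grs = np.array([p.cumulative_grs for p in profiles])
    if grs.size and (grs.min() < edges[0] or grs.max() >= edges[-1]):
        raise ValueError("bins do not cover the observed GRS range")
    is_case = np.array([p.status == "case" for p in phenotypes])
    which = np.digitize(grs, edges[1:-1], right=False)
    n_case = np.array([(is_case & (which == b)).sum() for b in range(len(labels))])
    n_ctrl = np.array([(~is_case & (which == b)).sum() for b in range(len(labels))])
    ref = labels.index(reference_bin)
    rc, rd = int(n_case[ref]), int(n_ctrl[ref])
    if rc == 0 or rd == 0:
        raise ValueError("reference bin empty in cases or controls")
    out = []
    for b, label in enumerate(labels):
        a, c = int(n_case[b]), int(n_ctrl[b])
        if b == ref:
            out.append(BinnedOrResult(label, a, c, 1.0, 1.0, 1.0, 0.0,
                                      reference_bin, is_reference=True))
            continue
        aa, cc, bb, dd = float(a), float(c), float(rc), float(rd)
        if min(a, c, rc, rd) == 0:
            aa, cc, bb, dd = a + 0.5, c + 0.5, rc + 0.5, rd + 0.5
        orv = (aa * dd) / (cc * bb)
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        log_or = math.log(orv)
        out.append(
            BinnedOrResult(
                bin_label=label, n_case=a, n_control=c, or_vs_reference=orv,
                ci_low=math.exp(log_or - Z95 * se), ci_high=math.exp(log_or + Z95 * se),
                log10_or=math.log10(orv), reference_bin=reference_bin,
            )
        )
    return out


def compare_grs_groups(
    profiles: Sequence[GrsProfile],
    phenotypes: Sequence[Phenotype],
    test: str = "wilcoxon",
) -> dict:
    """Two-sided case-vs-control comparison of cumulative GRS.

    Default is the Wilcoxon rank-sum (Mann-Whitney) test; ``test='t_test'``
    selects Welch's t.  On fully tied data the rank test reports P = 1.
    Returns the P value with per-group mean/median/n summaries.
    """
    grs = np.array([p.cumulative_grs for p in profiles])
    is_case = np.array([p.status == "case" for p in phenotypes])
    x, y = grs[is_case], grs[~is_case]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "wilcoxon":
        if np.ptp(grs) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    elif test == "t_test":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "p_value": min(max(p, np.nextafter(0, 1)), 1.0),
        "test": test,
        "case": {"n": int(x.size), "mean": float(x.mean()), "median": float(np.median(x))},
        "control": {"n": int(y.size), "mean": float(y.mean()), "median": float(np.median(y))},
    }
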