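"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by expectation-maximisation
over the double-heterozygote phase ambiguity (the only genotype whose gamete
composition is not determined).  From the fitted frequencies the usual
statistics follow: the raw disequilibrium D = f_AB - p_A p_B, Lewontin's
normalised |D'| = |D| / D_max, and the squared allele correlation
r^2 = D^2 / (p_A p_a p_B p_b).

Conventions match the standard haplotype-browser output: |D'| is reported
unsigned, individuals are pairwise-complete per SNP pair, and a pair where
either locus is monomorphic in the shared subset is flagged degenerate with
r^2 = 0 by convention (D and D' undefined).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import CohortDataset

__all__ = ["HaplotypeFreqs", "LdResult", "em_haplotypes", "ld_stats", "ld_matrix",
           "ld_long_frame", "r2_screen"]


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (A/a = minor/major at locus 1, B/b locus 2)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    log_likelihood: float
    n_iterations: int
    n_informative: int
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])


@dataclass(frozen=True)
class LdResult:
    snp1: str
    snp2: str
    D: float
    d_prime: float
    r2: float
    n_informative: int
    degenerate: bool = False


def _genotype_table(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete individuals."""
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    g1 = d1[ok].astype(int)
    g2 = d2[ok].astype(int)
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (g1, g2), 1.0)
    return table


def _loglik(table: np.ndarray, f: np.ndarray) -> float:
    f_AB, f_Ab, f_aB, f_ab = np.clip(f, 1e-300, None)
    ll = 0.0
    for g1 in range(3):
        for g2 in range(3):
            n = table[g1, g2]
            if n == 0:
                continue
            if g1 == 1 and g2 == 1:
                prob = 2 * f_AB * f_ab + 2 * f_Ab * f_aB
            else:
                # gamete composition determined: pick the two haplotypes
                h1 = _haps_for(g1, g2)
                fa, fb = h1
                prob = fa_freq(f, fa) * fa_freq(f, fb)
                if fa != fb:
                    prob *= 2
            ll += n * math.log(max(prob, 1e-300))
    return ll


_HAP_INDEX = {("A", "B"): 0, ("A", "b"): 1, ("a", "B"): 2, ("a", "b"): 3}


def fa_freq(f: np.ndarray, hap: tuple[str, str]) -> float:
    return float(f[_HAP_INDEX[hap]])


def _haps_for(g1: int, g2: int) -> tuple[tuple[str, str], tuple[str, str]]:
    """The determined unordered haplotype pair for a non-double-het genotype."""
    a1 = ["a", "A"]
    first = a1[1] if g1 >= 1 else a1[0]
    second = a1[1] if g1 == 2 else a1[0]
    b1 = ["b", "B"]
    firstb = b1[1] if g2 >= 1 else b1[0]
    secondb = b1[1] if g2 == 2 else b1[0]
    # het at one locus pairs the minor allele with one of each at the other;
    # ordering within the pair is immaterial for frequencies
    if g1 == 1 and g2 != 1:
        return (("A", firstb), ("a", secondb))
    if g2 == 1 and g1 != 1:
        return ((first, "B"), (second, "b"))
    return ((first, firstb), (second, secondb))


def em_haplotypes(
    dosages_locus1: Sequence[float] | np.ndarray,
    dosages_locus2: Sequence[float] | np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> HaplotypeFreqs:
    """EM estimate of the four two-locus haplotype frequencies.

    Starts from linkage-equilibrium product frequencies; iterates the
    double-heterozygote phase split until the largest frequency change is
    below ``tol`` (default 1e-9) or ``max_iter`` (default 1000) iterations.
    """
    d1 = np.asarray(dosages_locus1, dtype=float)
    d2 = np.asarray(dosages_locus2, dtype=float)
    table = _genotype_table(d1, d2)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals non-missing at both loci")
    p_A = (table[1].sum() + 2 * table[2].sum()) / (2 * n)
    p_B = (table[:, 1].sum() + 2 * table[:, 2].sum()) / (2 * n)
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        warnings.warn("monomorphic locus in pairwise-complete subset; LD undefined",
                      stacklevel=2)
        f = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)])
        return HaplotypeFreqs(*f, log_likelihood=_loglik(table, f), n_iterations=0,
                              n_informative=int(n), degenerate=True)

    # fixed gamete contributions from phase-determined genotypes
    known = np.zeros(4)
    for g1, g2 in itertools.product(range(3), range(3)):
        if g1 == 1 and g2 == 1:
            continue
        cnt = table[g1, g2]
        if cnt == 0:
            continue
        for hap in _haps_for(g1, g2):
            known[_HAP_INDEX[hap]] += cnt
    n_dh = table[1, 1]

    f = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)])
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]          # AB/ab phase
        trans = f[1] * f[2]        # Ab/aB phase
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = known.copy()
        counts[[0, 3]] += n_dh * w
        counts[[1, 2]] += n_dh * (1 - w)
        f_new = counts / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return HaplotypeFreqs(
        *f, log_likelihood=_loglik(table, f), n_iterations=it,
        n_informative=int(n),
    )


def ld_stats(h: HaplotypeFreqs, snp1: str = "locus1", snp2: str = "locus2") -> LdResult:
    """D, |D'| and r^2 from fitted haplotype frequencies."""
    if h.degenerate:
        return LdResult(snp1=snp1, snp2=snp2, D=0.0, d_prime=0.0, r2=0.0,
                        n_informative=h.n_informative, degenerate=True)
    p_A = h.f_AB + h.f_Ab
    p_B = h.f_AB + h.f_aB
    p_a, p_b = 1 - p_A, 1 - p_B
    D = h.f_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    denom = p_A * p_a * p_B * p_b
    r2 = D * D / denom if denom > 0 else 0.0
    # clamp float overshoot
    d_prime = float(min(max(d_prime, 0.0), 1.0))
    r2 = float(min(max(r2, 0.0), 1.0))
    return LdResult(snp1=snp1, snp2=snp2, D=float(D), d_prime=d_prime, r2=r2,
                    n_informative=h.n_informative)


def ld_matrix(ds: CohortDataset, snp_ids: Sequence[str] | None = None) -> list[LdResult]:
    """All pairwise LD results (i < j) for the requested SNPs.

    Individuals are pairwise-complete per pair; degenerate pairs propagate
    their flag.  The implied matrix is symmetric with diagonal r^2 = 1 for
    polymorphic loci.
    """
    ids = list(snp_ids) if snp_ids is not None else ds.snp_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 SNPs for an LD matrix")
    out = []
    for s1, s2 in itertools.combinations(ids, 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = em_haplotypes(ds.dosage_column(s1), ds.dosage_column(s2))
        out.append(ld_stats(h, snp1=s1, snp2=s2))
    return out


def ld_long_frame(results: Sequence[LdResult]) -> pd.DataFrame:
    """Long-format LD table: snp1, snp2, D, Dprime, r2, n."""
    return pd.DataFrame(
        {
            "snp1": [r.snp1 for r in results],
            "snp2": [r.snp2 for r in results],
            "D": [r.D for r in results],
            "Dprime": [r.d_prime for r in results],
            "r2": [r.r2 for r in results],
            "n": [r.n_informative for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def r2_screen(
    ds: CohortDataset,
    focal_snp: str,
    marker_ids: Sequence[str],
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Independence screen: r^2 between a focal SNP and each known marker.

    Returns one row per marker with the estimated r^2 and whether it falls
    at or below ``threshold`` (default 0.15), the conventional bound for
    declaring a signal not tagged by nearby known loci.
    """
    rows = []
    for mid in marker_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = em_haplotypes(ds.dosage_column(focal_snp), ds.dosage_column(mid))
        res = ld_stats(h, snp1=focal_snp, snp2=mid)
        rows.append(
            {"focal": focal_snp, "marker": mid, "r2": res.r2,
             "below_threshold": res.r2 <= threshold, "n": res.n_informative}
        )
    return pd.DataFrame(rows)
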