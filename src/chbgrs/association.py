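"""Per-SNP descriptive statistics and case-control association tests.

Implements the full testing battery of a candidate-gene case-control study:

* minor-allele frequency and Hardy-Weinberg equilibrium (1-df chi-square and
  the Wigginton exact test conditional on allele counts);
* the allele test — a 1-df Pearson chi-square on the 2x2 table of minor vs
  major allele counts in cases and controls, with the cross-product odds
  ratio and a Woolf (log-OR +/- 1.96 SE) confidence interval, Haldane-
  Anscombe 0.5 correction when a cell is empty;
* additive-model logistic regression (dosage 0/1/2 as a linear predictor)
  with optional age/sex covariates, fit by an in-package IRLS Newton solver;
* conditional association (target dosage adjusted for a known marker's
  dosage) for signal-independence analysis, with collinearity flagging;
* Bonferroni correction and a stratified train/test split validation.

All statistics are complete-case per marker: missing dosages are dropped for
the SNP(s) entering each test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln

from .cohort_model import CohortDataset, GenotypeCounts, counts_from_dataset

__all__ = [
    "SnpSummary",
    "AssociationResult",
    "LogisticFit",
    "SplitResult",
    "compute_maf",
    "hwe_test",
    "allele_test",
    "fit_logistic",
    "additive_assoc",
    "conditional_assoc",
    "bonferroni",
    "split_validate",
    "COMPARISONS",
]

#: comparison name -> (group coded y=1, group coded y=0)
COMPARISONS = {
    "CHB_vs_PC": ("case", "control"),
    "HCCneg_vs_PC": ("HCC_neg", "control"),
    "HCCpos_vs_PC": ("HCC_pos", "control"),
    "HCCneg_vs_HCCpos": ("HCC_pos", "HCC_neg"),
}

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class SnpSummary:
    snp_id: str
    group: str
    maf: float
    hwe_p: float
    n_genotyped: int


@dataclass(frozen=True)
class AssociationResult:
    """OR, 95% CI and P for one SNP in one group comparison."""

    snp_id: str
    comparison: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    p_corrected: float
    method: str
    n_case: int = 0
    n_control: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with Wald inference."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    log_likelihood_path: tuple[float, ...] = field(repr=False, default=())
    flags: tuple[str, ...] = ()


# -- descriptive ------------------------------------------------------------


def compute_maf(counts: GenotypeCounts) -> float:
    """Minor-allele frequency from a genotype count triplet."""
    if counts.total == 0:
        raise ValueError("cannot compute MAF from zero genotyped individuals")
    return counts.n_minor_alleles / (2 * counts.total)


def _hwe_chi_square(counts: GenotypeCounts) -> float:
    n = counts.total
    q = compute_maf(counts)
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array(counts.as_tuple(), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    stat = float(np.nansum(terms))
    return float(stats.chi2.sf(stat, df=1))

def _hwe_exact(counts: GenotypeCounts) -> float:
    # Exact test conditional on allele counts (Wigginton et al. convention):
    # sum probabilities of heterozygote configurations no more likely than
    # the observed one.
    n = counts.total
    n_rare = min(counts.n_minor_alleles, counts.n_major_alleles)
    obs_het = counts.n_het
    parity = n_rare % 2
    hets = np.arange(parity, n_rare + 1, 2)
    # log P(het = h | n, n_rare) up to a constant:
    #   n! / (hom_r! h! hom_c!) * 2^h  with hom_r=(n_rare-h)/2, hom_c=n-h-hom_r
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = hets * math.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == obs_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(counts: GenotypeCounts, method: str = "chi_square") -> float:
    """Hardy-Weinberg equilibrium P value for one group's genotype counts."""
    if counts.total == 0:
        raise ValueError("cannot test HWE with zero genotyped individuals")
    if counts.n_minor_alleles == 0 or counts.n_major_alleles == 0:
        warnings.warn("monomorphic SNP: HWE P set to 1", stacklevel=2)
        return 1.0
    if method == "chi_square":
        return _hwe_chi_square(counts)
    if method == "exact":
        return _hwe_exact(counts)
    raise ValueError(f"unknown HWE method {method!r}")


# -- allele test ------------------------------------------------------------


def allele_test(case: GenotypeCounts, control: GenotypeCounts, snp_id: str = "",
                comparison: str = "CHB_vs_PC") -> AssociationResult:
    """Allele-based 2x2 association test.

    Builds the table (case minor, case major; control minor, control major),
    reports the minor-allele cross-product odds ratio with a Woolf 95% CI and
    a 1-df Pearson chi-square P.  If any cell is zero, 0.5 is added to all
    four cells for the OR/CI (Haldane-Anscombe).
    """
    if case.total == 0 or control.total == 0:
        raise ValueError("both groups must contain genotyped individuals")
    a = case.n_minor_alleles      # case minor
    b = case.n_major_alleles      # case major
    c = control.n_minor_alleles   # control minor
    d = control.n_major_alleles   # control major
    for margin, name in (
        (a + b, "case alleles"), (c + d, "control alleles"),
        (a + c, "minor alleles"), (b + d, "major alleles"),
    ):
        if margin == 0:
            raise ValueError(f"degenerate allele table: margin '{name}' is zero")
    flags: tuple[str, ...] = ()
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags = ("haldane_correction",)
    or_point = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - Z95 * se)
    ci_high = math.exp(log_or + Z95 * se)
    chi2_stat, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    p = float(max(p, np.nextafter(0, 1)))
    return AssociationResult(
        snp_id=snp_id,
        comparison=comparison,
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        p_corrected=p,
        method="allele_test",
        n_case=case.total,
        n_control=control.total,
        flags=flags,
    )


# -- logistic regression ----------------------------------------------------

_SEPARATION_BOUND = 15.0


def _log_likelihood(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def fit_logistic(
    outcome: Sequence[float] | np.ndarray,
    design: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    on_singular: str = "error",
) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted least squares.

    ``design`` must already include the intercept column.  Convergence is
    declared when the largest absolute coefficient change drops below ``tol``
    (default 1e-8) or after ``max_iter`` (default 100) Newton steps.  Wald
    standard errors come from the inverse observed information at the optimum.

    Perfect separation (any |beta| exceeding 15) is flagged, not raised.  A
    singular information matrix raises by default; with ``on_singular='flag'``
    the fit falls back to the pseudoinverse and is flagged ``'collinear'``.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than predictors ({k})")
    nonconst = X[:, 1:] if k > 1 else X[:, :0]
    if nonconst.shape[1] and np.any(nonconst.std(axis=0) == 0):
        raise ValueError("constant non-intercept column in design matrix")

    beta = np.zeros(k)
    flags: list[str] = []
    ll_path: list[float] = []
    converged = False
    it = 0
    info = np.eye(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        ll_path.append(_log_likelihood(y, mu))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
            if np.linalg.cond(info) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned information matrix")
        except np.linalg.LinAlgError:
            if on_singular == "flag":
                flags.append("collinear")
                step = np.linalg.pinv(info) @ grad
            else:
                raise np.linalg.LinAlgError(
                    "singular information matrix in logistic fit"
                ) from None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    ll_path.append(_log_likelihood(y, mu))
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        flags.append("separation")
        warnings.warn("possible perfect separation: coefficient magnitude > 15", stacklevel=2)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info) if "collinear" in flags else np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return LogisticFit(
        beta=beta,
        se=se,
        z=z,
        p=p,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll_path[-1],
        log_likelihood_path=tuple(ll_path),
        flags=tuple(dict.fromkeys(flags)),
    )


def _comparison_arrays(
    ds: CohortDataset,
    comparison: str,
    snp_ids: Sequence[str],
    covariates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Outcome vector and design matrix (intercept, dosages..., covariates...)."""
    try:
        g1, g0 = COMPARISONS[comparison]
    except KeyError:
        raise ValueError(f"unknown comparison {comparison!r}") from None
    m1, m0 = ds.group_mask(g1), ds.group_mask(g0)
    if not m1.any() or not m0.any():
        raise ValueError(f"comparison {comparison!r}: empty group")
    keep = m1 | m0
    y = m1[keep].astype(float)
    cols = [np.ones(keep.sum())]
    for sid in snp_ids:
        cols.append(ds.dosage_column(sid)[keep])
    pheno = ds.phenotype_frame()
    for cov in covariates:
        if cov not in ("age", "sex"):
            raise ValueError(f"unknown covariate {cov!r}")
        cols.append(pheno.loc[keep, cov].to_numpy(dtype=float))
    X = np.column_stack(cols)
    complete = ~np.isnan(X).any(axis=1)
    y, X = y[complete], X[complete]
    return y, X, int(y.sum()), int((1 - y).sum())


def _wald_result(
    fit: LogisticFit, idx: int, snp_id: str, comparison: str,
    method: str, n_case: int, n_control: int, m: int,
) -> AssociationResult:
    beta, se = fit.beta[idx], fit.se[idx]
    p = float(fit.p[idx])
    flags = fit.flags

    def _exp(x: float) -> float:
        return math.exp(min(max(x, -700.0), 700.0))
    if "collinear" in flags:
        # coefficient not identifiable; report a null result, keep the flag
        return AssociationResult(
            snp_id=snp_id, comparison=comparison, or_point=1.0,
            ci_low=1.0, ci_high=1.0, p_value=1.0, p_corrected=1.0,
            method=method, n_case=n_case, n_control=n_control, flags=flags,
        )
    return AssociationResult(
        snp_id=snp_id,
        comparison=comparison,
        or_point=_exp(beta),
        ci_low=_exp(beta - Z95 * se),
        ci_high=_exp(beta + Z95 * se),
        p_value=p,
        p_corrected=bonferroni(p, m),
        method=method,
        n_case=n_case,
        n_control=n_control,
        flags=flags,
    )


def additive_assoc(
    ds: CohortDataset,
    snp_id: str,
    comparison: str = "CHB_vs_PC",
    covariates: Sequence[str] = (),
    m: int = 1,
) -> AssociationResult:
    """Additive-model logistic association: outcome ~ dosage (+ covariates).

    The reported OR is per copy of the minor allele, exp(beta_dosage).
    Complete-case over dosage and requested covariates.
    """
    y, X, n1, n0 = _comparison_arrays(ds, comparison, [snp_id], covariates)
    if np.nanstd(X[:, 1]) == 0:
        raise ValueError(f"{snp_id}: monomorphic in comparison {comparison!r}")
    fit = fit_logistic(y, X)
    return _wald_result(fit, 1, snp_id, comparison, "additive_logistic", n1, n0, m)


def conditional_assoc(
    ds: CohortDataset,
    snp_id: str,
    conditioning_snp_id: str,
    covariates: Sequence[str] = (),
    comparison: str = "CHB_vs_PC",
    m: int = 1,
) -> AssociationResult:
    """Association of ``snp_id`` conditional on a known marker's dosage.

    The reported P is for the target SNP's coefficient with the conditioning
    marker (and covariates) in the model.  A collinear conditioning marker
    (e.g. r^2 = 1 with the target) yields an unidentifiable coefficient,
    flagged ``'collinear'`` with P = 1.
    """
    if snp_id == conditioning_snp_id:
        raise ValueError("target and conditioning SNP must differ")
    y, X, n1, n0 = _comparison_arrays(ds, comparison, [snp_id, conditioning_snp_id], covariates)
    fit = fit_logistic(y, X, on_singular="flag")
    return _wald_result(fit, 1, snp_id, comparison, "conditional_logistic", n1, n0, m)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, m * p)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return min(1.0, m * p)


# -- split validation -------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    repeat: int
    train: AssociationResult | None
    test: AssociationResult | None
    warning: str | None = None


def split_validate(
    ds: CohortDataset,
    snp_id: str,
    train_fraction: float = 0.5,
    n_repeats: int = 10,
    seed: int = 0,
    method: str = "allele",
) -> list[SplitResult]:
    """Repeated stratified train/test split association for one SNP.

    Each repeat draws a random case/control-stratified split and runs the
    association (allele test by default, ``method='additive'`` for the
    logistic model) independently on the training and test halves.  Splits
    that yield a degenerate table are skipped with a per-split warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(ds.group_mask("case"))
    ctrl_idx = np.flatnonzero(ds.group_mask("control"))
    results: list[SplitResult] = []
    for rep in range(n_repeats):
        train_rows: list[np.ndarray] = []
        test_rows: list[np.ndarray] = []
        for idx in (case_idx, ctrl_idx):
            perm = rng.permutation(idx)
            k = int(round(train_fraction * idx.size))
            train_rows.append(perm[:k])
            test_rows.append(perm[k:])
        try:
            pair = []
            for rows in (np.concatenate(train_rows), np.concatenate(test_rows)):
                sub = CohortDataset(
                    snps=list(ds.snps),
                    dosages=ds.dosages[rows],
                    phenotypes=[ds.phenotypes[i] for i in rows],
                )
                if method == "allele":
                    res = allele_test(
                        counts_from_dataset(sub, snp_id, "case"),
                        counts_from_dataset(sub, snp_id, "control"),
                        snp_id=snp_id,
                    )
                elif method == "additive":
                    res = additive_assoc(sub, snp_id)
                else:
                    raise ValueError(f"unknown split method {method!r}")
                pair.append(res)
            results.append(SplitResult(repeat=rep, train=pair[0], test=pair[1]))
        except ValueError as exc:
            msg = f"split {rep} skipped: {exc}"
            warnings.warn(msg, stacklevel=2)
            results.append(SplitResult(repeat=rep, train=None, test=None, warning=msg))
    return results


def summarize_snp(ds: CohortDataset, snp_id: str, group: str,
                  hwe_method: str = "chi_square") -> SnpSummary:
    """MAF, HWE P and genotyped count for one SNP in one group."""
    counts = counts_from_dataset(ds, snp_id, group)
    if counts.total == 0:
        raise ValueError(f"{snp_id}: no genotyped individuals in group {group!r}")
    return SnpSummary(
        snp_id=snp_id,
        group=group,
        maf=compute_maf(counts),
        hwe_p=hwe_test(counts, method=hwe_method),
        n_genotyped=counts.total,
    )
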