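"""Multiple-testing procedures for GWAS.

Frequentist side: fixed P-value thresholds and Bonferroni (family-wise
error control), and the Benjamini-Hochberg (BH) and Benjamini-Yekutieli
(BY) step-up procedures (false discovery rate control).  Applied to GWAS
they are used on lead-variant P-values after LD clumping, so that each
tested hypothesis corresponds to an approximately independent locus; the
pipeline layer is responsible for passing lead P-values.

Bayesian side: Wakefield's approximate Bayes factor (ABF) and the Bayesian
false discovery probability (BFDP).  With effect estimate theta-hat,
sampling variance V, a N(0, W) effect prior and r = W/(V+W),

    ABF = 1/sqrt(1-r) * exp(-z^2 r / 2),
    BFDP = ABF*PO / (ABF*PO + 1),  PO = (1-pi1)/pi1,

where pi1 is the prior probability that a variant is associated.  Note the
convention: ABF = P(theta-hat | H0) / P(theta-hat | H1), so SMALL values
are evidence against the null.  The Bayesian FDR is controlled by a
step-up on sorted BFDPs: reject the k smallest where k is the largest
index at which their running mean is <= alpha.

Multi-trait: the metaMANOVA statistic t = z' Omega^-1 z (chi-square with L
degrees of freedom under the global null, Omega the trait correlation
matrix estimated from null variants), a multivariate extension of the ABF,
and the parallel-univariate adjustment that divides P thresholds by L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class ProcedureResult:
    """Rejection set plus the procedure's internals."""

    procedure: str                 # fixed_p | bonferroni | bh | by | bfdp
    alpha: float
    rejected_ids: list[str]        # ordered by score ascending
    k_reject: int
    correction_factor: float = 1.0  # c(m) for BY, 1 otherwise
    per_id_score: dict = field(default_factory=dict)  # id -> p or BFDP used
    m: int = 0

    def __post_init__(self):
        assert self.k_reject == len(self.rejected_ids)


def _sorted_items(score_map):
    """(ids, scores) sorted ascending by score, ties by id (deterministic)."""
    items = sorted(score_map.items(), key=lambda kv: (kv[1], kv[0]))
    ids = [k for k, _ in items]
    scores = np.array([v for _, v in items], dtype=float)
    return ids, scores


def fixed_threshold(pvals: dict, alpha_p: float) -> ProcedureResult:
    """Reject every variant with P strictly below ``alpha_p``.

    The strict inequality matches the conventional reading of
    "P < 5e-8"; a P-value exactly at the cutoff is not rejected.
    """
    ids, p = _sorted_items(pvals)
    k = int(np.searchsorted(p, alpha_p, side="left"))
    return ProcedureResult("fixed_p", alpha_p, ids[:k], k,
                           per_id_score=dict(pvals), m=len(ids))


def bonferroni(pvals: dict, alpha: float, m_eff: int | None = None) -> ProcedureResult:
    """Bonferroni FWER control: reject P <= alpha/m.

    ``m_eff`` substitutes an effective number of independent tests for the
    raw test count, loosening the cutoff when tests are correlated (the
    genome-wide 5e-8 convention is alpha=0.05 over one million effective
    common-variant tests).
    """
    m = len(pvals)
    denom = m_eff if m_eff is not None else m
    if m_eff is not None and m_eff > m:
        raise ValueError("m_eff cannot exceed the number of tests")
    ids, p = _sorted_items(pvals)
    cutoff = alpha / denom
    k = int(np.searchsorted(p, cutoff, side="right"))
    return ProcedureResult("bonferroni", alpha, ids[:k], k,
                           per_id_score=dict(pvals), m=m)


def _stepup(ids, scores, thresholds):
    """Largest k with scores[k-1] <= thresholds[k-1]; reject the k smallest."""
    ok = np.flatnonzero(scores <= thresholds)
    return 0 if len(ok) == 0 else int(ok[-1]) + 1


def harmonic_number(m: int) -> float:
    """c(m) = sum_{i=1..m} 1/i, the BY dependency correction factor."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def bh(pvals: dict, alpha: float) -> ProcedureResult:
    """Benjamini-Hochberg step-up at FDR level ``alpha``.

    Sort P ascending; k = max{k : p(k) <= k*alpha/m}; reject the k
    smallest.  Valid under positive regression dependence, hence applied to
    clumped lead variants in GWAS.
    """
    ids, p = _sorted_items(pvals)
    m = len(ids)
    k = _stepup(ids, p, np.arange(1, m + 1) * alpha / m)
    return ProcedureResult("bh", alpha, ids[:k], k, correction_factor=1.0,
                           per_id_score=dict(pvals), m=m)


def by(pvals: dict, alpha: float) -> ProcedureResult:
    """Benjamini-Yekutieli step-up: BH with threshold k*alpha/(m*c(m)).

    The harmonic factor c(m) buys validity under arbitrary dependence at
    the price of substantial conservatism.
    """
    ids, p = _sorted_items(pvals)
    m = len(ids)
    c = harmonic_number(m)
    k = _stepup(ids, p, np.arange(1, m + 1) * alpha / (m * c))
    return ProcedureResult("by", alpha, ids[:k], k, correction_factor=c,
                           per_id_score=dict(pvals), m=m)


# ---- Bayesian FDR ---------------------------------------------------------

def estimate_pi1(stats: SummaryStats, p_cut: float = 5e-8,
                 mode: str = "proportion", floor: bool = True) -> float:
    """Estimate the prior probability pi1 that a variant is associated.

    ``mode="proportion"`` (default): the proportion of tested variants with
    P < p_cut, a conservative plug-in.  ``mode="loci_per_million"``: the
    number of significant loci divided by one million, an estimate of the
    count of independent common variants genome-wide; pass the lead-variant
    stats in that case.  A zero estimate would make the prior odds
    infinite, so the value is floored at 1/(10 m) with a logged warning.
    """
    m = stats.m
    if m < 1:
        raise ValueError("empty study")
    n_sig = int((stats.table["P"].to_numpy() < p_cut).sum())
    if mode == "proportion":
        pi1 = n_sig / m
    elif mode == "loci_per_million":
        pi1 = n_sig / 1e6
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if floor and pi1 < 1.0 / (10 * m):
        logger.warning("pi1 estimate %.3g floored at 1/(10m)=%.3g", pi1,
                       1.0 / (10 * m))
        pi1 = 1.0 / (10 * m)
    return float(pi1)


def prior_odds(pi1: float) -> float:
    """PO = (1 - pi1)/pi1, the prior odds of no association."""
    if not 0 < pi1 < 1:
        raise ValueError("pi1 must lie strictly between 0 and 1")
    return (1.0 - pi1) / pi1


def abf(z, V, W):
    """Wakefield approximate Bayes factor (null over alternative).

    With r = W/(V+W): ABF = (1-r)^{-1/2} exp(-z^2 r/2).  Equals the density
    ratio N(theta_hat; 0, V) / N(theta_hat; 0, V+W) at theta_hat = z*sqrt(V).
    Accepts scalars or arrays; values below 1 favor association.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(V <= 0) or np.any(W <= 0):
        raise ValueError("V and W must be positive")
    r = W / (V + W)
    out = np.exp(-0.5 * z**2 * r) / np.sqrt(1.0 - r)
    return float(out) if out.ndim == 0 else out


def bfdp(abf_value, po):
    """Bayesian false discovery probability ABF*PO/(ABF*PO + 1)."""
    a = np.asarray(abf_value, dtype=float)
    if np.any(a < 0) or po <= 0:
        raise ValueError("ABF and prior odds must be positive")
    out = a * po / (a * po + 1.0)
    return float(out) if out.ndim == 0 else out


def bfdp_from_stats(z, se, W: float, pi1: float):
    """BFDP per variant from Z, its standard error and the prior (W, pi1)."""
    se = np.asarray(se, dtype=float)
    return bfdp(abf(z, se**2, W), prior_odds(pi1))


def bayesian_fdr_stepup(bfdps: dict, alpha: float) -> ProcedureResult:
    """Control the Bayesian FDR: reject the k smallest BFDPs where k is the
    largest index at which their running mean is <= alpha."""
    ids, b = _sorted_items(bfdps)
    m = len(ids)
    means = np.cumsum(b) / np.arange(1, m + 1)
    ok = np.flatnonzero(means <= alpha)
    k = 0 if len(ok) == 0 else int(ok[-1]) + 1
    return ProcedureResult("bfdp", alpha, ids[:k], k,
                           per_id_score=dict(bfdps), m=m)


# ---- multi-trait ----------------------------------------------------------

@dataclass
class TraitCorrelation:
    """Estimated correlation matrix Omega of Z statistics across L traits."""

    omega: np.ndarray
    trait_names: list[str]

    @property
    def L(self) -> int:
        return self.omega.shape[0]

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (len(self.trait_names),) * 2:
            raise ValueError("omega shape does not match trait count")
        if not np.allclose(om, om.T) or not np.allclose(np.diag(om), 1.0):
            raise ValueError("omega must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(om).min() <= 1e-8:
            raise ValueError("omega must be positive definite")
        self.omega = om


def estimate_trait_correlation(zmat: np.ndarray, trait_names=None,
                               null_mask=None, z_max: float = 2.0
                               ) -> TraitCorrelation:
    """Estimate Omega from a variants x L matrix of Z statistics.

    Under the null the Z vectors are multivariate normal with correlation
    equal to the residual trait correlation, so Omega is the Pearson
    correlation of the Z columns over (approximately) null variants —
    by default those with max |Z| < ``z_max``.  Truncating at ``z_max``
    attenuates the estimate somewhat (a known property of this standard
    plug-in, traded for robustness to genuine signal); pass an explicit
    ``null_mask`` of known-null variants for an unbiased estimate.  A ridge
    of 1e-6 is added if the estimate is numerically non-positive-definite.
    """
    zmat = np.asarray(zmat, dtype=float)
    L = zmat.shape[1]
    if trait_names is None:
        trait_names = [f"trait{i+1}" for i in range(L)]
    if L == 1:
        return TraitCorrelation(np.eye(1), list(trait_names))
    if null_mask is None:
        null_mask = np.abs(zmat).max(axis=1) < z_max
    sub = zmat[np.asarray(null_mask, dtype=bool)]
    if len(sub) < 100:
        raise ValueError("need at least 100 null variants to estimate omega")
    om = np.corrcoef(sub, rowvar=False)
    om = (om + om.T) / 2.0
    np.fill_diagonal(om, 1.0)
    while np.linalg.eigvalsh(om).min() <= 1e-8:
        logger.warning("trait correlation not positive definite; adding ridge")
        om = om + 1e-6 * np.eye(L)
        om = om / np.sqrt(np.outer(np.diag(om), np.diag(om)))
    return TraitCorrelation(om, list(trait_names))


def meta_manova(zvec: np.ndarray, omega: TraitCorrelation):
    """Joint test across L traits: t = z' Omega^{-1} z, chi-square_L P-value."""
    z = np.asarray(zvec, dtype=float)
    if z.shape != (omega.L,):
        raise ValueError("z vector length does not match omega")
    t = float(z @ np.linalg.solve(omega.omega, z))
    return t, float(sps.chi2.sf(t, omega.L))


def meta_manova_scan(zmat: np.ndarray, omega: TraitCorrelation):
    """Vectorized metaMANOVA over a variants x L Z matrix -> (t, p) arrays."""
    zmat = np.asarray(zmat, dtype=float)
    sol = np.linalg.solve(omega.omega, zmat.T)
    t = np.einsum("ij,ji->i", zmat, sol)
    return t, sps.chi2.sf(t, omega.L)


def multivariate_abf(zvec: np.ndarray, omega: TraitCorrelation, W: float) -> float:
    """Multi-trait extension of the ABF on the Z-vector scale.

    Density ratio N_L(z; 0, Omega) / N_L(z; 0, Omega + W I): the null
    predictive over an alternative with independent standardized effects of
    common prior variance W.  Reduces exactly to the univariate ABF with
    V = 1 when L = 1.
    """
    z = np.asarray(zvec, dtype=float)
    if W <= 0:
        raise ValueError("W must be positive")
    alt = omega.omega + W * np.eye(omega.L)
    if np.linalg.eigvalsh(alt).min() <= 0:
        raise ValueError("alternative covariance not positive definite")
    log_null = sps.multivariate_normal.logpdf(z, mean=np.zeros(omega.L),
                                              cov=omega.omega)
    log_alt = sps.multivariate_normal.logpdf(z, mean=np.zeros(omega.L),
                                             cov=alt)
    return float(np.exp(log_null - log_alt))


@dataclass
class MultiTraitResult:
    """Union of per-trait fixed-threshold rejections with trait provenance."""

    per_trait: dict                     # trait -> ProcedureResult
    union_ids: list[str]
    provenance: dict                    # id -> list of traits rejecting it
    cutoff: float


def univariate_multi_trait(pvals_per_trait: dict, alpha_p: float,
                           L: int | None = None) -> MultiTraitResult:
    """Parallel univariate testing of L traits at a per-trait cutoff alpha_p/L.

    Dividing the threshold by the number of traits Bonferroni-corrects for
    testing each variant against L traits (e.g. 5e-8/3 = 1.67e-8 for three
    lipid traits).  A variant significant for several traits appears once
    in the union, with every rejecting trait listed.
    """
    if L is None:
        L = len(pvals_per_trait)
    if L < 1:
        raise ValueError("L must be at least 1")
    cutoff = alpha_p / L
    per_trait = {t: fixed_threshold(pv, cutoff)
                 for t, pv in pvals_per_trait.items()}
    provenance: dict[str, list[str]] = {}
    for t, res in per_trait.items():
        for vid in res.rejected_ids:
            provenance.setdefault(vid, []).append(t)
    union = sorted(provenance)
    return MultiTraitResult(per_trait, union, provenance, cutoff)
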