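"""Multivariable MR: joint estimation over several exposures and
conditional instrument-strength diagnostics.

The model regresses the SNP-outcome effects on the L columns of SNP-exposure
effects jointly (weighted least squares, no intercept, weights se_out^-2),
so each exposure's coefficient is its direct effect on the outcome holding
the other exposures fixed. Covariance between the SNP-exposure effect
estimates is taken as zero, appropriate when the exposure GWAS come from
non-overlapping cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MultiExposureSet", "MVMRResult", "mvmr_fit", "conditional_f"]


@dataclass
class MultiExposureSet:
    """Per-SNP effects on L >= 2 exposures and one outcome.

    ``beta_exp`` and ``se_exp`` are (J, L) arrays; ``beta_out`` and
    ``se_out`` are length-J vectors. Requires more SNPs than exposures.
    """

    outcome_name: str
    exposures: list[str]
    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray

    def __post_init__(self):
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, float))
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        j, l = self.beta_exp.shape
        if l != len(self.exposures) or l < 2:
            raise ValueError("need >= 2 exposures matching beta_exp columns")
        if not (np.all(self.se_exp > 0) and np.all(self.se_out > 0)):
            raise ValueError("all standard errors must be > 0")
        if j <= l:
            raise ValueError(
                f"need more SNPs than exposures (J={j}, L={l})")

    @property
    def J(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def L(self) -> int:
        return self.beta_exp.shape[1]


@dataclass
class MVMRResult:
    exposures: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    conditional_f: np.ndarray
    weak_instruments: bool
    q_a: float
    q_a_df: int
    q_a_pval: float
    n_snps: int = 0


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via normal equations; returns coef, cov of
    coef (unscaled), weighted RSS."""
    xtw = x.T * w
    xtx = xtw @ x
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("rank-deficient design")
    cov = np.linalg.inv(xtx)
    coef = cov @ (xtw @ y)
    resid = y - x @ coef
    rss = float(np.sum(w * resid ** 2))
    return coef, cov, rss


def mvmr_fit(mset: MultiExposureSet) -> MVMRResult:
    """Fit the multivariable MR model.

    Coefficient SEs are inflated by the residual standard error when it
    exceeds 1 (multiplicative overdispersion, mirroring the random-effects
    IVW convention); Q_a, the weighted residual sum of squares, measures
    instrument heterogeneity against chi-square(J - L).
    """
    j, l = mset.J, mset.L
    w = mset.se_out ** -2.0
    try:
        coef, cov, rss = _wls(mset.beta_exp, mset.beta_out, w)
    except np.linalg.LinAlgError:
        raise ValueError(
            "rank-deficient exposure design; collinear exposures: "
            + ", ".join(mset.exposures)) from None
    df = j - l
    scale = max(1.0, np.sqrt(rss / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * scale
    pvals = 2.0 * stats.norm.sf(np.abs(coef / ses))
    fk = conditional_f(mset)
    return MVMRResult(exposures=list(mset.exposures), estimates=coef,
                      ses=ses, pvals=pvals, conditional_f=fk,
                      weak_instruments=bool(np.any(fk <= 10.0)),
                      q_a=rss, q_a_df=df,
                      q_a_pval=float(stats.chi2.sf(rss, df)), n_snps=j)


def conditional_f(mset: MultiExposureSet) -> np.ndarray:
    """Conditional instrument strength per exposure.

    For exposure k, its SNP-effect column is regressed on the remaining
    exposures' columns (weights se_exp[:, k]^-2, no intercept); the weighted
    residual sum of squares Q_xk over J - L degrees of freedom is the
    conditional F. Strength requires F strictly above 10: an exposure whose
    instruments are explained by the other exposures has F near 0 however
    strong they are marginally.
    """
    j, l = mset.J, mset.L
    out = np.empty(l)
    for k in range(l):
        y = mset.beta_exp[:, k]
        x = np.delete(mset.beta_exp, k, axis=1)
        w = mset.se_exp[:, k] ** -2.0
        try:
            _, _, rss = _wls(x, y, w)
        except np.linalg.LinAlgError:
            raise ValueError(
                "rank-deficient exposure design; collinear exposures: "
                + ", ".join(n for i, n in enumerate(mset.exposures) if i != k)
            ) from None
        out[k] = rss / (j - l)
    return out
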