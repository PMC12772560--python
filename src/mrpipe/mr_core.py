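"""Two-sample MR estimators and sensitivity diagnostics.

Given per-SNP harmonized effects (beta_exp_j, se_exp_j, beta_out_j,
se_out_j) the per-SNP Wald ratio is b_j = beta_out_j / beta_exp_j with
first-order standard error s_j = se_out_j / |beta_exp_j| and
inverse-variance weight w_j = s_j^-2.

Estimators
----------
* ``ivw`` — multiplicative random-effects inverse-variance-weighted
  estimate: through-origin WLS of outcome on exposure effects with weights
  se_out^-2; the fixed-effects SE is inflated by sqrt(Q/(J-1)) when
  Cochran's Q exceeds its degrees of freedom (never deflated below the
  fixed-effects SE).
* ``egger`` — WLS with an intercept after orienting all exposure effects
  non-negative; the intercept estimates average directional pleiotropy.
* ``weighted_median`` — weighted 50% quantile of the ordered Wald ratios;
  consistent while valid instruments carry >50% of the weight. SE by
  parametric bootstrap.
* ``weighted_mode`` — mode of a weighted normal-kernel density over the
  Wald ratios (Silverman-type bandwidth scaled by ``phi``); consistent when
  the largest group of instruments sharing a ratio is valid. SE by
  parametric bootstrap.

All p-values use the normal reference distribution, the summary-data MR
convention at typical instrument counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedInstrumentSet

__all__ = [
    "RatioEstimates",
    "MRResult",
    "RadialResult",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "heterogeneity",
    "radial_outliers",
]


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios, first-order SEs and inverse-variance weights."""

    snp_ids: list[str]
    b: np.ndarray          # Wald ratios beta_out / beta_exp
    s: np.ndarray          # first-order SEs se_out / |beta_exp|
    w: np.ndarray          # weights s^-2
    dropped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    pval: float
    n_snps: int
    cochran_q: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")
    i2: float = float("nan")
    i2_gx: float = float("nan")
    egger_intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    re_scale: float = float("nan")


@dataclass
class RadialResult:
    snp_ids: list[str]
    q_contributions: np.ndarray
    q_pvals: np.ndarray
    outliers: list[str]
    alpha: float
    iterations: int
    total_q: float


def _normal_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


def _extract(hset) -> tuple[np.ndarray, ...]:
    if isinstance(hset, HarmonizedInstrumentSet):
        bx, sx, _, by, sy, _ = hset.arrays()
        ids = [r.snp_id for r in hset.records]
    else:  # (snp_ids, beta_exp, se_exp, beta_out, se_out) tuple for callers
        ids, bx, sx, by, sy = hset
        bx, sx = np.asarray(bx, float), np.asarray(sx, float)
        by, sy = np.asarray(by, float), np.asarray(sy, float)
    return list(ids), bx, sx, by, sy


def wald_ratios(hset) -> RatioEstimates:
    """Per-SNP causal-effect ratios; SNPs with zero exposure effect are
    dropped (their ratio is undefined) and logged."""
    ids, bx, sx, by, sy = _extract(hset)
    nz = bx != 0
    dropped = [(ids[i], "zero_exposure_effect") for i in np.flatnonzero(~nz)]
    if not nz.any():
        raise ValueError("no usable instruments")
    ids = [s for s, keep in zip(ids, nz) if keep]
    b = by[nz] / bx[nz]
    s = sy[nz] / np.abs(bx[nz])
    return RatioEstimates(ids, b, s, s ** -2, dropped)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Through-origin WLS slope, fixed SE, ratio-scale Q and MRE scale."""
    w_out = sy ** -2.0
    den = float(np.sum(w_out * bx * bx))
    theta = float(np.sum(w_out * bx * by)) / den
    fixed_se = den ** -0.5
    nz = bx != 0
    b = by[nz] / bx[nz]
    w = (np.abs(bx[nz]) / sy[nz]) ** 2.0
    q = float(np.sum(w * (b - theta) ** 2))
    df = int(nz.sum()) - 1
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    return theta, fixed_se, q, df, scale


def ivw(hset, method_label: str = "ivw_mre") -> MRResult:
    """Multiplicative random-effects IVW estimate (needs >= 2 SNPs)."""
    ids, bx, sx, by, sy = _extract(hset)
    j = len(ids)
    if j < 2:
        raise ValueError("ivw requires at least 2 SNPs; use wald_ratios for one")
    theta, fixed_se, q, df, scale = _ivw_core(bx, by, sy)
    se = fixed_se * scale
    q_p, i2, i2_gx = _q_summaries(q, df, bx, sx)
    return MRResult(method=method_label, estimate=theta, se=se,
                    pval=float(_normal_p(theta / se)), n_snps=j,
                    cochran_q=q, q_df=df, q_pval=q_p, i2=i2, i2_gx=i2_gx,
                    re_scale=scale)


def egger(hset) -> MRResult:
    """MR-Egger regression (needs >= 3 SNPs): WLS of outcome on exposure
    effects with an intercept, exposure effects oriented non-negative.
    SEs are inflated by the residual standard error when it exceeds 1."""
    ids, bx, sx, by, sy = _extract(hset)
    j = len(ids)
    if j < 3:
        raise ValueError("egger requires at least 3 SNPs")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy ** -2.0
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    coef = cov @ (xtw @ by)
    resid = by - x @ coef
    rse = np.sqrt(float(np.sum(w * resid ** 2)) / (j - 2))
    scale = max(1.0, rse)
    ses = np.sqrt(np.diag(cov)) * scale
    slope, slope_se = float(coef[1]), float(ses[1])
    icept, icept_se = float(coef[0]), float(ses[0])
    return MRResult(method="egger", estimate=slope, se=slope_se,
                    pval=float(_normal_p(slope / slope_se)), n_snps=j,
                    egger_intercept=icept, intercept_se=icept_se,
                    intercept_p=float(_normal_p(icept / icept_se)))


def _weighted_median_1d(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[k] == 0.5:
        return float(b[k])
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return float(b[k] + frac * (b[k + 1] - b[k]))


def _bootstrap_se(estimator, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    j = len(bx)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    est = np.array([estimator(bxs[i], bys[i]) for i in range(n_boot)])
    return float(np.std(est, ddof=1))


def weighted_median(hset, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median MR estimate (needs >= 3 SNPs).

    The estimate is the inverse-variance-weighted 50% quantile of the
    ordered Wald ratios, interpolated linearly between cumulative weight
    midpoints; the SE comes from a parametric bootstrap resampling the
    observed exposure and outcome effects from their sampling distributions.
    """
    ids, bx, sx, by, sy = _extract(hset)
    if len(ids) < 3:
        raise ValueError("weighted_median requires at least 3 SNPs")
    r = wald_ratios((ids, bx, sx, by, sy))
    est = _weighted_median_1d(r.b, r.w)

    def one(bx_i, by_i):
        nz = bx_i != 0
        b = by_i[nz] / bx_i[nz]
        w = (np.abs(bx_i[nz]) / sy[nz]) ** 2
        return _weighted_median_1d(b, w)

    se = _bootstrap_se(one, bx, sx, by, sy, n_boot, seed)
    p = float(_normal_p(est / se)) if se > 0 else (0.0 if est != 0 else 1.0)
    return MRResult(method="weighted_median", estimate=est, se=se, pval=p,
                    n_snps=len(ids))


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    sd = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(b) ** (-1 / 5)


def _weighted_mode_1d(b: np.ndarray, w: np.ndarray, phi: float,
                      grid_size: int = 2001) -> float:
    h = _mode_bandwidth(b, phi)
    if h <= 0:  # all ratios (effectively) identical
        return float(b[0])
    lo, hi = b.min() - 3 * h, b.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    wn = w / w.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ wn
    # ties resolved toward the smallest mode
    return float(grid[int(np.argmax(dens))])


def weighted_mode(hset, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MRResult:
    """Weighted-mode MR estimate (needs >= 3 SNPs): the maximiser of a
    weighted normal-kernel density over the Wald ratios, bandwidth
    h = phi * 0.9 * min(SD, IQR/1.349) * J^(-1/5). Identical ratios give a
    degenerate density; the common ratio is returned with SE 0."""
    ids, bx, sx, by, sy = _extract(hset)
    if len(ids) < 3:
        raise ValueError("weighted_mode requires at least 3 SNPs")
    r = wald_ratios((ids, bx, sx, by, sy))
    if np.all(r.b == r.b[0]):
        return MRResult(method="weighted_mode", estimate=float(r.b[0]),
                        se=0.0, pval=1.0 if r.b[0] == 0 else 0.0,
                        n_snps=len(ids))
    est = _weighted_mode_1d(r.b, r.w, phi)

    def one(bx_i, by_i):
        nz = bx_i != 0
        b = by_i[nz] / bx_i[nz]
        w = (np.abs(bx_i[nz]) / sy[nz]) ** 2
        return _weighted_mode_1d(b, w, phi, grid_size=501)

    se = _bootstrap_se(one, bx, sx, by, sy, n_boot, seed)
    p = float(_normal_p(est / se)) if se > 0 else (0.0 if est != 0 else 1.0)
    return MRResult(method="weighted_mode", estimate=est, se=se, pval=p,
                    n_snps=len(ids))


def _q_summaries(q: float, df: int, bx: np.ndarray, sx: np.ndarray):
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    # NOME diagnostic: heterogeneity of the SNP-exposure effects themselves
    wx = sx ** -2.0
    bbar = float(np.sum(wx * bx) / np.sum(wx))
    q_gx = float(np.sum(wx * (bx - bbar) ** 2))
    i2_gx = max(0.0, (q_gx - df) / q_gx) if q_gx > 0 else 0.0
    return q_p, i2, i2_gx


def heterogeneity(hset) -> tuple[float, float, float, float]:
    """Cochran's Q on the Wald-ratio scale with its chi-square p-value, the
    ratio-scale I² and the NOME I²_GX diagnostic, as (Q, q_pval, i2, i2_gx)."""
    ids, bx, sx, by, sy = _extract(hset)
    if len(ids) < 2:
        raise ValueError("heterogeneity requires at least 2 SNPs")
    _, _, q, df, _ = _ivw_core(bx, by, sy)
    q_p, i2, i2_gx = _q_summaries(q, df, bx, sx)
    return q, q_p, i2, i2_gx


def radial_outliers(hset, alpha: float = 0.05,
                    iterate: bool = False, max_iter: int = 10) -> RadialResult:
    """Radial-MR outlier screen (needs >= 3 SNPs).

    Each SNP's contribution to Cochran's Q, Q_j = w_j (b_j - theta)², is
    referred to chi-square(1); SNPs with p < alpha are flagged (no
    multiplicity correction). With ``iterate`` the fit is repeated without
    the flagged SNPs until none remains or ``max_iter`` passes.
    """
    ids, bx, sx, by, sy = _extract(hset)
    if len(ids) < 3:
        raise ValueError("radial_outliers requires at least 3 SNPs")
    all_out: list[str] = []
    cur = np.arange(len(ids))
    iters = 0
    while True:
        iters += 1
        theta, _, q, _, _ = _ivw_core(bx[cur], by[cur], sy[cur])
        b = by[cur] / bx[cur]
        w = (np.abs(bx[cur]) / sy[cur]) ** 2
        qj = w * (b - theta) ** 2
        pj = stats.chi2.sf(qj, 1)
        flagged = pj < alpha
        if iters == 1:
            first_q, first_qj, first_pj, first_ids = q, qj, pj, [ids[i] for i in cur]
        new = [ids[cur[i]] for i in np.flatnonzero(flagged)]
        all_out.extend(new)
        if not iterate or not new or iters >= max_iter or (~flagged).sum() < 3:
            break
        cur = cur[~flagged]
    return RadialResult(snp_ids=first_ids, q_contributions=first_qj,
                        q_pvals=first_pj, outliers=all_out, alpha=alpha,
                        iterations=iters, total_q=first_q)


def remove_snps(hset: HarmonizedInstrumentSet, snp_ids,
                reason: str = "radial_outlier") -> HarmonizedInstrumentSet:
    """Drop the named SNPs from a harmonized set, logging the reason."""
    drop = set(snp_ids)
    present = {r.snp_id for r in hset.records}
    kept = [r for r in hset.records if r.snp_id not in drop]
    extra = [(s, "dropped", reason) for s in sorted(drop & present)]
    return hset.replaced(kept, extra)
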