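"""Two-sample MR estimators and diagnostics.

All estimators operate on harmonized per-variant pairs: exposure effect
``bx`` with standard error ``sx``, outcome effect ``by`` with standard error
``sy``, both referring to the same effect allele.  Outcome effects for a
binary trait are log-odds ratios, so causal estimates exponentiate to odds
ratios per unit of exposure.

Implemented: Wald ratio, inverse-variance-weighted (fixed and multiplicative
random effects), MR-Egger with its intercept test for directional pleiotropy,
the weighted median with a parametric-bootstrap standard error, Cochran's Q,
leave-one-out influence analysis, and MR-PRESSO (global RSS test, per-variant
outlier test, distortion test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError, DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedData

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class MRData:
    """Harmonized instrument arrays for one exposure/outcome analysis."""

    variant_ids: np.ndarray
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray

    def __post_init__(self):
        n = len(self.bx)
        for name in ("variant_ids", "sx", "by", "sy"):
            if len(getattr(self, name)) != n:
                raise DomainError("MRData arrays must have equal length")
        if n and (np.any(self.sx <= 0) or np.any(self.sy <= 0)):
            raise DomainError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.bx)

    @classmethod
    def from_harmonized(cls, h: HarmonizedData) -> "MRData":
        p = h.pairs
        return cls(
            variant_ids=p["variant_id"].to_numpy(dtype=object),
            bx=p["beta_exposure"].to_numpy(dtype=float),
            sx=p["se_exposure"].to_numpy(dtype=float),
            by=p["beta_outcome"].to_numpy(dtype=float),
            sy=p["se_outcome"].to_numpy(dtype=float),
        )

    @classmethod
    def from_arrays(cls, bx, by, sy, sx=None, variant_ids=None) -> "MRData":
        bx = np.asarray(bx, dtype=float)
        if sx is None:
            sx = np.full_like(bx, np.nan)
        if variant_ids is None:
            variant_ids = np.array([f"snp{i}" for i in range(len(bx))], dtype=object)
        return cls(
            variant_ids=np.asarray(variant_ids, dtype=object),
            bx=bx,
            sx=np.asarray(sx, dtype=float),
            by=np.asarray(by, dtype=float),
            sy=np.asarray(sy, dtype=float),
        )

    def drop(self, mask_or_ids) -> "MRData":
        """New MRData without the masked variants (boolean mask or id list)."""
        if isinstance(mask_or_ids, (list, set, frozenset, tuple, np.ndarray)) and not (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool
        ):
            mask = np.isin(self.variant_ids, list(mask_or_ids))
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        keep = ~mask
        return MRData(self.variant_ids[keep], self.bx[keep], self.sx[keep], self.by[keep], self.sy[keep])


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate, on the outcome's beta scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - Z95 * self.se)), float(np.exp(self.beta + Z95 * self.se)))

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass(frozen=True)
class PleiotropyTest:
    intercept: float
    intercept_se: float
    pval: float


@dataclass(frozen=True)
class HeterogeneityTest:
    q_stat: float
    df: int
    pval: float


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: pd.DataFrame = field(repr=False)  # variant_id, pval_raw, pval_adjusted
    outliers: list = field(default_factory=list)
    distortion_pval: float = float("nan")
    n_simulations: int = 0
    seed: int | None = None


def _two_sided_normal_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, 5e-324), 1.0))


def wald_ratio(bx: float, by: float, sy: float) -> MREstimate:
    """Single-variant causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise DomainError("Wald ratio undefined for zero exposure effect")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald", beta, se, _two_sided_normal_p(beta / se), 1)


def ivw(data: MRData, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Fixed effect: beta = sum(w bx by) / sum(w bx^2), w = 1/sy^2, with
    se = sqrt(1 / sum(w bx^2)).  The multiplicative random-effects variant
    (default when n >= 2) inflates the SE by sqrt(max(1, Q/(n-1))), which
    never reports less uncertainty than the fixed-effect model.
    """
    n = len(data)
    if n < 1:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    w = 1.0 / data.sy**2
    denom = float(np.sum(w * data.bx**2))
    if denom == 0.0:
        raise DegenerateDesignError("all exposure effects are zero")
    beta = float(np.sum(w * data.bx * data.by)) / denom
    se = float(np.sqrt(1.0 / denom))
    method = "ivw_fixed"
    if random_effects and n >= 2:
        q = float(np.sum(w * (data.by - beta * data.bx) ** 2))
        se *= float(np.sqrt(max(1.0, q / (n - 1))))
        method = "ivw_re"
    return MREstimate(method, beta, se, _two_sided_normal_p(beta / se), n)


def egger(data: MRData, t_dist: bool = False) -> tuple[MREstimate, PleiotropyTest]:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Pairs are oriented so bx >= 0 before fitting (the standard convention
    under the InSIDE assumption; the orientation changes the intercept's
    sign but not the slope).  A nonzero intercept indicates directional
    horizontal pleiotropy; "no pleiotropy" is declared at intercept p >= .05.
    """
    n = len(data)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    sgn = np.where(data.bx < 0, -1.0, 1.0)
    x = data.bx * sgn
    y = data.by * sgn
    w = 1.0 / data.sy**2

    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = float(np.sum(w * (x - xbar) ** 2))
    # relative check: exactly-constant bx leaves only rounding noise in sxx
    if sxx <= 1e-24 * sw * max(xbar**2, np.max(x**2), 1e-300):
        raise DegenerateDesignError("zero variance in exposure effects")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    se_slope = float(np.sqrt(1.0 / sxx))
    se_intercept = float(np.sqrt(1.0 / sw + xbar**2 / sxx))

    if t_dist:
        resid = y - intercept - slope * x
        sigma2 = float(np.sum(w * resid**2) / (n - 2))
        scale = np.sqrt(max(sigma2, 1.0))  # never deflate below the known-SE model
        se_slope *= scale
        se_intercept *= scale
        p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df=n - 2))
        p_int = float(2.0 * stats.t.sf(abs(intercept / se_intercept), df=n - 2))
    else:
        p_slope = _two_sided_normal_p(slope / se_slope)
        p_int = _two_sided_normal_p(intercept / se_intercept)
    return (
        MREstimate("egger", slope, se_slope, p_slope, n),
        PleiotropyTest(intercept, se_intercept, p_int),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(data: MRData, n_boot: int = 1000, seed: int | None = 0) -> MREstimate:
    """Weighted-median causal estimate.

    Per-variant Wald ratios are ordered and weighted by bx^2/sy^2; the
    estimate sits at cumulative weight 0.5 (interpolated).  Valid when at
    least half the weight comes from valid instruments.  The SE has no
    closed form and is obtained by a seeded parametric bootstrap that
    resamples (bx, by) from their normal sampling distributions.
    """
    n = len(data)
    if n < 2:
        raise InsufficientInstrumentsError("weighted median needs at least 2 instruments")
    if np.all(data.bx == 0):
        raise DegenerateDesignError("all exposure effects are zero")
    ratios = data.by / data.bx
    weights = data.bx**2 / data.sy**2
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    sx = data.sx
    if np.any(~np.isfinite(sx)):
        sx = np.zeros_like(data.bx)  # exposure SEs unknown: bootstrap the outcome side only
    bx_b = rng.normal(data.bx, sx, size=(n_boot, n))
    by_b = rng.normal(data.by, data.sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bxk = bx_b[k]
        ok = bxk != 0
        boots[k] = _weighted_median_point(by_b[k][ok] / bxk[ok], bxk[ok] ** 2 / data.sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        pval = 1.0 if point == 0 else 5e-324
    else:
        pval = _two_sided_normal_p(point / se)
    return MREstimate("weighted_median", point, se, pval, n)


def cochran_q(data: MRData, at: MREstimate | float, df_offset: int = 1) -> HeterogeneityTest:
    """Cochran's Q at a candidate slope: Q = sum w (by - beta*bx)^2, w = 1/sy^2.

    df = n - 1 for an IVW slope, n - 2 for an Egger fit (``df_offset=2``).
    Homogeneous instruments give an upper-tail chi-square p-value near 1.
    """
    n = len(data)
    if n < 2:
        raise InsufficientInstrumentsError("Cochran Q needs at least 2 instruments")
    beta = at.beta if isinstance(at, MREstimate) else float(at)
    w = 1.0 / data.sy**2
    q = float(np.sum(w * (data.by - beta * data.bx) ** 2))
    df = n - df_offset
    if df < 1:
        raise DomainError("Cochran Q needs df >= 1")
    return HeterogeneityTest(q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(data: MRData, random_effects: bool = True) -> pd.DataFrame:
    """IVW re-estimated with each variant omitted in turn.

    Returns one row per omitted variant: beta, se, pval and an ``influential``
    flag raised when the omission changes the estimate's sign or leaves the
    full-set estimate outside the fixed-effect 95% CI of the reduced fit.
    """
    n = len(data)
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 instruments")
    full = ivw(data, random_effects=random_effects)
    rows = []
    for i in range(n):
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        sub = data.drop(mask)
        est = ivw(sub, random_effects=random_effects)
        est_fixed = ivw(sub, random_effects=False)
        sign_change = np.sign(est.beta) != np.sign(full.beta) and full.beta != 0 and est.beta != 0
        outside = abs(full.beta - est_fixed.beta) > Z95 * est_fixed.se
        rows.append(
            {
                "variant_omitted": data.variant_ids[i],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "influential": bool(sign_change or outside),
            }
        )
    return pd.DataFrame(rows)


def _loo_ivw_fixed_vec(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each variant left out, via sum updates."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx**2) - w * bx**2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def mr_presso(
    data: MRData,
    n_simulations: int = 1000,
    outlier_p_threshold: float = 1.0,
    significance_threshold: float = 0.05,
    seed: int | None = 0,
) -> tuple[PressoResult, MRData]:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    The observed statistic is the weighted leave-one-out residual sum of
    squares.  Its null distribution is simulated by drawing (bx*, by*) from
    normal sampling distributions centred on the observed bx and on each
    variant's leave-one-out IVW prediction.  Per-variant outlier p-values are
    the simulated tail probabilities of each variant's weighted residual,
    Bonferroni-adjusted; variants with adjusted p below ``outlier_p_threshold``
    (default 1: every flagged variant) are removed, but only when the global
    test is significant at ``significance_threshold`` — with a clean
    instrument set nothing is removed.  The distortion test compares the
    change in the IVW estimate after outlier removal against removals of
    random subsets of the same size.  Fully deterministic given ``seed``.
    """
    n = len(data)
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    if n_simulations < 1:
        raise DomainError("n_simulations must be >= 1")
    rng = np.random.default_rng(seed)
    w = 1.0 / data.sy**2
    sx = data.sx
    if np.any(~np.isfinite(sx)):
        sx = np.zeros(n)

    beta_loo = _loo_ivw_fixed_vec(data.bx, data.by, w)
    resid_obs = data.by - beta_loo * data.bx
    rss_terms_obs = w * resid_obs**2
    rss_obs = float(np.sum(rss_terms_obs))

    # simulate under the no-pleiotropy model
    bx_sim = rng.normal(data.bx, sx, size=(n_simulations, n))
    by_sim = rng.normal(beta_loo * data.bx, data.sy, size=(n_simulations, n))
    num = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True) - w * bx_sim * by_sim
    den = np.sum(w * bx_sim**2, axis=1, keepdims=True) - w * bx_sim**2
    beta_loo_sim = num / den
    rss_terms_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(rss_terms_sim, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_simulations + 1))
    p_raw = (1 + np.sum(rss_terms_sim >= rss_terms_obs[None, :], axis=0)) / (n_simulations + 1)
    p_adj = np.minimum(1.0, n * p_raw)
    outlier_tbl = pd.DataFrame(
        {"variant_id": data.variant_ids, "pval_raw": p_raw, "pval_adjusted": p_adj}
    )

    outliers: list = []
    if global_pval < significance_threshold:
        outliers = list(data.variant_ids[p_adj < outlier_p_threshold])

    distortion_pval = float("nan")
    retained = data
    if outliers and len(outliers) < n - 1:
        retained = data.drop(outliers)
        beta_all = ivw(data, random_effects=False).beta
        beta_out = ivw(retained, random_effects=False).beta
        if beta_out != 0.0:
            d_obs = (beta_all - beta_out) / abs(beta_out)
            k = len(outliers)
            d_sim = np.empty(n_simulations)
            idx = np.arange(n)
            for s in range(n_simulations):
                drop = rng.choice(idx, size=k, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[drop] = True
                b_sub = ivw(data.drop(mask), random_effects=False).beta
                d_sim[s] = (beta_all - b_sub) / abs(b_sub) if b_sub != 0 else np.inf
            distortion_pval = float(
                (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_simulations + 1)
            )

    result = PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_tbl,
        outliers=outliers,
        distortion_pval=distortion_pval,
        n_simulations=n_simulations,
        seed=seed,
    )
    return result, retained
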