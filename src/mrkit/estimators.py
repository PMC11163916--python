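"""Two-sample Mendelian randomization estimators and sensitivity statistics.

The three causal estimators are scikit-learn style regressors fit on the
per-variant effect pairs (x_j = instrument-exposure effect, y_j =
instrument-outcome effect, with the outcome standard errors supplied as
``se_y``):

* :class:`IVWEstimator` — inverse-variance-weighted regression of y on x
  through the origin with weights 1/se_y^2; the meta-analysis of per-variant
  Wald ratios. Multiplicative random effects by default (the SE is inflated
  by sqrt(Q/df) when Cochran's Q exceeds its degrees of freedom, never
  deflated).
* :class:`MREggerEstimator` — the same weighted regression with an
  unconstrained intercept; a nonzero intercept estimates the average
  directional pleiotropic effect, and the slope remains a consistent causal
  estimate under the InSIDE assumption. Inference uses t(n-2).
* :class:`WeightedMedianEstimator` — the weighted median of the per-variant
  Wald ratios; consistent when valid instruments carry more than half of
  the total weight. SE from a parametric bootstrap.

Module-level functions (:func:`ivw`, :func:`mr_egger`, :func:`weighted_median`,
:func:`wald_ratio`, :func:`cochran_q`, :func:`leave_one_out`) are thin
wrappers operating on harmonized pairs and returning :class:`MREstimate` /
:class:`SensitivityReport` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .harmonize import HarmonizedPair

__all__ = [
    "MREstimate",
    "SensitivityReport",
    "IVWEstimator",
    "MREggerEstimator",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "leave_one_out",
    "to_odds_ratio",
]

Z95 = 1.96  # 95% Wald multiplier used throughout


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the outcome scale per SD exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_scale: Optional[tuple[float, float, float]] = None  # (or, or_low, or_high)

    def with_odds_ratio(self) -> "MREstimate":
        """Attach the exponentiated (OR) scale for binary outcomes."""
        return MREstimate(
            self.method,
            self.beta,
            self.se,
            self.ci_low,
            self.ci_high,
            self.pval,
            self.n_snp,
            or_scale=to_odds_ratio(self.beta, self.se),
        )


@dataclass
class SensitivityReport:
    """Cochran's Q, Egger intercept test, and leave-one-out diagnostics."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[float]
    egger_intercept_se: Optional[float]
    egger_intercept_pval: Optional[float]
    loo_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    loo_outlier_flag: bool = False


# ---------------------------------------------------------------------------
# array plumbing


def _as_xy(X, y, se_y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("MR estimators take a single exposure column")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if not (X.shape == y.shape == se_y.shape):
        raise ValueError("x, y and se_y must have identical shapes")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(se_y)):
        raise ValueError("non-finite values in estimator input")
    if np.any(se_y <= 0):
        raise ValueError("se_y must be strictly positive")
    return X, y, se_y


def _wald_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _pairs_to_arrays(pairs: Sequence[HarmonizedPair]):
    use = [p for p in pairs if not p.dropped]
    bx = np.array([p.beta_exp for p in use])
    sx = np.array([p.se_exp for p in use])
    by = np.array([p.beta_out for p in use])
    sy = np.array([p.se_out for p in use])
    ids = [p.variant_id for p in use]
    return bx, sx, by, sy, ids


# ---------------------------------------------------------------------------
# estimators


class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared fit plumbing for the pair-based MR regressors."""

    def _ci(self, beta: float, se: float, crit: float) -> tuple[float, float]:
        return beta - crit * se, beta + crit * se

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return getattr(self, "intercept_", 0.0) + self.beta_ * x


class IVWEstimator(_BaseMREstimator):
    """Inverse-variance-weighted causal-effect estimator.

    Weighted least-squares slope of the outcome effects on the exposure
    effects through the origin, weights 1/se_y^2 — algebraically the
    inverse-variance meta-analysis of the per-variant Wald ratios.

    Parameters
    ----------
    effects_model:
        ``"multiplicative_random"`` (default) inflates the fixed-effect SE
        by ``max(1, sqrt(Q/(n-1)))`` so heterogeneity widens the interval;
        ``"fixed"`` uses the fixed-effect SE unchanged.

    Attributes
    ----------
    beta_, se_, ci_low_, ci_high_, pval_ : fitted causal estimate.
    q_, q_df_, q_pval_ : Cochran heterogeneity statistic of the fit.
    """

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def fit(self, X, y, se_y):
        if self.effects_model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        x, y, se_y = _as_xy(X, y, se_y)
        if x.size < 1:
            raise ValueError("IVW requires at least one pair")
        w = 1.0 / se_y**2
        sxx = float(np.sum(w * x * x))
        if sxx == 0:
            raise ValueError("all exposure effects are zero; slope undefined")
        beta = float(np.sum(w * x * y) / sxx)
        se_fixed = float(np.sqrt(1.0 / sxx))
        self.n_snp_ = int(x.size)
        self.q_ = float(np.sum(w * (y - beta * x) ** 2))
        self.q_df_ = max(self.n_snp_ - 1, 0)
        self.q_pval_ = (
            float(stats.chi2.sf(self.q_, self.q_df_)) if self.q_df_ > 0 else 1.0
        )
        scale = 1.0
        if self.effects_model == "multiplicative_random" and self.q_df_ > 0:
            scale = max(1.0, float(np.sqrt(self.q_ / self.q_df_)))
        self.beta_ = beta
        self.se_ = se_fixed * scale
        self.se_fixed_ = se_fixed
        self.ci_low_, self.ci_high_ = self._ci(beta, self.se_, Z95)
        self.pval_ = _wald_p(beta / self.se_) if self.se_ > 0 else 1.0
        return self

    def to_estimate(self) -> MREstimate:
        check_is_fitted(self, "beta_")
        return MREstimate(
            "ivw", self.beta_, self.se_, self.ci_low_, self.ci_high_, self.pval_, self.n_snp_
        )


class MREggerEstimator(_BaseMREstimator):
    """MR-Egger regression: weighted regression with an intercept.

    Each pair is first recoded so the exposure effect is positive (flipping
    both effects when it is negative) — the conventional orientation that
    makes the intercept identifiable. Standard errors use multiplicative
    scaling ``max(1, residual SD)`` and p-values the t distribution with
    n-2 degrees of freedom. ``intercept_pval_ > 0.05`` is the usual
    no-detectable-directional-pleiotropy reading.
    """

    def fit(self, X, y, se_y):
        x, y, se_y = _as_xy(X, y, se_y)
        if x.size < 3:
            raise ValueError("MR-Egger requires at least 3 pairs")
        flip = np.sign(x)
        flip[flip == 0] = 1.0
        xr, yr = np.abs(x), y * flip
        design = sm.add_constant(xr)
        res = sm.WLS(yr, design, weights=1.0 / se_y**2).fit()
        sigma = float(np.sqrt(res.scale))
        infl = max(1.0, sigma)
        bse_unscaled = np.asarray(res.bse) / sigma if sigma > 0 else np.asarray(res.bse)
        se_scaled = bse_unscaled * infl
        df = x.size - 2
        self.n_snp_ = int(x.size)
        self.df_ = df
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(se_scaled[0])
        self.beta_ = float(res.params[1])
        self.se_ = float(se_scaled[1])
        self.ci_low_, self.ci_high_ = self._ci(self.beta_, self.se_, Z95)
        self.pval_ = (
            float(2 * stats.t.sf(abs(self.beta_ / self.se_), df)) if self.se_ > 0 else 1.0
        )
        self.intercept_pval_ = (
            float(2 * stats.t.sf(abs(self.intercept_ / self.intercept_se_), df))
            if self.intercept_se_ > 0
            else 1.0
        )
        return self

    def to_estimate(self) -> MREstimate:
        check_is_fitted(self, "beta_")
        return MREstimate(
            "mr_egger", self.beta_, self.se_, self.ci_low_, self.ci_high_, self.pval_, self.n_snp_
        )


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted median of the per-variant Wald ratios.

    The estimate is the percentile-interpolated ratio at which the
    cumulative weight (midpoint convention, cum_j - w_j/2) crosses one half.
    It is consistent as long as valid instruments contribute more than 50%
    of the weight, tolerating up to half the weight coming from pleiotropic
    variants. The SE comes from a parametric bootstrap: both effects of
    every pair are resampled from normal(observed, se) ``n_boot`` times.

    Parameters
    ----------
    weights:
        ``"first_order"`` (default): w_j = x_j^2 / se_y_j^2, the inverse of
        the first-order delta-method variance of the ratio. ``"second_order"``
        additionally propagates the exposure SE (requires ``se_x``).
    n_boot, random_state:
        Bootstrap replicates and seed.
    """

    def __init__(
        self,
        weights: str = "first_order",
        n_boot: int = 1000,
        random_state: Optional[int] = 0,
    ):
        self.weights = weights
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(ratios, kind="stable")
        r = ratios[order]
        wn = w[order] / w[order].sum()
        cum = np.cumsum(wn) - wn / 2.0
        return float(np.interp(0.5, cum, r))

    def _weights(self, x, y, se_y, se_x):
        if self.weights == "first_order":
            return x**2 / se_y**2
        if self.weights == "second_order":
            if se_x is None:
                raise ValueError("second_order weights require se_x")
            var = se_y**2 / x**2 + (y**2 * se_x**2) / x**4
            return 1.0 / var
        raise ValueError(f"unknown weights {self.weights!r}")

    def fit(self, X, y, se_y, se_x=None):
        x, y, se_y = _as_xy(X, y, se_y)
        if se_x is not None:
            se_x = np.asarray(se_x, dtype=float)
        if x.size < 3:
            raise ValueError("weighted median requires at least 3 pairs")
        if np.any(x == 0):
            raise ValueError("zero exposure effect makes a Wald ratio undefined")
        self.beta_ = self._weighted_median(y / x, self._weights(x, y, se_y, se_x))
        rng = np.random.default_rng(self.random_state)
        boot = np.empty(self.n_boot)
        sx = se_x if se_x is not None else np.zeros_like(x)
        for b in range(self.n_boot):
            xb = rng.normal(x, sx)
            yb = rng.normal(y, se_y)
            xb[xb == 0] = x[xb == 0]  # guard pathological resamples
            boot[b] = self._weighted_median(yb / xb, self._weights(xb, yb, se_y, se_x))
        self.se_ = float(np.std(boot, ddof=1))
        self.n_snp_ = int(x.size)
        self.ci_low_, self.ci_high_ = self._ci(self.beta_, self.se_, Z95)
        self.pval_ = _wald_p(self.beta_ / self.se_) if self.se_ > 0 else 1.0
        return self

    def to_estimate(self) -> MREstimate:
        check_is_fitted(self, "beta_")
        return MREstimate(
            "weighted_median",
            self.beta_,
            self.se_,
            self.ci_low_,
            self.ci_high_,
            self.pval_,
            self.n_snp_,
        )


# ---------------------------------------------------------------------------
# pair-level functional interface


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-variant causal estimate: beta_out / beta_exp with the
    first-order delta-method SE se_out / |beta_exp|."""
    if pair.beta_exp == 0:
        raise ValueError(f"degenerate instrument {pair.variant_id}: beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MREstimate("wald_ratio", beta, se, lo, hi, _wald_p(beta / se), 1)


def ivw(
    pairs: Sequence[HarmonizedPair],
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """IVW estimate over harmonized pairs; a single pair falls back to the
    Wald ratio."""
    bx, _, by, sy, _ = _pairs_to_arrays(pairs)
    if bx.size < 1:
        raise ValueError("IVW requires at least one non-dropped pair")
    if bx.size == 1:
        est = wald_ratio([p for p in pairs if not p.dropped][0])
        return MREstimate("ivw", est.beta, est.se, est.ci_low, est.ci_high, est.pval, 1)
    model = IVWEstimator(effects_model=effects_model).fit(bx, by, sy)
    return model.to_estimate()


def mr_egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, float, float, float]:
    """MR-Egger slope estimate plus ``(intercept, intercept_se, intercept_pval)``."""
    bx, _, by, sy, _ = _pairs_to_arrays(pairs)
    if bx.size < 3:
        raise ValueError("MR-Egger requires at least 3 non-dropped pairs")
    model = MREggerEstimator().fit(bx, by, sy)
    return model.to_estimate(), model.intercept_, model.intercept_se_, model.intercept_pval_


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: Optional[int] = 0,
    weights: str = "first_order",
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE."""
    bx, sx, by, sy, _ = _pairs_to_arrays(pairs)
    if bx.size < 3:
        raise ValueError("weighted median requires at least 3 non-dropped pairs")
    model = WeightedMedianEstimator(weights=weights, n_boot=n_boot, random_state=seed)
    model.fit(bx, by, sy, se_x=sx)
    return model.to_estimate()


def cochran_q(
    pairs: Sequence[HarmonizedPair], beta_ref: float
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a reference slope.

    Q = sum_j w_j (ratio_j - beta_ref)^2 with first-order weights
    w_j = beta_exp_j^2 / se_out_j^2; df = n - 1.
    """
    bx, _, by, sy, _ = _pairs_to_arrays(pairs)
    if bx.size < 2:
        raise ValueError("Cochran's Q requires at least 2 pairs")
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - beta_ref) ** 2))
    df = bx.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(
    pairs: Sequence[HarmonizedPair],
    effects_model: str = "multiplicative_random",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Leave-one-out IVW: refit excluding each pair in turn.

    The outlier flag is raised when any single exclusion flips the sign of
    the estimate or moves its p-value across the nominal ``alpha`` line
    relative to the full-sample fit.
    """
    use = [p for p in pairs if not p.dropped]
    if len(use) < 3:
        raise ValueError("leave-one-out requires at least 3 non-dropped pairs")
    full = ivw(use, effects_model)
    rows = []
    flag = False
    for j, excluded in enumerate(use):
        sub = use[:j] + use[j + 1 :]
        est = ivw(sub, effects_model)
        sign_change = np.sign(est.beta) != np.sign(full.beta) and est.beta != 0 != full.beta
        p_cross = (est.pval < alpha) != (full.pval < alpha)
        flag = flag or bool(sign_change or p_cross)
        rows.append(
            (excluded.variant_id, est.beta, est.se, est.pval, bool(sign_change or p_cross))
        )
    table = pd.DataFrame(rows, columns=["excluded_variant", "beta", "se", "pval", "influential"])
    return table, flag


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into ``(or, or_low, or_high)``."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z95 * se)),
        float(np.exp(beta + Z95 * se)),
    )


def sensitivity_report(
    pairs: Sequence[HarmonizedPair],
    ivw_estimate: Optional[MREstimate] = None,
    effects_model: str = "multiplicative_random",
) -> SensitivityReport:
    """Assemble Q, the Egger intercept test, and leave-one-out diagnostics."""
    use = [p for p in pairs if not p.dropped]
    est = ivw_estimate or ivw(use, effects_model)
    if len(use) >= 2:
        q, q_df, q_p = cochran_q(use, est.beta)
    else:
        q, q_df, q_p = 0.0, 0, 1.0
    if len(use) >= 3:
        _, icpt, icpt_se, icpt_p = mr_egger(use)
        loo_table, loo_flag = leave_one_out(use, effects_model)
    else:
        icpt = icpt_se = icpt_p = None
        loo_table, loo_flag = pd.DataFrame(), False
    return SensitivityReport(q, q_df, q_p, icpt, icpt_se, icpt_p, loo_table, loo_flag)
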