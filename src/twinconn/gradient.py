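"""Per-area aggregation and gradient models over hierarchical level.

Covers: averaging connection-level values into per-area profiles, linear and
quadratic regressions of a profile on hierarchical level (with overall F and
nested F-ratio comparison), the restricted early-visual slope test, the
two-component plasticity decomposition

    h2(eta) = h_max - a1*exp(-b1*eta) - a2*exp(+b2*eta),

fixed-shape single-intercept component fits against independent target
profiles (ICC, anatomical heritability), and Akaike-weight model comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Per-area profiles
# --------------------------------------------------------------------------

def area_profile(values: pd.Series, mask: pd.Series | None = None) -> pd.DataFrame:
    """Mean and SEM per area over its kept connections.

    ``values`` is indexed by (area_a, area_b) connection pairs; each kept
    connection contributes to both endpoint areas.  Areas left with no kept
    connection are excluded with a warning.
    """
    all_areas = set(itertools.chain.from_iterable(values.index))
    if mask is not None:
        values = values[mask.reindex(values.index).fillna(False).astype(bool)]
    per_area: dict[str, list[float]] = {}
    for (a, b), v in values.items():
        per_area.setdefault(a, []).append(float(v))
        per_area.setdefault(b, []).append(float(v))
    dropped = sorted(all_areas - set(per_area))
    if dropped:
        log.warning("areas with no kept connections excluded: %s", dropped)
    rows = []
    for area in sorted(per_area):
        vals = np.asarray(per_area[area])
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append({"area": area, "mean": vals.mean(), "sem": sem, "n_connections": len(vals)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Polynomial gradient fits
# --------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS fit of a per-area profile on hierarchical level."""

    degree: int
    params: np.ndarray          # beta_0 .. beta_degree
    r2: float
    f_stat: float               # overall F against intercept-only
    df1: int
    df2: int
    p_value: float
    rss: float
    n: int
    slope_t: float | None = None     # degree-1 only
    slope_p: float | None = None
    slope_df: int | None = None

    def predict(self, eta):
        eta = np.asarray(eta, dtype=float)
        return sum(b * eta**k for k, b in enumerate(self.params))


def fit_polynomial(eta, y, degree: int = 1) -> RegressionFit:
    """OLS of y on [1, eta, ..., eta^degree] with overall-F significance."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(eta) <= degree + 1:
        raise ValueError("need more points than parameters")
    if np.ptp(eta) == 0:
        raise ValueError("hierarchical level is constant")
    x = np.column_stack([eta**k for k in range(degree + 1)])
    res = sm.OLS(y, x).fit()
    fit = RegressionFit(
        degree=degree,
        params=np.asarray(res.params),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        p_value=float(res.f_pvalue),
        rss=float(res.ssr),
        n=len(y),
    )
    if degree == 1:
        fit.slope_t = float(res.tvalues[1])
        fit.slope_p = float(res.pvalues[1])
        fit.slope_df = int(res.df_resid)
    return fit


def nested_f_test(fit_lin: RegressionFit, fit_quad: RegressionFit):
    """F-ratio test of the quadratic against the nested linear model.

    F = ((RSS1 - RSS2) / 1) / (RSS2 / (n - 3)); a perfect quadratic fit
    (RSS2 = 0) yields F = inf, p = 0.

    Returns (F, df1, df2, p).
    """
    if fit_lin.n != fit_quad.n:
        raise ValueError("fits must use the same data")
    rss1, rss2 = fit_lin.rss, fit_quad.rss
    if rss2 > rss1 * (1 + 1e-10) + 1e-12:
        raise ValueError("larger model has larger RSS: fits are not nested")
    df2 = fit_quad.n - 3
    if rss2 <= 1e-12 * max(rss1, 1e-300):
        return float("inf"), 1, df2, 0.0
    f = (rss1 - rss2) / (rss2 / df2)
    return float(f), 1, df2, float(stats.f.sf(f, 1, df2))


def early_visual_slope(profile: pd.DataFrame, levels: pd.Series, early_set):
    """Slope t-test of the linear fit restricted to the early-visual areas.

    Returns (t, df, p) with df = n_early - 2.
    """
    early = [a for a in early_set if a in set(profile["area"])]
    if len(early) < 3:
        raise ValueError("fewer than 3 early-visual areas present")
    sub = profile[profile["area"].isin(early)]
    eta = levels.loc[sub["area"]].to_numpy(dtype=float)
    fit = fit_polynomial(eta, sub["mean"].to_numpy(), degree=1)
    return fit.slope_t, fit.slope_df, fit.slope_p


# --------------------------------------------------------------------------
# Two-component plasticity model
# --------------------------------------------------------------------------

class TwoComponentModel(BaseEstimator, RegressorMixin):
    """Robust non-linear least squares for the plasticity decomposition.

    Fits h2(eta) = h_max - a1*exp(-b1*eta) - a2*exp(+b2*eta) with all four
    parameters bounded below by zero; ``h_max`` is fixed (default 0.5, the
    assumed heritability ceiling under measurement noise common to all
    levels).  The loss is soft-L1 by default ("robust non-linear least
    squares"); multi-start over a grid of decay/growth rates with the
    amplitudes initialised by non-negative linear least squares.  ``r2_`` is
    computed on raw residuals.
    """

    def __init__(self, h_max: float = 0.5, loss: str = "soft_l1",
                 f_scale: float = 0.05, b_grid=(0.1, 0.5, 1.0, 2.0)):
        self.h_max = h_max
        self.loss = loss
        self.f_scale = f_scale
        self.b_grid = b_grid

    def fit(self, eta, y):
        eta = np.asarray(eta, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(eta)) < 4 or len(eta) < 6:
            raise ValueError("need >= 6 areas spanning >= 4 distinct levels")

        def residuals(theta):
            a1, b1, a2, b2 = theta
            return y - (self.h_max - a1 * np.exp(-b1 * eta) - a2 * np.exp(b2 * eta))

        best = None
        deficit = self.h_max - y
        for b1, b2 in itertools.product(self.b_grid, self.b_grid):
            basis = np.column_stack([np.exp(-b1 * eta), np.exp(b2 * eta)])
            amps, _ = optimize.nnls(basis, deficit)
            x0 = np.array([amps[0], b1, amps[1], b2])
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(0.0, np.inf),
                    loss=self.loss, f_scale=self.f_scale,
                )
            except ValueError:  # pragma: no cover - degenerate start
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        self.converged_ = best is not None
        if best is None:
            self.a1_ = self.b1_ = self.a2_ = self.b2_ = np.nan
            self.r2_ = np.nan
            return self
        self.a1_, self.b1_, self.a2_, self.b2_ = (float(v) for v in best.x)
        resid = residuals(best.x)
        tss = np.sum((y - y.mean()) ** 2)
        self.r2_ = float(1.0 - np.sum(resid**2) / tss) if tss > 0 else np.nan
        return self

    def short_term(self, eta):
        return self.a1_ * np.exp(-self.b1_ * np.asarray(eta, dtype=float))

    def long_term(self, eta):
        return self.a2_ * np.exp(self.b2_ * np.asarray(eta, dtype=float))

    def predict(self, eta):
        return self.h_max - self.short_term(eta) - self.long_term(eta)


def fit_two_component(eta, y, h_max: float = 0.5, **params) -> TwoComponentModel:
    """Functional wrapper over :class:`TwoComponentModel`."""
    return TwoComponentModel(h_max=h_max, **params).fit(eta, y)


def component_intercept_fit(eta, y, model: TwoComponentModel, which: str):
    """Single-intercept fit of one frozen component against a target profile.

    The chosen component's shape c(eta) is fixed from the full fit and only
    the intercept of y = beta - c(eta) is free: beta_hat = mean(y + c(eta)).
    AIC = n*ln(RSS/n) + 2k with k = 2 (intercept + error variance).

    Returns (beta_hat, aic, rss).
    """
    if not getattr(model, "converged_", False):
        raise ValueError("component shapes require a converged full fit")
    if which == "short":
        c = model.short_term(eta)
    elif which == "long":
        c = model.long_term(eta)
    else:
        raise ValueError("which must be 'short' or 'long'")
    y = np.asarray(y, dtype=float)
    beta = float(np.mean(y + c))
    rss = float(np.sum((y - (beta - c)) ** 2))
    n = len(y)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 2
    return beta, float(aic), rss


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AIC values")
    if np.any(np.isnan(a)):
        raise ValueError("NaN AIC")
    delta = a - np.min(a)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def relative_likelihood(aic_i: float, aic_j: float) -> float:
    """Relative likelihood of model i versus model j: exp(-(AIC_i-AIC_j)/2)."""
    return float(np.exp(-(aic_i - aic_j) / 2.0))
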