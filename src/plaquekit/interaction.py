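"""Calcium-interaction models of NIRS-IVUS measurements on CTA measurements.

The question these models answer: does the calcium burden seen on CTA
modulate how well CTA predicts the NIRS-IVUS reference measurement? The
NIRS-IVUS value is regressed on the CTA value (restricted cubic spline),
optionally adjusted for the CTA calcium area (its own spline), and the
calcium x measurement interaction is tested:

* segment and lesion level — proportional-odds (cumulative logit) ordinal
  regression, ordinalizing the outcome over its observed distinct values
  (semiparametric: no binning is imposed); interaction tested by
  likelihood ratio;
* cross-sectional (frame) level — ordinary least squares with
  subject-clustered standard errors; interaction tested by a robust Wald
  F-test.

The interaction is parameterised on the linear terms only (product of the
linear CTA and calcium columns), keeping the test at 1 df at lesion-level
sample sizes.

The cumulative-logit likelihood is maximised by L-BFGS with analytic
gradients in a monotone cutpoint parameterisation, which stays fast when
every distinct outcome value is its own category (hundreds of cutpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .agreement import EstimationError, rcs_basis, rcs_knots

__all__ = [
    "InteractionFit",
    "fit_prop_odds",
    "fit_ols_interaction",
    "difference_curves",
]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _spline_or_linear(x: np.ndarray, n_knots: int,
                      knots: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    """RCS columns, degrading to the bare linear term when the data cannot
    support knot placement (too few distinct values)."""
    if knots is not None:
        return rcs_basis(x, knots=knots), knots
    try:
        k = rcs_knots(x, n_knots)
    except ValueError:
        return x[:, None], None
    return rcs_basis(x, knots=k), k


def _build_design(
    cta: np.ndarray,
    ca: np.ndarray | None,
    interaction: bool,
    n_knots: int,
    knots_cta: np.ndarray | None = None,
    knots_ca: np.ndarray | None = None,
):
    cols, names = [], []
    xb, knots_cta = _spline_or_linear(cta, n_knots, knots_cta)
    for i in range(xb.shape[1]):
        cols.append(xb[:, i])
        names.append("cta" if i == 0 else f"cta_rcs{i}")
    if ca is not None:
        cb, knots_ca = _spline_or_linear(ca, n_knots, knots_ca)
        for i in range(cb.shape[1]):
            cols.append(cb[:, i])
            names.append("ca" if i == 0 else f"ca_rcs{i}")
    inter_idx: list[int] = []
    if interaction:
        if ca is None:
            raise ValueError("interaction requires the calcium covariate")
        cols.append(cta * ca)
        names.append("cta:ca")
        inter_idx = [len(cols) - 1]
    X = np.column_stack(cols)
    return X, names, inter_idx, knots_cta, knots_ca


# ---------------------------------------------------------------------------
# Cumulative-logit (proportional odds) maximum likelihood
# ---------------------------------------------------------------------------

def _po_unpack(theta: np.ndarray, n_cut: int) -> tuple[np.ndarray, np.ndarray]:
    a0 = theta[0]
    d = theta[1:n_cut]
    alpha = a0 + np.concatenate([[0.0], np.cumsum(np.exp(d))])
    beta = theta[n_cut:]
    return alpha, beta


def _po_nll_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 n_cut: int) -> tuple[float, np.ndarray]:
    n = y.size
    alpha, beta = _po_unpack(theta, n_cut)
    eta = X @ beta
    K = n_cut + 1
    hi = np.where(y < K - 1, alpha[np.minimum(y, n_cut - 1)] - eta, np.inf)
    lo = np.where(y > 0, alpha[np.maximum(y - 1, 0)] - eta, -np.inf)
    Fu = special.expit(hi)
    Fl = special.expit(lo)
    fu = np.where(np.isfinite(hi), Fu * (1 - Fu), 0.0)
    fl = np.where(np.isfinite(lo), Fl * (1 - Fl), 0.0)
    P = np.clip(Fu - Fl, 1e-300, None)
    nll = -np.sum(np.log(P))

    deta = (fu - fl) / P  # dNLL/deta
    g_beta = X.T @ deta
    g_alpha = np.zeros(n_cut)
    upper_mask = y < K - 1
    np.add.at(g_alpha, y[upper_mask], (-fu / P)[upper_mask])
    lower_mask = y > 0
    np.add.at(g_alpha, y[lower_mask] - 1, (fl / P)[lower_mask])
    # chain rule to (a0, d) parameterisation
    g_a0 = g_alpha.sum()
    tail = np.cumsum(g_alpha[::-1])[::-1]  # tail[i] = sum_{j>=i} g_alpha[j]
    g_d = np.exp(theta[1:n_cut]) * tail[1:]
    return nll, np.concatenate([[g_a0], g_d, g_beta])


def _po_start(y: np.ndarray, n_cut: int, p: int) -> np.ndarray:
    n = y.size
    cum = np.cumsum(np.bincount(y, minlength=n_cut + 1))[:-1] / n
    cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
    alpha = special.logit(cum)
    alpha = np.maximum.accumulate(alpha)
    diffs = np.maximum(np.diff(alpha), 1e-3)
    theta = np.concatenate([[alpha[0]], np.log(diffs), np.zeros(p)])
    return theta


def _fit_cumulative_logit(y: np.ndarray, X: np.ndarray,
                          start: np.ndarray | None = None):
    """Maximise the proportional-odds likelihood.

    Design columns are standardised internally (the cubic spline columns
    of skewed covariates span several orders of magnitude, and the raw
    problem is ill-conditioned enough to stall L-BFGS short of the
    optimum, which would bias likelihood-ratio statistics); estimates are
    mapped back to the original scale. Returns
    ``(alpha, beta, loglik, converged, theta_std)`` where ``theta_std``
    is the optimiser state in standardised space (usable as a warm
    start for a model extending this design).
    """
    n_cut = int(y.max())  # y coded 0..K-1
    p = X.shape[1]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    theta0 = _po_start(y, n_cut, p) if start is None else start
    res = optimize.minimize(
        _po_nll_grad,
        theta0,
        args=(y, Xs, n_cut),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 10000, "maxfun": 20000, "ftol": 1e-13, "gtol": 1e-7},
    )
    alpha_s, beta_s = _po_unpack(res.x, n_cut)
    beta = beta_s / sd
    alpha = alpha_s + float(np.dot(beta_s, mu / sd))
    converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-3)
    return alpha, beta, -float(res.fun), converged, res.x


def _po_beta_se(theta_std: np.ndarray, y: np.ndarray, X: np.ndarray,
                n_cut: int) -> np.ndarray:
    """Standard errors of beta (original scale) from the numerically
    differentiated observed information (finite differences of the
    analytic gradient, evaluated in the standardised parameter space)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    m = theta_std.size
    H = np.empty((m, m))
    eps = 1e-5
    for j in range(m):
        tp = theta_std.copy()
        tp[j] += eps
        _, gp = _po_nll_grad(tp, y, Xs, n_cut)
        tm = theta_std.copy()
        tm[j] -= eps
        _, gm = _po_nll_grad(tm, y, Xs, n_cut)
        H[:, j] = (gp - gm) / (2 * eps)
    H = (H + H.T) / 2
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[n_cut:], 0, None)) / sd
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    return se


# ---------------------------------------------------------------------------
# Public fits
# ---------------------------------------------------------------------------

@dataclass
class InteractionFit:
    """A fitted calcium-interaction model.

    ``interaction_p`` is the likelihood-ratio p (proportional odds) or the
    cluster-robust Wald F p (OLS) for the CTA x calcium interaction block;
    it is None for fits without the interaction term.
    """

    level: str
    outcome: str
    model: str  # "prop_odds" | "ols"
    adjusted: bool
    interaction: bool
    n: int
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, se)
    loglik: float
    interaction_p: float | None
    converged: bool
    categories: np.ndarray | None = None  # prop-odds outcome values
    alpha: np.ndarray | None = None  # prop-odds cutpoints
    beta: np.ndarray | None = None
    coef_names: list[str] = field(default_factory=list)
    n_knots: int = 3
    knots_cta: np.ndarray | None = None
    knots_ca: np.ndarray | None = None
    ca_range: tuple[float, float] | None = None
    cta_quartiles: np.ndarray | None = None

    def _design_row(self, cta: np.ndarray, ca: np.ndarray | None) -> np.ndarray:
        X, _, _, _, _ = _build_design(
            np.asarray(cta, dtype=float),
            np.asarray(ca, dtype=float) if ca is not None else None,
            self.interaction,
            self.n_knots,
            knots_cta=self.knots_cta if self.knots_cta is not None else None,
            knots_ca=self.knots_ca,
        )
        # fits that degraded to a linear CTA term have no stored knots; in
        # that case rebuild a bare-linear design of matching width
        if X.shape[1] != len(self.coef_names):
            raise EstimationError("prediction design does not match the fit")
        return X

    def predict(self, cta, ca=None) -> np.ndarray:
        """Predicted NIRS-IVUS value: modelled median for the proportional
        odds fit, fitted mean for the OLS fit."""
        cta = np.atleast_1d(np.asarray(cta, dtype=float))
        ca_arr = None
        if self.adjusted:
            if ca is None:
                raise ValueError("adjusted fit requires the calcium covariate")
            ca_arr = np.broadcast_to(np.asarray(ca, dtype=float), cta.shape).copy()
        X = self._design_row(cta, ca_arr)
        eta = X @ self.beta
        if self.model == "ols":
            return self.coefficients["const"][0] + eta
        cum = special.expit(self.alpha[None, :] - eta[:, None])
        idx = np.argmax(cum >= 0.5, axis=1)
        no_median = cum[:, -1] < 0.5  # median is the top category
        values = self.categories[np.where(no_median, len(self.categories) - 1, idx)]
        return values


def fit_prop_odds(
    outcome,
    cta,
    ca_area=None,
    *,
    interaction: bool = False,
    n_knots: int = 3,
    level: str = "segment",
    outcome_name: str = "outcome",
    compute_se: bool = True,
) -> InteractionFit:
    """Proportional-odds model of the NIRS-IVUS outcome on the CTA value.

    Every distinct outcome value is an ordinal category. ``ca_area`` adds
    the calcium spline (adjusted model); ``interaction`` adds the linear
    CTA x calcium product and reports its 1-df likelihood-ratio p-value.
    """
    y_raw = np.asarray(outcome, dtype=float)
    cta = np.asarray(cta, dtype=float)
    categories, y = np.unique(y_raw, return_inverse=True)
    if categories.size < 3:
        raise ValueError("need at least 3 distinct outcome values")
    if not (np.all(np.isfinite(cta)) and np.all(np.isfinite(y_raw))):
        raise ValueError("non-finite outcome or predictor")
    ca = np.asarray(ca_area, dtype=float) if ca_area is not None else None

    X, names, inter_idx, kc, kca = _build_design(cta, ca, interaction, n_knots)
    interaction_p = None
    start_full = None
    if interaction:
        X0 = X[:, [i for i in range(X.shape[1]) if i not in inter_idx]]
        a0_, b0_, ll0, conv0, th0 = _fit_cumulative_logit(y, X0)
        if not conv0:
            raise EstimationError("nested proportional-odds fit did not converge")
        # warm-start the full model at the nested optimum so the LRT
        # statistic is nonnegative by construction
        start_full = np.concatenate([th0, np.zeros(len(inter_idx))])
    alpha, beta, ll, conv, theta = _fit_cumulative_logit(y, X, start=start_full)
    if not conv:
        raise EstimationError("proportional-odds fit did not converge")
    if interaction:
        lrt = max(0.0, 2.0 * (ll - ll0))
        interaction_p = float(stats.chi2.sf(lrt, len(inter_idx)))
        interaction_p = max(interaction_p, np.nextafter(0, 1))

    se = _po_beta_se(theta, y, X, int(y.max())) if compute_se else np.full(len(names), np.nan)
    return InteractionFit(
        level=level,
        outcome=outcome_name,
        model="prop_odds",
        adjusted=ca is not None,
        interaction=interaction,
        n=y.size,
        coefficients={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)},
        loglik=ll,
        interaction_p=interaction_p,
        converged=conv,
        categories=categories,
        alpha=alpha,
        beta=beta,
        coef_names=names,
        n_knots=n_knots,
        knots_cta=kc,
        knots_ca=kca,
        ca_range=(float(ca.min()), float(ca.max())) if ca is not None else None,
        cta_quartiles=np.quantile(cta, [0.25, 0.5, 0.75]),
    )


def fit_ols_interaction(
    outcome,
    cta,
    ca_area=None,
    *,
    interaction: bool = False,
    n_knots: int = 5,
    cluster=None,
    cov_type: str = "auto",
    level: str = "frame",
    outcome_name: str = "outcome",
) -> InteractionFit:
    """OLS model of the NIRS-IVUS outcome on the CTA value (frame level).

    Standard errors (and the interaction Wald F-test) are clustered by
    ``cluster`` (subject identifiers) when provided, since subjects
    contribute many frames; without clusters the default is
    heteroskedasticity-robust HC1. ``cov_type`` may force "nonrobust".
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    cta = np.asarray(cta, dtype=float)
    ca = np.asarray(ca_area, dtype=float) if ca_area is not None else None
    X, names, inter_idx, kc, kca = _build_design(cta, ca, interaction, n_knots)
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise EstimationError(
            f"rank-deficient design ({rank} < {exog.shape[1]} columns): "
            + ", ".join(["const"] + names)
        )
    if y.size <= exog.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.OLS(y, exog)
    if cov_type == "auto":
        cov_type = "cluster" if cluster is not None else "HC1"
    if cov_type == "cluster":
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    elif cov_type == "nonrobust":
        res = model.fit()
    else:
        res = model.fit(cov_type=cov_type)
    interaction_p = None
    if interaction:
        R = np.zeros((len(inter_idx), exog.shape[1]))
        for r, i in enumerate(inter_idx):
            R[r, i + 1] = 1.0  # +1 for the constant column
        wt = res.wald_test(R, use_f=True, scalar=True)
        interaction_p = float(wt.pvalue)
    all_names = ["const"] + names
    coeffs = {
        nm: (float(b), float(s)) for nm, b, s in zip(all_names, res.params, res.bse)
    }
    return InteractionFit(
        level=level,
        outcome=outcome_name,
        model="ols",
        adjusted=ca is not None,
        interaction=interaction,
        n=y.size,
        coefficients=coeffs,
        loglik=float(res.llf),
        interaction_p=interaction_p,
        converged=True,
        beta=res.params[1:],
        coef_names=names,
        n_knots=n_knots,
        knots_cta=kc,
        knots_ca=kca,
        ca_range=(float(ca.min()), float(ca.max())) if ca is not None else None,
        cta_quartiles=np.quantile(cta, [0.25, 0.5, 0.75]),
    )


def difference_curves(
    fit: InteractionFit,
    ca_grid: np.ndarray | None = None,
    cta_values: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Predicted NIRS-IVUS minus CTA difference versus calcium area.

    Evaluated on a calcium grid (default: 1st-99th percentile span of the
    training calcium, ``n_points`` points) at representative CTA values
    (default: training quartiles). Calcium values outside the observed
    range are clipped with a warning.
    """
    if not fit.adjusted:
        raise ValueError("difference curves need a calcium-adjusted fit")
    lo, hi = fit.ca_range
    if ca_grid is None:
        ca_grid = np.linspace(lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo), n_points)
    else:
        ca_grid = np.asarray(ca_grid, dtype=float)
        if ca_grid.min() < lo or ca_grid.max() > hi:
            warnings.warn("calcium grid clipped to the observed range", stacklevel=2)
            ca_grid = np.clip(ca_grid, lo, hi)
    if cta_values is None:
        cta_values = fit.cta_quartiles
    rows = []
    for cta_v in np.atleast_1d(cta_values):
        cta_col = np.full(ca_grid.size, float(cta_v))
        pred = fit.predict(cta_col, ca_grid)
        for ca_v, p in zip(ca_grid, pred):
            rows.append(
                {
                    "ca_area": float(ca_v),
                    "cta_value": float(cta_v),
                    "predicted_nirs": float(p),
                    "difference": float(p - cta_v),
                }
            )
    return pd.DataFrame(rows)
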