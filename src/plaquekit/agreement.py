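"""Agreement statistics between paired imaging modalities.

Implements the full agreement toolkit used to compare NIRS-IVUS and CTA
plaque measurements at segment, lesion and cross-sectional (frame) level:

* Wilcoxon signed-rank paired comparison;
* Bland–Altman bias and 95% limits of agreement, parametric
  (mean +/- 1.96 SD) and nonparametric (median and 2.5th/97.5th
  percentiles by intercept-only quantile regression);
* intraclass correlation ICC(A,2) — two-way random effects, absolute
  agreement, average of the two modalities — estimated by REML with
  subject and modality random intercepts, optionally adjusted for a
  covariate entered as a restricted cubic spline; confidence intervals by
  subject-level (cluster) nonparametric bootstrap;
* quantile stratification (terciles / deciles) and a Fisher-z,
  DerSimonian–Laird heterogeneity test across stratum ICCs.

For balanced covariate-free two-way data the REML variance components
coincide with the classical ANOVA estimators, so that case is solved in
closed form; unbalanced or covariate-adjusted fits go through
:class:`statsmodels` ``MixedLM``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "EstimationError",
    "AgreementResult",
    "IccModelSpec",
    "IccResult",
    "HeterogeneityResult",
    "wilcoxon_paired",
    "bland_altman",
    "icc_mixed",
    "rcs_basis",
    "rcs_knots",
    "compare_adjusted_icc",
    "stratify",
    "icc_heterogeneity",
    "icc_band",
]


class DegenerateDataError(ValueError):
    """All information cancels (e.g. every paired difference is zero)."""


class EstimationError(RuntimeError):
    """A model fit failed to converge; carries diagnostics in ``args``."""


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one variable at one analysis level."""

    variable: str
    level: str  # segment | lesion | frame
    n: int
    bias: float
    loa_low: float
    loa_high: float
    p_value: float
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    stratum: str = "all"


@dataclass(frozen=True)
class IccModelSpec:
    """Specification of the ICC mixed model.

    Random intercepts for subject and modality are always included
    (two-way random effects, absolute agreement, average of k=2
    measurements). ``covariate`` adds a restricted-cubic-spline fixed
    effect with ``n_knots`` knots (3 for segment/lesion level, 5 for
    frame level).
    """

    covariate: str | None = None
    n_knots: int = 3
    cluster: str = "subject"

    def __post_init__(self) -> None:
        if self.n_knots not in (3, 5):
            raise ValueError("n_knots must be 3 or 5")


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci: tuple[float, float]
    var_subject: float
    var_modality: float
    var_error: float
    n_subjects: int
    n_obs: int
    method: str  # "anova-reml" (balanced closed form) or "mixedlm-reml"
    n_boot: int
    seed: int | None
    n_boot_failed: int = 0


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_value: float
    tau2: float


# ---------------------------------------------------------------------------
# Paired tests and Bland–Altman
# ---------------------------------------------------------------------------

def wilcoxon_paired(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired measurements.

    Zero differences are dropped; the exact distribution is used for
    n <= 25 without ties, otherwise the normal approximation with
    continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def bland_altman(diffs, mode: str = "parametric") -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired differences.

    parametric
        bias = mean difference, LOA = mean +/- 1.96 x sample SD (ddof=1).
    nonparametric
        bias = median, LOA = 2.5th and 97.5th percentiles, each the
        intercept of an intercept-only quantile regression (pinball-loss
        minimiser), the convention suited to skewed small samples.

    Returns ``(bias, loa_low, loa_high)``.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise ValueError("Bland–Altman needs at least 3 differences")
    if mode == "parametric":
        m = float(np.mean(d))
        s = float(np.std(d, ddof=1))
        return m, m - 1.96 * s, m + 1.96 * s
    if mode != "nonparametric":
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(d) == 0:
        v = float(d[0])
        return v, v, v
    from statsmodels.regression.quantile_regression import QuantReg

    exog = np.ones((d.size, 1))
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in (0.5, 0.025, 0.975):
            res = QuantReg(d, exog).fit(q=tau, max_iter=2000)
            out.append(float(res.params[0]))
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

_KNOT_QUANTILES = {3: (0.10, 0.50, 0.90), 5: (0.05, 0.275, 0.50, 0.725, 0.95)}


def rcs_knots(x, n_knots: int) -> np.ndarray:
    """Default knot locations: outer/inner quantiles of the data."""
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError("n_knots must be 3 or 5")
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct values for {n_knots} knots"
        )
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.unique(knots).size < n_knots:
        raise ValueError("degenerate data: knots are not distinct")
    return knots


def rcs_basis(x, n_knots: int = 3, knots: np.ndarray | None = None) -> np.ndarray:
    """Restricted cubic spline design columns (Harrell truncated-power form).

    Returns ``k - 1`` columns including the linear term; the nonlinear
    columns are cubic between the outer knots and exactly linear outside
    them, with continuous first and second derivatives everywhere.
    """
    x = np.asarray(x, dtype=float)
    t = rcs_knots(x, n_knots) if knots is None else np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    cols = [x]

    def cube(v):
        return np.where(v > 0, v, 0.0) ** 3

    tk, tk1 = t[-1], t[-2]
    denom = tk - tk1
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - tk1) * (tk - t[j]) / denom
            + cube(x - tk) * (tk1 - t[j]) / denom
        )
        cols.append(term)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# ICC via two-way random-effects mixed model
# ---------------------------------------------------------------------------

def _anova_icc(mat: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form variance components for a balanced n x k table.

    Equal to the REML solution for balanced two-way crossed random
    designs (variances floored at zero on the boundary). Returns
    (icc, var_subject, var_modality, var_error).
    """
    n, k = mat.shape
    grand = mat.mean()
    rows = mat.mean(axis=1)
    cols = mat.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = mat - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    var_e = mse
    var_s = max(0.0, (msr - mse) / k)
    var_m = max(0.0, (msc - mse) / n)
    denom = var_s + (var_m + var_e) / k
    icc = var_s / denom if denom > 0 else 1.0
    return float(np.clip(icc, -1.0, 1.0)), float(var_s), float(var_m), float(var_e)


def _anova_icc_batch(mats: np.ndarray, max_elems: int = 20_000_000) -> np.ndarray:
    """Vectorised `_anova_icc` ICC over a (B, n, k) stack of tables,
    chunked to bound peak memory."""
    B, n, k = mats.shape
    if B * n * k > max_elems:
        step = max(1, max_elems // (n * k))
        return np.concatenate(
            [_anova_icc_batch(mats[i : i + step]) for i in range(0, B, step)]
        )
    grand = mats.mean(axis=(1, 2))
    rows = mats.mean(axis=2)
    cols = mats.mean(axis=1)
    msr = k * ((rows - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    msc = n * ((cols - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
    resid = mats - rows[:, :, None] - cols[:, None, :] + grand[:, None, None]
    mse = (resid**2).sum(axis=(1, 2)) / ((n - 1) * (k - 1))
    var_s = np.maximum(0.0, (msr - mse) / k)
    var_m = np.maximum(0.0, (msc - mse) / n)
    denom = var_s + (var_m + mse) / k
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, var_s / denom, 1.0)
    return np.clip(icc, -1.0, 1.0)


def _mixedlm_icc(df: pd.DataFrame, spec: IccModelSpec,
                 knots: np.ndarray | None = None
                 ) -> tuple[float, float, float, float, bool]:
    """REML fit with subject and modality random intercepts via MixedLM.

    The two crossed random effects are expressed as variance components
    within a single all-encompassing group.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    work = df.copy()
    work["_one"] = 1
    # the ICC is invariant to affine rescaling of the outcome; standardise
    # internally so volumes (~10^2 mm^3) and indices (~10^-1) condition the
    # REML optimisation identically, then unscale the components
    y = work["value"].to_numpy(dtype=float)
    scale = float(np.std(y))
    scale = scale if scale > 0 else 1.0
    work["value"] = (y - float(np.mean(y))) / scale
    if spec.covariate is not None:
        basis = rcs_basis(work[spec.covariate].to_numpy(), spec.n_knots, knots=knots)
        names = [f"_rcs{i}" for i in range(basis.shape[1])]
        for i, name in enumerate(names):
            col = basis[:, i]
            sd = col.std()
            work[name] = (col - col.mean()) / (sd if sd > 0 else 1.0)
        fixed = "value ~ 1 + " + " + ".join(names)
    else:
        fixed = "value ~ 1"
    vc = {"subject": "0 + C(subject)", "modality": "0 + C(modality)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(fixed, groups="_one", vc_formula=vc, data=work)
        result = model.fit(reml=True)
        if not result.converged:
            result = model.fit(reml=True, method="lbfgs")
    if not result.converged:
        raise EstimationError("MixedLM REML did not converge", str(result.summary()))
    comp = dict(zip(model.exog_vc.names, result.vcomp))
    var_s = max(0.0, float(comp["subject"])) * scale**2
    var_m = max(0.0, float(comp["modality"])) * scale**2
    var_e = float(result.scale) * scale**2
    denom = var_s + (var_m + var_e) / 2.0
    icc = var_s / denom if denom > 0 else 1.0
    return float(np.clip(icc, -1.0, 1.0)), var_s, var_m, var_e, result.converged


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["subject", "modality"], sort=False, observed=True).size()
    if (counts != 1).any():
        return False
    n_mod = df["modality"].nunique()
    per_subject = df.groupby("subject", sort=False, observed=True)["modality"].nunique()
    return bool((per_subject == n_mod).all()) and n_mod == 2


def _balanced_matrix(df: pd.DataFrame, covariate: str | None,
                     cluster: str) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Pivot balanced long data to (n_subjects x 2 matrix, per-subject
    covariate, per-subject cluster id)."""
    wide = df.pivot(index="subject", columns="modality", values="value")
    mat = wide.to_numpy(dtype=float)
    per_subject = df.drop_duplicates("subject").set_index("subject")
    cov = (
        per_subject.loc[wide.index, covariate].to_numpy(dtype=float)
        if covariate is not None
        else None
    )
    if cluster == "subject":
        clus = wide.index.to_numpy()
    else:
        clus = per_subject.loc[wide.index, cluster].to_numpy()
    return mat, cov, clus


def _residualized_matrix(mat: np.ndarray, cov: np.ndarray,
                         n_knots: int, knots: np.ndarray) -> np.ndarray:
    """Remove the RCS fixed effect of a per-subject covariate from both
    modality columns by pooled OLS; the covariate is constant within a
    pair, so residualization preserves the paired structure exactly."""
    basis = rcs_basis(cov, n_knots, knots=knots)
    X = np.column_stack([np.ones(cov.size), basis])
    y = mat.mean(axis=1)
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coefs
    return mat - fitted[:, None]


def icc_mixed(
    data: pd.DataFrame,
    spec: IccModelSpec = IccModelSpec(),
    *,
    n_boot: int = 2000,
    seed: int | None = 0,
    fitter: str = "auto",
    ci_alpha: float = 0.05,
    mixedlm_max_subjects: int = 1500,
) -> IccResult:
    """ICC(A,2) with bootstrap CI from long-format paired data.

    Parameters
    ----------
    data
        Long format with columns ``subject`` (the measurement target: a
        segment, lesion or matched frame), ``modality``, ``value`` and,
        when ``spec.covariate`` is set, that covariate column (constant
        within a target). An extra column named by ``spec.cluster`` (e.g.
        the patient id) groups targets for the bootstrap.
    spec
        Model specification (covariate adjustment, knots, bootstrap
        cluster variable).
    n_boot
        Cluster-level nonparametric bootstrap resamples for the
        percentile CI; 0 disables the CI.
    seed
        Bootstrap seed; mandatory when ``n_boot > 0``.
    fitter
        "auto" dispatches: balanced unadjusted -> closed-form ANOVA/REML;
        balanced adjusted -> MixedLM REML up to
        ``mixedlm_max_subjects`` targets, covariate residualization +
        closed form beyond that; unbalanced -> MixedLM. "anova",
        "mixedlm" and "residual-anova" force a route.
    """
    required = {"subject", "modality", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if n_boot > 0 and seed is None:
        raise ValueError("seed is mandatory when bootstrapping")

    cluster = spec.cluster
    if cluster != "subject" and cluster not in data.columns:
        raise ValueError(f"cluster column {cluster!r} not in data")

    balanced = _is_balanced(data)
    adjusted = spec.covariate is not None
    if fitter == "auto":
        if balanced and not adjusted:
            method = "anova-reml"
        elif balanced and data["subject"].nunique() > mixedlm_max_subjects:
            method = "residual-anova"
        else:
            method = "mixedlm-reml"
    else:
        method = {"anova": "anova-reml", "mixedlm": "mixedlm-reml",
                  "residual-anova": "residual-anova"}[fitter]
    if method != "mixedlm-reml" and not balanced:
        raise ValueError("closed-form fitters require balanced data")
    if method == "anova-reml" and adjusted:
        raise ValueError("the unadjusted closed form cannot take a covariate")
    if method == "residual-anova" and not adjusted:
        raise ValueError("residual-anova requires a covariate")

    knots = None
    if adjusted:
        knots = rcs_knots(data[spec.covariate].to_numpy(), spec.n_knots)

    mat = cov = clus = None
    if balanced:
        mat, cov, clus = _balanced_matrix(data, spec.covariate, cluster)

    if method == "anova-reml":
        icc, var_s, var_m, var_e = _anova_icc(mat)
    elif method == "residual-anova":
        icc, var_s, var_m, var_e = _anova_icc(
            _residualized_matrix(mat, cov, spec.n_knots, knots)
        )
    else:
        try:
            icc, var_s, var_m, var_e, _ = _mixedlm_icc(data, spec, knots=knots)
        except EstimationError:
            # REML iteration can stall on the variance boundary; on
            # balanced data the closed form is available as a fallback
            # (an explicitly requested mixedlm fit still raises)
            if fitter == "auto" and balanced:
                warnings.warn(
                    "MixedLM REML did not converge; falling back to the "
                    "balanced closed form",
                    stacklevel=2,
                )
                if adjusted:
                    icc, var_s, var_m, var_e = _anova_icc(
                        _residualized_matrix(mat, cov, spec.n_knots, knots)
                    )
                    method = "residual-anova(fallback)"
                else:
                    icc, var_s, var_m, var_e = _anova_icc(mat)
                    method = "anova-reml(fallback)"
            else:
                raise

    lo = hi = np.nan
    n_failed = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        qs = (100 * ci_alpha / 2, 100 * (1 - ci_alpha / 2))
        if balanced:
            # resample clusters of targets; closed-form components per
            # resample (residualized first when adjusted)
            work = (
                mat
                if not adjusted
                else _residualized_matrix(mat, cov, spec.n_knots, knots)
            )
            uniq, inv = np.unique(clus, return_inverse=True)
            if uniq.size == mat.shape[0]:
                n_sub = mat.shape[0]
                step = max(1, 20_000_000 // (2 * n_sub))
                parts = []
                for b0 in range(0, n_boot, step):
                    idx = rng.integers(0, n_sub, size=(min(step, n_boot - b0), n_sub))
                    parts.append(_anova_icc_batch(work[idx]))
                boots = np.concatenate(parts)
            else:
                rows_by_cluster = [np.flatnonzero(inv == i) for i in range(uniq.size)]
                boots = np.empty(n_boot)
                for b in range(n_boot):
                    chosen = rng.integers(0, uniq.size, size=uniq.size)
                    rows = np.concatenate([rows_by_cluster[c] for c in chosen])
                    boots[b] = _anova_icc(work[rows])[0]
            lo, hi = np.percentile(boots, qs)
        else:
            ids = data[cluster].to_numpy()
            uniq = pd.unique(ids)
            groups = {u: data.index[ids == u].to_numpy() for u in uniq}
            vals = []
            for _ in range(n_boot):
                chosen = rng.choice(uniq, size=uniq.size, replace=True)
                parts = []
                for rep, u in enumerate(chosen):
                    block = data.loc[groups[u]].copy()
                    block["subject"] = block["subject"].astype(str) + f"__b{rep}"
                    parts.append(block)
                sample = pd.concat(parts, ignore_index=True)
                try:
                    b_icc, *_ = _mixedlm_icc(sample, spec, knots=knots)
                    vals.append(b_icc)
                except (EstimationError, np.linalg.LinAlgError, ValueError):
                    n_failed += 1
            if not vals:
                raise EstimationError("every bootstrap refit failed")
            lo, hi = np.percentile(vals, qs)

    return IccResult(
        icc=icc,
        ci=(float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1)))
        if n_boot > 0
        else (np.nan, np.nan),
        var_subject=var_s,
        var_modality=var_m,
        var_error=var_e,
        n_subjects=int(data["subject"].nunique()),
        n_obs=len(data),
        method=method,
        n_boot=n_boot,
        seed=seed,
        n_boot_failed=n_failed,
    )


def compare_adjusted_icc(unadjusted: IccResult, adjusted: IccResult) -> bool:
    """True (significant difference) iff the two CIs are disjoint."""
    lo1, hi1 = unadjusted.ci
    lo2, hi2 = adjusted.ci
    return bool(hi1 < lo2 or hi2 < lo1)


def icc_band(icc: float) -> str:
    """Interpretation band: < 0.50 poor, 0.50-0.75 moderate, 0.75-0.90
    good, > 0.90 excellent."""
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Stratification and heterogeneity
# ---------------------------------------------------------------------------

_SCHEMES = {"terciles": 3, "deciles": 10}


def stratify(values, scheme: str | int = "terciles") -> np.ndarray:
    """Quantile group labels (0-based) for tercile/decile stratification.

    Cut-points are lower empirical quantiles (pinball-loss minimisers);
    values tied with a cut-point fall in the lower group.
    """
    g = _SCHEMES.get(scheme, scheme) if isinstance(scheme, str) else int(scheme)
    if isinstance(g, str):
        raise ValueError(f"unknown scheme {scheme!r}")
    v = np.asarray(values, dtype=float)
    if v.size < g:
        raise ValueError(f"need at least {g} observations for {g} groups")
    cuts = np.quantile(v, np.arange(1, g) / g, method="inverted_cdf")
    labels = (v[:, None] > cuts[None, :]).sum(axis=1)
    if np.unique(labels).size == 1 and g > 1:
        warnings.warn("degenerate strata: all observations fall in one group",
                      stacklevel=2)
    return labels


def icc_heterogeneity(stratum_iccs) -> HeterogeneityResult:
    """Heterogeneity of stratum ICCs: Cochran's Q on the Fisher-z scale.

    Each (icc, (lo, hi)) is z-transformed; the standard error is the CI
    width on the z scale divided by 2 x 1.96; Q uses inverse-variance
    weights, the p-value is chi-square with G-1 df, and the
    DerSimonian–Laird tau^2 is reported alongside.
    """
    items = list(stratum_iccs)
    if len(items) < 2:
        raise ValueError("need at least 2 strata")
    z, w = [], []
    for icc, (lo, hi) in items:
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("stratum CI is not finite")
        zl, zh = np.arctanh(np.clip([lo, hi], -0.999999, 0.999999))
        se = (zh - zl) / (2 * 1.959963984540054)
        if se <= 0:
            raise ValueError("zero-width CI gives an infinite weight")
        z.append(np.arctanh(np.clip(icc, -0.999999, 0.999999)))
        w.append(1.0 / se**2)
    z = np.asarray(z)
    w = np.asarray(w)
    zbar = np.sum(w * z) / np.sum(w)
    q = float(np.sum(w * (z - zbar) ** 2))
    df = len(items) - 1
    p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = float(max(0.0, (q - df) / c)) if c > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_value=p, tau2=tau2)
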