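"""Multilevel segmented regression of a monthly prescribing share.

The interrupted-time-series model for practice p in month t (months are
coded relative to the anchor month, the month before the safety
communication; the communication month itself is a transition month and is
excluded from fitting by default)::

    y_pt = (b0 + u0p) + (b1 + u1p) t + (b2 + u2p) post_t + (b3 + u3p) s_t
           + seasonal month effects + e_pt

where ``post_t`` switches on in the month after the communication and
``s_t = (t - 2) * post_t`` counts months since then, so b0 is the level at
the anchor month, b1 the pre-communication monthly trend, b2 the immediate
level change and b3 the change in trend.  Practice deviations
(u0..u3) ~ MVN(0, G) with an unstructured covariance G, and the
within-practice errors e follow a stationary AR(2) process.  Seasonality is
eleven calendar-month dummies with January as the reference.

Estimation maximises the restricted (REML, default) or full (ML) Gaussian
likelihood of the marginal model, in which each practice's covariance is
``V_p = Z_p G Z_p' + sigma^2 R(rho1, rho2)`` with R the AR(2) correlation
matrix at the practice's (possibly gapped) observation times.  G is
parametrised through a log-Cholesky factor, the AR coefficients through
partial autocorrelations (tanh-transformed, hence always stationary), and
the innovation scale on the log scale; the profile GLS solution for the
fixed effects is exact given the covariance parameters.  Practices sharing
an observation-time pattern share one Cholesky factorisation, so balanced
panels cost a single n_t x n_t decomposition per likelihood evaluation.

Per-practice random-effect predictions (BLUPs) are returned with their
conditional (posterior) standard errors, which feed the responder
classification downstream.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from prescvar.panel_io import parse_period

RANDOM_EFFECTS = ("intercept", "slope", "level_change", "slope_change")

#: design-matrix column backing each random effect
_EFFECT_COLUMN = {
    "intercept": "intercept",
    "slope": "t",
    "level_change": "post",
    "slope_change": "s",
}


class ConvergenceError(RuntimeError):
    pass


def build_design(share_panel: pd.DataFrame, dhpc_month,
                 include_transition: bool = False) -> pd.DataFrame:
    """Construct the segmented-regression design from a share panel.

    Time is coded in months with the anchor (month before the
    communication) at t = 0; ``post`` is 1 from t = 2 (the month after the
    communication) and ``s = (t - 2) * post``.  The communication month
    (t = 1) is excluded unless ``include_transition``, in which case it is
    kept as a pre-period row (its coding already places it on the pre
    line).  Rows with an undefined share are dropped.
    """
    dhpc = parse_period(dhpc_month)
    periods = share_panel["period"]
    if not ((periods < dhpc - 1).any() and (periods > dhpc + 1).any()):
        raise ValueError("panel must span at least 2 months either side of "
                         f"the communication month {dhpc}")
    anchor = dhpc - 1
    out = share_panel.loc[share_panel["share_defined"],
                          ["practice_id", "period", "share_pct"]].copy()
    t = np.array([(p - anchor).n for p in out["period"]], dtype=float)
    out["t"] = t
    out["post"] = (t >= 2).astype(float)
    out["s"] = (t - 2) * out["post"]
    out["month"] = [p.month for p in out["period"]]
    out["is_transition"] = t == 1
    if not include_transition:
        out = out[~out["is_transition"]]
    return out.sort_values(["practice_id", "t"]).reset_index(drop=True)


def _design_matrix(design: pd.DataFrame, seasonality: bool):
    """Fixed-effects matrix and column names (January reference dummies)."""
    cols = ["intercept", "t", "post", "s"]
    X = [np.ones(len(design)), design["t"].to_numpy(),
         design["post"].to_numpy(), design["s"].to_numpy()]
    if seasonality:
        months = sorted(design["month"].unique())
        for m in months:
            if m == 1:  # January reference
                continue
            X.append((design["month"] == m).to_numpy(dtype=float))
            cols.append(f"month_{m}")
    return np.column_stack(X), cols


def ar2_corr(rho1: float, rho2: float, times: np.ndarray) -> np.ndarray:
    """Stationary AR(2) correlation matrix at integer observation times."""
    lags = np.abs(times[:, None] - times[None, :]).astype(int)
    maxlag = int(lags.max())
    r = np.ones(maxlag + 1)
    if maxlag >= 1:
        r[1] = rho1 / (1.0 - rho2) if rho2 != 1.0 else 0.0
    for k in range(2, maxlag + 1):
        r[k] = rho1 * r[k - 1] + rho2 * r[k - 2]
    return r[lags]


def _pacf_to_ar(a1: float, a2: float) -> tuple[float, float]:
    """Map unconstrained reals to stationary AR(2) coefficients."""
    p1, p2 = np.tanh(a1), np.tanh(a2)
    return p1 * (1.0 - p2), p2


def _ar_to_pacf(rho1: float, rho2: float) -> tuple[float, float]:
    p2 = rho2
    p1 = rho1 / (1.0 - p2)
    return np.arctanh(np.clip(p1, -0.999, 0.999)), np.arctanh(
        np.clip(p2, -0.999, 0.999))


@dataclasses.dataclass
class ItsFit:
    """Result of the segmented mixed-model fit."""

    params: pd.DataFrame  # estimate / se / ci_low / ci_high / p per fixed effect
    beta: pd.Series
    cov_beta: pd.DataFrame
    G: pd.DataFrame  # random-effect covariance (q x q, named)
    rho: tuple
    sigma2: float
    loglik: float
    method: str  # "reml" or "ml"
    n_obs: int
    n_practices: int
    random_spec: tuple
    ar_order: int
    blups: pd.DataFrame  # practice_id, b_<effect>, se_<effect>
    results: pd.DataFrame  # design rows + fitted + resid
    x_columns: list
    converged: bool
    fallbacks: tuple = ()

    def summary(self) -> pd.DataFrame:
        return self.params

    @property
    def structural(self) -> pd.Series:
        """The four interrupted-time-series parameters."""
        return self.beta[["intercept", "t", "post", "s"]].rename(
            dict(zip(["intercept", "t", "post", "s"], RANDOM_EFFECTS)))


class _PatternData:
    """Rows grouped by shared observation-time pattern."""

    def __init__(self, times, X, Z, Y, practice_ids):
        self.times = times  # (n_t,)
        self.X = X          # (n_t, p)
        self.Z = Z          # (n_t, q)
        self.Y = Y          # (n_t, n_practices_in_pattern)
        self.practice_ids = practice_ids


def _group_patterns(design, X, z_cols):
    patterns = {}
    order = {}
    for pid, idx in design.groupby("practice_id", sort=True).indices.items():
        key = tuple(design["t"].to_numpy()[idx])
        patterns.setdefault(key, []).append((pid, idx))
        order[pid] = None
    out = []
    for key, members in patterns.items():
        idx0 = members[0][1]
        times = design["t"].to_numpy()[idx0]
        Xp = X[idx0]
        Zp = Xp[:, z_cols] if len(z_cols) else np.zeros((len(idx0), 0))
        Y = np.column_stack([design["share_pct"].to_numpy()[idx]
                             for _, idx in members])
        out.append(_PatternData(times, Xp, Zp, Y, [pid for pid, _ in members]))
    return out


def _unpack_theta(theta, q, ar_order):
    ntri = q * (q + 1) // 2
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    assert k == ntri
    if ar_order == 2:
        rho = _pacf_to_ar(theta[k], theta[k + 1])
        k += 2
    elif ar_order == 1:
        rho = (np.tanh(theta[k]), 0.0)
        k += 1
    else:
        rho = (0.0, 0.0)
    sigma2 = np.exp(2.0 * theta[k])
    return L @ L.T, rho, sigma2


def _neg2ll(theta, patterns, p_fixed, q, ar_order, reml):
    G, rho, sigma2 = _unpack_theta(theta, q, ar_order)
    tot_logdet = 0.0
    XtVX = np.zeros((p_fixed, p_fixed))
    XtVy = np.zeros(p_fixed)
    ytVy = 0.0
    n_obs = 0
    for pat in patterns:
        n_t, m = pat.Y.shape
        if ar_order and (rho[0] or rho[1]):
            R = ar2_corr(rho[0], rho[1], pat.times)
        else:
            R = np.eye(n_t)
        V = sigma2 * R
        if q:
            V = V + pat.Z @ G @ pat.Z.T
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(c)).sum()
        ViX = linalg.cho_solve((c, low), pat.X)
        ViY = linalg.cho_solve((c, low), pat.Y)
        tot_logdet += m * logdet
        XtVX += m * (pat.X.T @ ViX)
        XtVy += pat.X.T @ ViY.sum(axis=1)
        ytVy += float(np.einsum("ij,ij->", pat.Y, ViY))
        n_obs += n_t * m
    try:
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    except linalg.LinAlgError:
        return 1e12
    quad = ytVy - float(beta @ XtVy)
    n2ll = tot_logdet + quad + n_obs * np.log(2.0 * np.pi)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        n2ll += ld - p_fixed * np.log(2.0 * np.pi)
    return n2ll


def _fit_ols(design, X, x_names, method):
    """Closed form when there are no random effects and no AR terms."""
    y = design["share_pct"].to_numpy()
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    XtX = X.T @ X
    if method == "reml":
        sigma2 = rss / (n - p)
        sign, ld = np.linalg.slogdet(XtX / sigma2)
        loglik = -0.5 * ((n - p) * np.log(2 * np.pi)
                         + n * np.log(sigma2) + rss / sigma2 + ld)
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2)
                         + rss / sigma2)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    return beta, cov_beta, sigma2, loglik, resid


def fit_segmented(
    design: pd.DataFrame,
    random_spec: tuple = RANDOM_EFFECTS,
    ar_order: int = 2,
    method: str = "reml",
    seasonality: bool = True,
    strict: bool = False,
    maxiter: int = 500,
) -> ItsFit:
    """Fit the multilevel segmented regression.

    Parameters
    ----------
    design
        Output of :func:`build_design`.
    random_spec
        Subset of ``("intercept", "slope", "level_change", "slope_change")``
        to treat as practice random effects (unstructured covariance).
    ar_order
        0, 1 or 2 for the within-practice error autocorrelation.
    method
        ``"reml"`` (default) or ``"ml"``.  Likelihood-ratio comparisons of
        random-effect structures should use ML fits.
    strict
        Raise :class:`ConvergenceError` instead of falling back when the
        optimiser fails.  The fall-back ladder drops the AR terms first,
        then the slope-change random effect, recording each step.

    Notes
    -----
    With no random effects and ``ar_order=0`` the model collapses to
    ordinary least squares, computed in closed form.
    """
    random_spec = tuple(random_spec)
    for eff in random_spec:
        if eff not in RANDOM_EFFECTS:
            raise ValueError(f"unknown random effect {eff!r}")
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")

    X, x_names = _design_matrix(design, seasonality)
    # guard against collinear month dummies on short panels
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; for panels "
                         "shorter than a full year set seasonality=False")
    n_practices = design["practice_id"].nunique()
    q = len(random_spec)
    reml = method == "reml"

    if q == 0 and ar_order == 0:
        beta, cov_beta, sigma2, loglik, resid = _fit_ols(design, X, x_names,
                                                         method)
        fit = _assemble_fit(design, X, x_names, beta, cov_beta,
                            np.zeros((0, 0)), (0.0, 0.0), sigma2, loglik,
                            method, random_spec, ar_order, None, True, ())
        return fit

    p_fixed = X.shape[1]
    effect_col = {"intercept": 0, "slope": 1, "level_change": 2,
                  "slope_change": 3}

    fallbacks = []
    spec, order = random_spec, ar_order
    while True:
        qq = len(spec)
        zc = [effect_col[e] for e in spec]
        theta0 = _start_theta(design, X, qq, zc, order)
        pats = _group_patterns(design, X, zc)
        bounds = _theta_bounds(qq, order)
        res = optimize.minimize(
            _neg2ll, theta0, args=(pats, p_fixed, qq, order, reml),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < 1e11
        if ok or strict or (order == 0 and "slope_change" not in spec):
            break
        if order > 0:
            fallbacks.append(f"dropped AR({order}) terms")
            order = 0
        elif "slope_change" in spec:
            fallbacks.append("dropped slope_change random effect")
            spec = tuple(e for e in spec if e != "slope_change")
        else:  # pragma: no cover
            break
    if strict and not ok:
        raise ConvergenceError(res.message)

    G, rho, sigma2 = _unpack_theta(res.x, len(spec), order)
    beta, cov_beta, loglik, blup_info = _post_process(
        pats, p_fixed, G, rho, sigma2, order, reml, res.fun)
    fit = _assemble_fit(design, X, x_names, beta, cov_beta, G, rho, sigma2,
                        loglik, method, spec, order, blup_info, ok,
                        tuple(fallbacks))
    if not ok:
        warnings.warn("segmented model did not converge; fit flagged",
                      RuntimeWarning)
    return fit


def _theta_bounds(q, ar_order):
    bounds = []
    for i in range(q):
        for j in range(i + 1):
            bounds.append((-8.0, 6.0) if i == j else (-50.0, 50.0))
    bounds.extend([(-5.0, 5.0)] * (2 if ar_order == 2 else
                                   1 if ar_order == 1 else 0))
    bounds.append((-8.0, 6.0))
    return bounds


def _start_theta(design, X, q, z_cols, ar_order):
    y = design["share_pct"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    v = max(float(np.var(y - X @ beta_ols)), 1e-4)
    var_t = max(float(np.var(design["t"])), 1.0)
    diag_starts = {0: 0.4 * v, 1: 0.1 * v / var_t, 2: 0.05 * v,
                   3: 0.01 * v / var_t}
    theta = []
    for i in range(q):
        for j in range(i + 1):
            theta.append(0.5 * np.log(max(diag_starts[z_cols[i]], 1e-6))
                         if i == j else 0.0)
    theta.extend([0.0] * (2 if ar_order == 2 else 1 if ar_order == 1 else 0))
    theta.append(0.5 * np.log(0.5 * v))
    return np.array(theta)


def _post_process(patterns, p_fixed, G, rho, sigma2, ar_order, reml, n2ll):
    XtVX = np.zeros((p_fixed, p_fixed))
    XtVy = np.zeros(p_fixed)
    cache = []
    for pat in patterns:
        n_t = pat.Y.shape[0]
        R = (ar2_corr(rho[0], rho[1], pat.times)
             if ar_order and (rho[0] or rho[1]) else np.eye(n_t))
        V = sigma2 * R
        if pat.Z.shape[1]:
            V = V + pat.Z @ G @ pat.Z.T
        c = linalg.cho_factor(V, lower=True)
        ViX = linalg.cho_solve(c, pat.X)
        ViY = linalg.cho_solve(c, pat.Y)
        XtVX += pat.Y.shape[1] * (pat.X.T @ ViX)
        XtVy += pat.X.T @ ViY.sum(axis=1)
        cache.append((pat, c, ViY))
    cov_beta = np.linalg.inv(XtVX)
    beta = cov_beta @ XtVy
    loglik = -0.5 * n2ll

    blup_rows = []
    q = G.shape[0]
    if q:
        for pat, c, ViY in cache:
            ViZ = linalg.cho_solve(c, pat.Z)
            K = G @ pat.Z.T  # q x n_t
            cond_cov = G - K @ ViZ @ G.T  # shared across the pattern
            cond_se = np.sqrt(np.clip(np.diag(cond_cov), 0.0, None))
            r = pat.Y - (pat.X @ beta)[:, None]
            b = K @ linalg.cho_solve(c, r)  # BLUP: G Z' V^-1 residual
            for j, pid in enumerate(pat.practice_ids):
                blup_rows.append((pid, b[:, j], cond_se))
    return beta, cov_beta, loglik, blup_rows


def _assemble_fit(design, X, x_names, beta, cov_beta, G, rho, sigma2, loglik,
                  method, random_spec, ar_order, blup_info, converged,
                  fallbacks) -> ItsFit:
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=x_names,
    )
    q = len(random_spec)
    G_df = pd.DataFrame(np.asarray(G).reshape(q, q), index=random_spec,
                        columns=random_spec)

    if blup_info is not None and q:
        rows = []
        for pid, b, cse in blup_info:
            rec = {"practice_id": pid}
            for e, bv, sv in zip(random_spec, b, cse):
                rec[f"b_{e}"] = bv
                rec[f"se_{e}"] = sv
            rows.append(rec)
        blups = pd.DataFrame(rows).sort_values("practice_id").reset_index(
            drop=True)
    else:
        blups = pd.DataFrame({"practice_id": sorted(
            design["practice_id"].unique())})

    results = design.copy()
    fixed_fit = X @ beta
    re_fit = np.zeros(len(design))
    if q:
        bmap = blups.set_index("practice_id")
        z_cols = [ {"intercept": 0, "slope": 1, "level_change": 2,
                    "slope_change": 3}[e] for e in random_spec]
        B = bmap.loc[results["practice_id"],
                     [f"b_{e}" for e in random_spec]].to_numpy()
        re_fit = np.einsum("ij,ij->i", X[:, z_cols], B)
    results["fitted"] = fixed_fit + re_fit
    results["resid"] = results["share_pct"] - results["fitted"]

    return ItsFit(
        params=params,
        beta=pd.Series(beta, index=x_names),
        cov_beta=pd.DataFrame(cov_beta, index=x_names, columns=x_names),
        G=G_df,
        rho=tuple(rho),
        sigma2=float(sigma2),
        loglik=float(loglik),
        method=method,
        n_obs=len(design),
        n_practices=design["practice_id"].nunique(),
        random_spec=tuple(random_spec),
        ar_order=ar_order,
        blups=blups,
        results=results,
        x_columns=list(x_names),
        converged=converged,
        fallbacks=fallbacks,
    )


def lr_test_random_effect(fit_full: ItsFit, fit_reduced: ItsFit) -> dict:
    """Likelihood-ratio test comparing nested random-effect structures.

    The degrees of freedom are the difference in variance-parameter counts
    (Cholesky elements of G plus AR coefficients); the reference
    distribution is the naive chi-square, which is conservative for
    boundary variance tests.  Both fits should use ML on the same data with
    the same fixed effects.
    """
    if not set(fit_reduced.random_spec) <= set(fit_full.random_spec):
        raise ValueError("models are not nested: reduced random effects must "
                         "be a subset of the full model's")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("models were fitted to different data")
    if fit_full.method != fit_reduced.method:
        raise ValueError("mixed REML/ML comparison")
    if fit_full.method == "reml":
        warnings.warn("LR tests of random effects should use ML fits",
                      RuntimeWarning)

    def n_varpar(fit):
        qq = len(fit.random_spec)
        return qq * (qq + 1) // 2 + fit.ar_order + 1

    df = n_varpar(fit_full) - n_varpar(fit_reduced)
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    if df == 0:
        return {"statistic": stat, "df": 0, "p": 1.0}
    return {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


def predict_counterfactual(fit: ItsFit, design: pd.DataFrame) -> pd.DataFrame:
    """Population-level monthly predictions with and without the
    communication terms.

    The factual curve is the fixed-effects prediction; the counterfactual
    sets the level-change and slope-change contributions to zero, extending
    the pre-communication trend.  Calendar-month effects enter both as
    observed.  Returns one row per month with the two curves averaged over
    the design rows of that month.
    """
    seasonality = any(c.startswith("month_") for c in fit.x_columns)
    X, x_names = _design_matrix(design, seasonality)
    if x_names != fit.x_columns:
        # align columns (months present may differ); missing dummies are zero
        Xf = np.zeros((len(design), len(fit.x_columns)))
        for j, name in enumerate(fit.x_columns):
            if name in x_names:
                Xf[:, j] = X[:, x_names.index(name)]
        X = Xf
    beta = fit.beta.to_numpy()
    factual = X @ beta
    Xcf = X.copy()
    Xcf[:, fit.x_columns.index("post")] = 0.0
    Xcf[:, fit.x_columns.index("s")] = 0.0
    counterfactual = Xcf @ beta
    out = design[["period"]].copy()
    out["factual"] = factual
    out["counterfactual"] = counterfactual
    return (out.groupby("period", sort=True).mean(numeric_only=True)
            .reset_index())
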