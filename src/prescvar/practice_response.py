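"""Responder classification and predictor models.

Each practice's post-communication response is summarised by its BLUPs for
the level-change and slope-change random effects.  A practice is classed as
a *decrease* when the upper bound of the 95% confidence interval
(BLUP +/- 1.96 conditional SE) lies below zero, an *increase* when the
lower bound lies above zero, and *no change* otherwise.  Because BLUPs are
shrunken toward zero, this classification is conservative under the null.

Practice characteristics are then modelled as predictors of being a
decreaser with multivariate logistic regression (all covariates entered
jointly).  Continuous covariates are standardized (z-scored over the
practices entering the model) so odds ratios are per standard deviation;
the registrar indicator stays on its natural 0/1 scale.  Practices with
missing characteristics are dropped from the predictor model only and
reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from prescvar.segmented_model import ItsFit

CLASS_LABELS = ("decrease", "no_change", "increase")

#: covariates entering the predictor model, in reporting order
PREDICTOR_COVARIATES = [
    "gp_fte",
    "pct_gp_female",
    "pct_gp_45plus",
    "has_registrar",
    "list_size",
    "pct_patients_female",
    "pct_patients_65plus",
    "qof_overall_pct",
    "hypertension_prevalence",
    "dementia_prevalence",
    "imd_decile",
]

BINARY_COVARIATES = {"has_registrar"}


def _classify(b: np.ndarray, se: np.ndarray, z: float) -> np.ndarray:
    lo, hi = b - z * se, b + z * se
    out = np.full(len(b), "no_change", dtype=object)
    out[hi < 0] = "decrease"
    out[lo > 0] = "increase"
    return out


def classify_practices(fit: ItsFit, z: float = 1.96):
    """Three-way response labels per practice for level and slope change.

    Returns ``(classes, counts)``: a per-practice frame with the BLUPs,
    conditional SEs, CI bounds and labels, and a counts table with rows
    decrease / no change / increase by columns level / slope (n and %).
    """
    for eff in ("level_change", "slope_change"):
        if f"b_{eff}" not in fit.blups.columns:
            raise ValueError(f"fit has no {eff} random effect; refit with it "
                             "in random_spec")
        if fit.blups[f"se_{eff}"].isna().any():
            raise ValueError(f"missing conditional SEs for {eff}")

    classes = fit.blups[["practice_id"]].copy()
    for eff, short in (("level_change", "level"), ("slope_change", "slope")):
        b = fit.blups[f"b_{eff}"].to_numpy(dtype=float)
        se = fit.blups[f"se_{eff}"].to_numpy(dtype=float)
        classes[f"b_{short}"] = b
        classes[f"se_{short}"] = se
        classes[f"ci_low_{short}"] = b - z * se
        classes[f"ci_high_{short}"] = b + z * se
        classes[f"{short}_class"] = _classify(b, se, z)

    n = len(classes)
    counts = pd.DataFrame(index=list(CLASS_LABELS))
    for short in ("level", "slope"):
        cnt = classes[f"{short}_class"].value_counts()
        counts[f"{short}_n"] = [int(cnt.get(lbl, 0)) for lbl in CLASS_LABELS]
        counts[f"{short}_pct"] = 100.0 * counts[f"{short}_n"] / n
    counts.index.name = "response"
    return classes, counts


def fit_predictors(
    classes: pd.DataFrame,
    profiles: pd.DataFrame,
    outcome: str = "decrease_level",
    covariates: list | None = None,
    standardize: bool = True,
    standardize_binary: bool = False,
    min_events: int = 10,
):
    """Logistic model of practice characteristics on decrease status.

    ``outcome`` is ``"decrease_level"`` or ``"decrease_slope"``; the
    contrast is decrease vs (no change or increase).  Returns a
    ``PredictorFit``-style dict with the OR table (odds ratio, 95% CI, p
    per covariate), sample sizes, standardization constants and any flags
    (separation, non-convergence, practices dropped for missing fields).
    """
    if outcome not in ("decrease_level", "decrease_slope"):
        raise ValueError("outcome must be decrease_level or decrease_slope")
    covariates = list(covariates or PREDICTOR_COVARIATES)
    short = outcome.split("_")[1]

    data = classes[["practice_id", f"{short}_class"]].merge(
        profiles, on="practice_id", how="inner", validate="1:1")
    complete = data[covariates].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    data = data[complete]
    y = (data[f"{short}_class"] == "decrease").astype(float).to_numpy()
    n_events = int(y.sum())
    flags = []
    if n_dropped:
        flags.append(f"dropped {n_dropped} practices with missing covariates")
    if n_events == 0 or n_events == len(y):
        raise ValueError("outcome is single-class; cannot fit predictors")
    if n_events < min_events:
        warnings.warn(f"only {n_events} events for {outcome}; estimates "
                      "will be unstable", RuntimeWarning)
        flags.append("few_events")

    Xcols = {}
    scaling = {}
    for cov in covariates:
        x = data[cov].to_numpy(dtype=float)
        if standardize and (standardize_binary or cov not in BINARY_COVARIATES):
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {cov} is constant")
            Xcols[cov] = (x - mu) / sd
            scaling[cov] = {"mean": mu, "sd": sd}
        else:
            Xcols[cov] = x
            scaling[cov] = {"mean": 0.0, "sd": 1.0}
    X = sm.add_constant(pd.DataFrame(Xcols, index=data.index))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # separation and friends
            flags.append(f"fit_failed: {exc}")
            raise
    if not converged:
        flags.append("non_convergence_or_separation")

    coef = res.params.drop("const")
    se = res.bse.drop("const")
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "p": res.pvalues.drop("const"),
            "log_or": coef,
            "se_log_or": se,
        }
    ).loc[covariates]

    return {
        "outcome": outcome,
        "table": table,
        "n": len(y),
        "n_events": n_events,
        "scaling": scaling,
        "converged": converged,
        "flags": flags,
        "loglik": float(res.llf),
    }
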