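"""Synthetic practice-prescribing panels with known ground truth.

The generator mirrors the data-generating process assumed by the segmented
mixed model.  For practice ``p`` in month ``t`` (coded in months relative to
the month before the safety communication) the latent percentage share is::

    mu_pt = (b0 + u0p) + (b1 + u1p) t + (b2 + u2p) post_t + (b3 + u3p) s_t
            + gamma_{month(t)} + eps_pt

with practice effects (u0..u3) ~ MVN(0, G) (unstructured covariance),
calendar-month seasonal offsets constrained to sum to zero, and AR(2)
within-practice noise eps.  Observed counts are then
``class_items ~ Poisson(lambda_p)`` with a per-practice lognormal volume
``lambda_p`` and ``focal_items ~ Binomial(class_items, mu_pt / 100)`` with
the latent share clamped to [0, 100] (clamp events are counted and
reported in the truth record).

Practice characteristics are drawn to resemble English general practice
(list size, GP workforce, patient age/sex mix, quality scores, deprivation
decile); the vectors ``delta_level``/``delta_slope`` shift each practice's
post-communication level/slope deviations by a linear combination of its
standardized characteristics, planting an association for the predictor
models to recover.  With both deltas zero, response is independent of
characteristics.

All randomness flows from one seed through named ``numpy`` SeedSequence
spawns, so each stream (profiles, practice effects, volumes, noise, counts)
is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from prescvar import panel_io
from prescvar.panel_io import parse_period

RANDOM_EFFECTS = ("intercept", "slope", "level_change", "slope_change")

#: Characteristics that enter the delta association (standardized scale).
DELTA_COVARIATES = ("list_size", "pct_patients_65plus", "imd_decile")


def _default_gamma() -> tuple:
    """Mild winter-peaked seasonality, ~0.3 percentage-point amplitude."""
    months = np.arange(12)
    g = 0.3 * np.cos(2 * np.pi * months / 12.0)
    return tuple(np.round(g - g.mean(), 10))


def _default_corr() -> tuple:
    """Correlation of (u0, u1, u2, u3): intercept and slope correlate 0.5."""
    c = np.eye(4)
    c[0, 1] = c[1, 0] = 0.5
    return tuple(map(tuple, c))


@dataclasses.dataclass
class SimConfig:
    """Configuration of the synthetic panel generator.

    Fixed-effect defaults plant the segmented-regression estimates from the
    mirabegron study as ground truth: level 8.30 % at the anchor month,
    pre-communication trend +0.294 %/month, immediate level change −0.023,
    trend change −0.036 %/month.
    """

    n_practices: int = 200
    start: str = "2014-01"
    n_months: int = 39
    dhpc_month: str = "2015-09"
    # structural fixed effects (percentage-point scale)
    beta0: float = 8.30
    beta1: float = 0.294
    beta2: float = -0.023
    beta3: float = -0.036
    # seasonal offsets for Jan..Dec, constrained to sum to zero
    gamma: tuple = dataclasses.field(default_factory=_default_gamma)
    # random-effect SDs for (intercept, slope, level change, slope change)
    sd_b: tuple = (2.0, 0.05, 0.2, 0.02)
    corr_b: tuple = dataclasses.field(default_factory=_default_corr)
    # AR(2) residual parameters
    rho1: float = 0.3
    rho2: float = 0.1
    sigma_w: float = 1.0
    # per-practice monthly class volume: lognormal with this mean and
    # log-scale SD
    lambda_mean: float = 76.0
    lambda_sigma: float = 0.6
    # association of standardized covariates with (u2, u3); keys from
    # DELTA_COVARIATES
    delta_level: dict = dataclasses.field(default_factory=dict)
    delta_slope: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def months(self) -> pd.PeriodIndex:
        start = parse_period(self.start)
        return pd.period_range(start, periods=self.n_months, freq="M")

    def G(self) -> np.ndarray:
        sd = np.asarray(self.sd_b, dtype=float)
        corr = np.asarray(self.corr_b, dtype=float)
        return corr * np.outer(sd, sd)

    def validate(self) -> None:
        G = self.G()
        eig = np.linalg.eigvalsh(G)
        if eig.min() < -1e-10:
            raise ValueError("random-effect covariance not positive semi-definite")
        r1, r2 = self.rho1, self.rho2
        if not (abs(r2) < 1 and r1 + r2 < 1 and r2 - r1 < 1):
            raise ValueError(f"AR(2) coefficients ({r1}, {r2}) not stationary")
        if abs(sum(self.gamma)) > 1e-8:
            raise ValueError("seasonal effects must sum to zero")
        dhpc = parse_period(self.dhpc_month)
        months = self.months()
        if not (months[0] < dhpc < months[-1]):
            raise ValueError("dhpc_month must lie inside the study window")


def recovery_config(n_practices: int = 500, seed: int = 0) -> SimConfig:
    """Parameter-recovery conditions: planted structural effects, no
    seasonality, no autocorrelation (iid within-practice noise)."""
    return SimConfig(
        n_practices=n_practices,
        gamma=tuple([0.0] * 12),
        rho1=0.0,
        rho2=0.0,
        seed=seed,
    )


def null_predictor_config(n_practices: int = 150, seed: int = 0) -> SimConfig:
    """Null-association control conditions for the predictor model.

    Slope-change heterogeneity is widened (sd 0.5 %/month) so that both
    responder classes are well populated at modest panel sizes, while the
    characteristics remain unrelated to response (both deltas zero); any
    association the predictor model finds is then a false positive.
    """
    cfg = recovery_config(n_practices, seed)
    return dataclasses.replace(cfg, sd_b=(2.0, 0.05, 0.2, 0.5))


def paper_like_config(n_practices: int = 7408, seed: int = 0) -> SimConfig:
    """Full-scale conditions with a wider practice-intercept spread.

    The intercept SD is raised to 4.0 to widen the cross-sectional share
    distribution; pushing it to the observed cross-sectional SD of the real
    data would clamp a large fraction of early-period latent shares at zero
    under a Gaussian intercept, so the generator deliberately stops short of
    reproducing that spread.
    """
    return SimConfig(n_practices=n_practices, sd_b=(4.0, 0.05, 0.2, 0.02),
                     seed=seed)


def _ar2_noise(rng: np.random.Generator, n_series: int, n_t: int,
               rho1: float, rho2: float, sigma_w: float) -> np.ndarray:
    """Simulate stationary AR(2) series (rows: series, cols: time)."""
    if sigma_w == 0:
        return np.zeros((n_series, n_t))
    if rho1 == 0 and rho2 == 0:
        return rng.normal(0.0, sigma_w, size=(n_series, n_t))
    # stationary variance and lag-1 autocovariance (Yule-Walker)
    g0 = sigma_w**2 * (1 - rho2) / ((1 + rho2) * ((1 - rho2) ** 2 - rho1**2))
    g1 = rho1 * g0 / (1 - rho2)
    eps = np.empty((n_series, n_t))
    cov0 = np.array([[g0, g1], [g1, g0]])
    L = np.linalg.cholesky(cov0)
    eps[:, :2] = rng.standard_normal((n_series, 2)) @ L.T
    w = rng.normal(0.0, sigma_w, size=(n_series, n_t))
    for t in range(2, n_t):
        eps[:, t] = rho1 * eps[:, t - 1] + rho2 * eps[:, t - 2] + w[:, t]
    return eps


def _draw_profiles(rng: np.random.Generator, ids: list) -> pd.DataFrame:
    """Practice characteristics resembling English general practice."""
    n = len(ids)
    clip = lambda x, lo, hi: np.clip(x, lo, hi)
    list_size = np.round(rng.lognormal(8.80, 0.66, n)).astype(int)
    # workforce scales with list size: patients per FTE ~ lognormal around
    # the national median (~1650), keeping nearly all practices inside the
    # 500-5000 per-FTE plausibility band
    per_fte = rng.lognormal(np.log(1650.0), 0.30, n)
    prof = pd.DataFrame(
        {
            "practice_id": ids,
            "list_size": list_size,
            "pct_patients_65plus": clip(rng.normal(16.8, 6.5, n), 0, 100),
            "pct_patients_female": clip(rng.normal(49.9, 2.3, n), 0, 100),
            "gp_fte": np.maximum(np.round(list_size / per_fte, 1), 0.1),
            "pct_gp_female": clip(rng.normal(46.5, 25.9, n), 0, 100),
            "pct_gp_45plus": clip(rng.normal(56.2, 28.4, n), 0, 100),
            "has_registrar": rng.random(n) < 0.255,
            "qof_overall_pct": clip(rng.normal(95.0, 4.0, n), 0, 100),
            "hypertension_prevalence": clip(rng.normal(13.9, 2.5, n), 0, 100),
            "dementia_prevalence": clip(rng.normal(0.8, 0.35, n), 0, 100),
            "imd_decile": rng.integers(1, 11, n),
        }
    )
    return prof


def _delta_shift(profiles: pd.DataFrame, delta: dict) -> np.ndarray:
    shift = np.zeros(len(profiles))
    for cov, coef in delta.items():
        x = profiles[cov].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=0)
        shift += coef * z
    return shift


def simulate_panel(config: SimConfig):
    """Generate (panel, profiles, truth) under the configured process.

    Returns the practice-month count panel and characteristics table in the
    ``panel_io`` layouts, plus a truth record holding every latent quantity:
    the structural parameters, G, per-practice effects, latent shares,
    AR noise, volumes and the clamp rate.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("profiles", "effects", "volumes", "noise", "counts"),
            root.spawn(5),
        )
    }

    n = config.n_practices
    ids = [f"S{i:05d}" for i in range(n)]
    months = config.months()
    dhpc = parse_period(config.dhpc_month)
    anchor = dhpc - 1
    t = np.array([(m - anchor).n for m in months], dtype=float)
    post = (t >= 2).astype(float)  # from the month after the communication
    s = (t - 2) * post
    gamma = np.asarray(config.gamma)[[m.month - 1 for m in months]]

    profiles = _draw_profiles(streams["profiles"], ids)

    G = config.G()
    u = streams["effects"].multivariate_normal(
        np.zeros(4), G, size=n, method="eigh"  # eigh tolerates singular G
    )
    u[:, 2] += _delta_shift(profiles, config.delta_level)
    u[:, 3] += _delta_shift(profiles, config.delta_slope)

    lam_mu = np.log(config.lambda_mean) - config.lambda_sigma**2 / 2.0
    lam = streams["volumes"].lognormal(lam_mu, config.lambda_sigma, n)

    eps = _ar2_noise(streams["noise"], n, len(months),
                     config.rho1, config.rho2, config.sigma_w)

    mu = (
        (config.beta0 + u[:, 0])[:, None]
        + (config.beta1 + u[:, 1])[:, None] * t[None, :]
        + (config.beta2 + u[:, 2])[:, None] * post[None, :]
        + (config.beta3 + u[:, 3])[:, None] * s[None, :]
        + gamma[None, :]
        + eps
    )
    clamped = np.clip(mu, 0.0, 100.0)
    clamp_rate = float(np.mean((mu < 0.0) | (mu > 100.0)))

    rng_counts = streams["counts"]
    class_items = rng_counts.poisson(lam[:, None], size=mu.shape)
    focal_items = rng_counts.binomial(class_items, clamped / 100.0)
    # other (non-class) items: a stable practice-level volume so the panel
    # carries realistic totals for the low-volume exclusion rule
    other_items = rng_counts.poisson(40.0 * lam[:, None], size=mu.shape)

    panel = pd.DataFrame(
        {
            "practice_id": np.repeat(ids, len(months)),
            "period": np.tile(months, n),
            "focal_items": focal_items.ravel(),
            "class_items": class_items.ravel(),
            "total_items": (class_items + other_items).ravel(),
        }
    )

    truth = {
        "beta": {
            "intercept": config.beta0,
            "slope": config.beta1,
            "level_change": config.beta2,
            "slope_change": config.beta3,
        },
        "gamma": list(config.gamma),
        "G": G.tolist(),
        "rho": [config.rho1, config.rho2],
        "sigma_w": config.sigma_w,
        "clamp_rate": clamp_rate,
        "practice_effects": pd.DataFrame(
            u, columns=list(RANDOM_EFFECTS)
        ).assign(practice_id=ids),
        "lambda": pd.Series(lam, index=ids, name="lambda"),
        "latent_share": pd.DataFrame(mu, index=ids, columns=months.astype(str)),
        "delta_level": dict(config.delta_level),
        "delta_slope": dict(config.delta_slope),
        "seed": config.seed,
    }
    return panel_io.validate_panel(panel), profiles, truth


_FIXTURE_SIZES = {"tiny": (10, 8), "small": (200, 39), "paper_like": (7408, 39)}


def make_fixture(size: str, seed: int, outdir) -> dict:
    """Write prescribing/characteristics CSV fixtures plus a truth JSON.

    ``tiny`` is 10 practices x 8 months for unit tests; ``small`` is 200
    practices over the full window with five practices planted to violate
    one exclusion rule each; ``paper_like`` is full scale (slow).  Returns
    the file paths.
    """
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    n, n_months = _FIXTURE_SIZES[size]
    cfg = SimConfig(n_practices=n, n_months=n_months, seed=seed)
    if size == "tiny":
        cfg = dataclasses.replace(cfg, start="2015-05", dhpc_month="2015-09")
    panel, profiles, truth = simulate_panel(cfg)

    planted = []
    if size == "small":
        ids = sorted(profiles["practice_id"])[:5]
        prof = profiles.set_index("practice_id")
        prof.loc[ids[0], "list_size"] = 700  # below minimum list
        prof.loc[ids[1], ["list_size", "gp_fte"]] = [2000, 5.0]  # <500/FTE
        prof.loc[ids[2], ["list_size", "gp_fte"]] = [6000, 1.0]  # >5000/FTE
        prof.loc[ids[3], "gp_fte"] = 0.0  # per-FTE undefined
        profiles = prof.reset_index()
        # low volume: one in-window month with <100 total items
        mask = (panel["practice_id"] == ids[4]) & (
            panel["period"] == parse_period(cfg.dhpc_month) + 3
        )
        panel.loc[mask, ["focal_items", "class_items", "total_items"]] = [0, 10, 50]
        planted = [
            {"practice_id": ids[0], "rule": "min_list"},
            {"practice_id": ids[1], "rule": "per_fte_low"},
            {"practice_id": ids[2], "rule": "per_fte_high"},
            {"practice_id": ids[3], "rule": "per_fte_undefined"},
            {"practice_id": ids[4], "rule": "low_volume"},
        ]
        # ensure the remaining practices cannot trip a rule by chance
        prof = profiles.set_index("practice_id")
        others = [p for p in prof.index if p not in ids]
        ratio = prof.loc[others, "list_size"] / prof.loc[others, "gp_fte"]
        bad = ratio[(ratio < 500) | (ratio > 5000)].index
        small = prof.loc[others][prof.loc[others, "list_size"] < 750].index
        fix = bad.union(small)
        prof.loc[fix, "list_size"] = 6000
        prof.loc[fix, "gp_fte"] = 4.0
        profiles = prof.reset_index()

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescribing": outdir / f"{size}_prescribing.csv",
        "profiles": outdir / f"{size}_profiles.csv",
        "truth": outdir / f"{size}_truth.json",
    }
    panel_io.write_prescribing(panel, paths["prescribing"])
    panel_io.write_profiles(profiles, paths["profiles"])
    record = {
        k: v
        for k, v in truth.items()
        if k not in ("practice_effects", "lambda", "latent_share")
    }
    record["practice_effects"] = truth["practice_effects"].to_dict("list")
    record["planted_exclusions"] = planted
    record["size"] = size
    paths["truth"].write_text(json.dumps(record, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
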