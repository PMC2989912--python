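"""Fruiting-phenology models.

From weekly trap records three descriptive metrics are computed per
tree-season: production (total fruits trapped), peak (count-weighted mean
fall day, days since July 1) and duration (four times the count-weighted SD
of fall days).  Two complementary mixed models drive the simulator:

* **model I** — season totals:  N_ij ~ Poisson(exp(c1 + c2*dbh_i + u_i + v_j))
  with crossed tree/season normal random intercepts (Laplace fit).
* **model II** — individual fruit-fall dates:
  day = c3 + w_i + z_j + eps,  w ~ N(0, sd_w^2), z ~ N(0, sd_z^2),
  eps ~ N(0, sigma_resid^2), fit by REML.  The residual SD is what encodes
  the within-season duration of fruiting, replacing the width parameter of
  an (intractable) nonlinear Gaussian-curve mixed model.

Variance components sit on the boundary of their parameter space under the
null, so p-values come from a parametric simulate-under-the-null bootstrap
of the likelihood-ratio statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glmm import (ConvergenceError, CrossedLMM, CrossedPoissonGLMM, LMMResults,
                   NonIdentifiableError, PoissonGLMMResults)
from .io import PhenologyRecord

__all__ = [
    "SeasonMetrics",
    "compute_season_metrics",
    "ModelIFit",
    "ModelIIFit",
    "DescriptiveFit",
    "FruitProductionModel",
    "FruitDateModel",
    "fit_model_I",
    "fit_model_II",
    "fit_descriptive_lmm",
    "bootstrap_variance_pvalue",
    "records_to_fruit_dates",
]


# ---------------------------------------------------------------------------
# Season metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonMetrics:
    tree_id: str
    season_id: str
    production: int                 # total fruits trapped
    peak: Optional[float]           # count-weighted mean day; None if no fruit
    duration: Optional[float]       # 4 x weighted SD of days; None if < 2 fruits


def compute_season_metrics(records: Sequence[PhenologyRecord]) -> list[SeasonMetrics]:
    """Per tree-season production, peak and duration.

    The SD underlying the duration uses the n-1 denominator over individual
    fruits; all fruits of one trap visit carry that visit's day.
    """
    df = pd.DataFrame(
        [(r.tree_id, r.season_id, r.day, r.count) for r in records],
        columns=["tree_id", "season_id", "day", "count"],
    )
    out = []
    for (tid, sid), g in df.groupby(["tree_id", "season_id"], sort=True):
        n = int(g["count"].sum())
        if n == 0:
            out.append(SeasonMetrics(tid, sid, 0, None, None))
            continue
        peak = float(np.average(g["day"], weights=g["count"]))
        if n < 2:
            out.append(SeasonMetrics(tid, sid, n, peak, None))
            continue
        ss = float((g["count"] * (g["day"] - peak) ** 2).sum())
        duration = 4.0 * float(np.sqrt(ss / (n - 1)))
        out.append(SeasonMetrics(tid, sid, n, peak, duration))
    return out


def records_to_fruit_dates(records: Sequence[PhenologyRecord]) -> pd.DataFrame:
    """Expand trap visits to one row per trapped fruit (tree_id, season_id, day)."""
    rows = [(r.tree_id, r.season_id, r.day) for r in records for _ in range(int(r.count))]
    return pd.DataFrame(rows, columns=["tree_id", "season_id", "day"])


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelIFit:
    """Poisson GLMM of season totals (log link, DBH fixed effect)."""

    c1: float                   # log-scale intercept
    c2: float                   # log-scale slope per mm DBH
    sd_u: float                 # between-tree SD (log scale)
    sd_v: float                 # between-season SD (log scale)
    loglik: float
    c1_se: float = np.nan
    c2_se: float = np.nan
    sd_u_se: float = np.nan
    sd_v_se: float = np.nan
    p_u: Optional[float] = None
    p_v: Optional[float] = None
    p_c2: Optional[float] = None
    raw: Optional[PoissonGLMMResults] = None

    def summary(self) -> str:
        lines = ["Model I: season fruit totals ~ Poisson, log link, crossed tree/season intercepts",
                 f"  c1 (intercept)      = {self.c1:9.4f}  (SE {self.c1_se:.4f})",
                 f"  c2 (per mm DBH)     = {self.c2:9.6f}  (SE {self.c2_se:.6f})",
                 f"  sd_u (tree)         = {self.sd_u:9.4f}",
                 f"  sd_v (season)       = {self.sd_v:9.4f}",
                 f"  logLik              = {self.loglik:.2f}"]
        for nm, p in (("p_u", self.p_u), ("p_v", self.p_v), ("p_c2", self.p_c2)):
            if p is not None:
                lines.append(f"  {nm:<19} = {p:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("c1", "c2", "sd_u", "sd_v", "loglik", "c1_se", "c2_se",
                 "sd_u_se", "sd_v_se", "p_u", "p_v", "p_c2")}


@dataclass
class ModelIIFit:
    """Gaussian REML model of individual fruit-fall dates."""

    c3: float                   # intercept, days since July 1
    sd_w: float                 # between-tree SD, days
    sd_z: float                 # between-season SD, days
    sigma_resid: float          # within tree-season SD, days (season duration)
    loglik: float
    c3_se: float = np.nan
    p_w: Optional[float] = None
    p_z: Optional[float] = None
    raw: Optional[LMMResults] = None

    def summary(self) -> str:
        return "\n".join([
            "Model II: fruit-fall date ~ Gaussian, crossed tree/season intercepts (REML)",
            f"  c3 (intercept)      = {self.c3:9.2f} d  (SE {self.c3_se:.2f})",
            f"  sd_w (tree)         = {self.sd_w:9.2f} d",
            f"  sd_z (season)       = {self.sd_z:9.2f} d",
            f"  sigma_resid         = {self.sigma_resid:9.2f} d",
            f"  logLik (REML)       = {self.loglik:.2f}",
        ])

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("c3", "sd_w", "sd_z", "sigma_resid", "loglik", "c3_se", "p_w", "p_z")}


@dataclass
class DescriptiveFit:
    """One of the three per-metric crossed random-effects models."""

    metric: str                 # production | peak | duration
    intercept: float
    sd_tree: float
    sd_season: float
    sd_resid: float
    loglik: float
    p_tree: Optional[float] = None
    p_season: Optional[float] = None
    raw: object = None

    def summary(self) -> str:
        return (f"Descriptive LMM [{self.metric}]: intercept {self.intercept:.2f}, "
                f"sd_tree {self.sd_tree:.2f}, sd_season {self.sd_season:.2f}, "
                f"sd_resid {self.sd_resid:.2f}")


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class FruitProductionModel:
    """Model I as a fittable object.

    Parameters
    ----------
    totals : DataFrame with columns tree_id, season_id, production
    dbh : mapping tree_id -> DBH (mm)
    """

    def __init__(self, totals: pd.DataFrame, dbh: dict):
        t = totals.copy()
        needed = {"tree_id", "season_id", "production"}
        if not needed.issubset(t.columns):
            raise ValueError(f"totals must have columns {sorted(needed)}")
        if t["tree_id"].nunique() < 3 or t["season_id"].nunique() < 3:
            raise ValueError("need >= 3 trees and >= 3 seasons")
        y = t["production"].to_numpy()
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("production totals must be non-negative integers")
        missing = set(t["tree_id"]) - set(dbh)
        if missing:
            raise ValueError(f"no DBH for tree(s) {sorted(missing)[:5]}")
        d = t["tree_id"].map(dbh).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(t)), d])
        self._glmm = CrossedPoissonGLMM(
            y, X, {"tree": t["tree_id"].to_numpy(), "season": t["season_id"].to_numpy()}
        )
        self.totals = t
        self.dbh = dict(dbh)

    def fit(self, **kw) -> ModelIFit:
        res = self._glmm.fit(**kw)
        sd_se = res.sd_se if res.sd_se is not None else [np.nan, np.nan]
        return ModelIFit(
            c1=float(res.beta[0]), c2=float(res.beta[1]),
            sd_u=float(res.sd_components[0]), sd_v=float(res.sd_components[1]),
            loglik=res.loglik, c1_se=float(res.beta_se[0]), c2_se=float(res.beta_se[1]),
            sd_u_se=float(sd_se[0]), sd_v_se=float(sd_se[1]), raw=res,
        )


class FruitDateModel:
    """Model II as a fittable object.

    Parameters
    ----------
    fruit_dates : DataFrame with one row per trapped fruit
        (columns tree_id, season_id, day)
    """

    def __init__(self, fruit_dates: pd.DataFrame):
        f = fruit_dates
        needed = {"tree_id", "season_id", "day"}
        if not needed.issubset(f.columns):
            raise ValueError(f"fruit_dates must have columns {sorted(needed)}")
        if len(f) < 2:
            raise ValueError("need >= 2 fruits")
        cells = f.groupby(["tree_id", "season_id"]).size()
        if len(cells) < 2:
            raise NonIdentifiableError(
                "a single tree-season cell cannot separate tree, season and "
                "residual variances"
            )
        self.frame = f
        self._lmm = CrossedLMM(
            f["day"].to_numpy(float), np.ones((len(f), 1)),
            {"tree": f["tree_id"].to_numpy(), "season": f["season_id"].to_numpy()},
        )
        # one observation per cell leaves sigma_resid confounded with the
        # interaction; refuse to return a silent answer
        if (cells <= 1).all():
            raise NonIdentifiableError(
                "every tree-season cell has a single fruit: the residual SD is "
                "not identifiable from the crossed design"
            )

    def fit(self, reml: bool = True) -> ModelIIFit:
        res = self._lmm.fit(reml=reml)
        return ModelIIFit(
            c3=float(res.beta[0]), sd_w=float(res.sd_components[0]),
            sd_z=float(res.sd_components[1]), sigma_resid=float(res.sigma_resid),
            loglik=res.loglik, c3_se=float(res.beta_se[0]), raw=res,
        )


def fit_model_I(totals: pd.DataFrame, dbh: dict, **kw) -> ModelIFit:
    return FruitProductionModel(totals, dbh).fit(**kw)


def fit_model_II(fruit_dates: pd.DataFrame, reml: bool = True) -> ModelIIFit:
    return FruitDateModel(fruit_dates).fit(reml=reml)


def fit_descriptive_lmm(
    metrics: Sequence[SeasonMetrics],
    metric: str,
    dbh: Optional[dict] = None,
) -> DescriptiveFit:
    """Fit one of the three descriptive crossed random-effects models.

    peak and duration are Gaussian REML fits with no fixed effects beyond the
    intercept; production is the Poisson log-link model and requires *dbh*.
    """
    if metric not in {"production", "peak", "duration"}:
        raise ValueError("metric must be production, peak or duration")
    if metric == "production":
        if dbh is None:
            raise ValueError("the production model needs per-tree DBH")
        totals = pd.DataFrame(
            [(m.tree_id, m.season_id, m.production) for m in metrics],
            columns=["tree_id", "season_id", "production"],
        )
        fit = fit_model_I(totals, dbh)
        return DescriptiveFit("production", fit.c1, fit.sd_u, fit.sd_v, np.nan,
                              fit.loglik, raw=fit)
    rows = [(m.tree_id, m.season_id, getattr(m, metric)) for m in metrics
            if getattr(m, metric) is not None]
    if not rows:
        raise ValueError(f"no tree-season has a defined {metric}")
    df = pd.DataFrame(rows, columns=["tree_id", "season_id", "value"])
    if df["tree_id"].nunique() < 3 or df["season_id"].nunique() < 3:
        raise ValueError("need >= 3 trees and >= 3 seasons with a defined metric")
    lmm = CrossedLMM(df["value"].to_numpy(float), np.ones((len(df), 1)),
                     {"tree": df["tree_id"].to_numpy(), "season": df["season_id"].to_numpy()})
    res = lmm.fit(reml=True)
    return DescriptiveFit(metric, float(res.beta[0]), float(res.sd_components[0]),
                          float(res.sd_components[1]), float(res.sigma_resid),
                          res.loglik, raw=res)


# ---------------------------------------------------------------------------
# Parametric bootstrap p-values
# ---------------------------------------------------------------------------

def bootstrap_variance_pvalue(
    model,
    component: str,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    max_failure_fraction: float = 0.10,
) -> float:
    """Parametric bootstrap p-value for dropping one model term.

    *model* is a :class:`FruitDateModel`, :class:`FruitProductionModel` or a
    bare :class:`~fruitscape.glmm.CrossedLMM`/:class:`CrossedPoissonGLMM`.
    *component* is ``"tree"``, ``"season"`` (variance components) or
    ``"fixed"`` (the last fixed-effect column, ML-based).

    The observed likelihood-ratio statistic is compared with its distribution
    under the null model, refit to ``n_boot`` datasets simulated from that
    null:  p = (1 + #{LR* >= LR_obs}) / (n_boot + 1).  Bootstrap refits that
    fail are discarded; more than ``max_failure_fraction`` failures raises.
    """
    rng = rng or np.random.default_rng()
    core = getattr(model, "_lmm", None) or getattr(model, "_glmm", None) or model
    gaussian = isinstance(core, CrossedLMM)
    reml = component != "fixed" and gaussian

    def build(y, X, factors):
        return (CrossedLMM if gaussian else CrossedPoissonGLMM)(y, X, factors)

    factors_full = {n: core.levels[i][core.codes[i]] for i, n in enumerate(core.factor_names)}
    if component in core.factor_names:
        null_factors = {n: v for n, v in factors_full.items() if n != component}
        X_full, X_null = core.X, core.X
    elif component == "fixed":
        if core.p < 2:
            raise ValueError("no non-intercept fixed effect to test")
        null_factors = factors_full
        X_full, X_null = core.X, core.X[:, :-1]
    else:
        raise ValueError(f"unknown component {component!r}; expected one of "
                         f"{core.factor_names + ('fixed',)}")

    y_obs = core.y.copy()
    full = build(y_obs, X_full, factors_full)
    null = build(y_obs, X_null, null_factors)

    if gaussian:
        return _bootstrap_gaussian(full, null, y_obs, n_boot, rng, reml)
    return _bootstrap_glmm(full, null, n_boot, rng, max_failure_fraction)


def _theta_axis():
    """Relative-SD grid: zero (the boundary) plus a geometric sweep.

    The grid is fixed and data-independent: observed and bootstrap statistics
    must be under-maximized identically, or the comparison loses its
    exchangeability and the p-value its calibration.
    """
    return np.concatenate([[0.0], np.geomspace(0.01, 12.0, 55)])


def _bootstrap_gaussian(full: CrossedLMM, null: CrossedLMM, y_obs, n_boot, rng, reml):
    """Grid-profiled REML likelihood-ratio bootstrap.

    The same grid estimator is applied to the observed data and to every
    bootstrap dataset, so the comparison is exchangeable under the null; the
    theta-dependent factorizations are shared across the whole batch, which
    makes 199 refits cost little more than one.
    """
    import itertools

    fit_null = null.fit(reml=reml, compute_se=False)
    axis = _theta_axis()
    grid_full = list(itertools.product(axis, repeat=len(full.sizes)))
    grid_null = list(itertools.product(axis, repeat=len(null.sizes)))

    prods_full = full.multi_y_products(y_obs[:, None])
    prods_null = null.multi_y_products(y_obs[:, None])
    dev1 = full.min_deviance_grid(prods_full, grid_full, reml=reml)[0]
    dev0 = null.min_deviance_grid(prods_null, grid_null, reml=reml)[0]
    lr_obs = max(dev0 - dev1, 0.0)

    block = max(1, min(n_boot, int(2e7 / max(full.n, 1))))
    exceed, done = 0, 0
    while done < n_boot:
        b = min(block, n_boot - done)
        Y = null.simulate_multi(fit_null, rng, b)
        d1 = full.min_deviance_grid(full.multi_y_products(Y), grid_full, reml=reml)
        d0 = null.min_deviance_grid(null.multi_y_products(Y), grid_null, reml=reml)
        lr = np.maximum(d0 - d1, 0.0)
        exceed += int(np.sum(lr >= lr_obs - 1e-10))
        done += b
    return (1.0 + exceed) / (n_boot + 1.0)


def _bootstrap_glmm(full: CrossedPoissonGLMM, null: CrossedPoissonGLMM, n_boot, rng,
                    max_failure_fraction):
    fit_full, fit_null = full.fit(compute_se=False), null.fit(compute_se=False)
    lr_obs = 2.0 * (fit_full.loglik - fit_null.loglik)
    exceed, failures, done = 0, 0, 0
    while done < n_boot:
        if failures > max_failure_fraction * n_boot + 10:
            raise ConvergenceError(
                f"more than {max_failure_fraction:.0%} of bootstrap refits failed"
            )
        y_star = null.simulate(fit_null, rng)
        try:
            f1 = full.refit_y(y_star)
            f0 = null.refit_y(y_star)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        lr = 2.0 * (f1.loglik - f0.loglik)
        if lr >= lr_obs - 1e-10:
            exceed += 1
        done += 1
    return (1.0 + exceed) / (n_boot + 1.0)
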