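"""Stochastic fruit-availability landscapes.

The fitted spatial and phenology models compose into an island-scale,
multi-season simulation:

1. a forest is drawn from the fitted intensity surface (thinning) with DBHs
   from the rank-transform sampler;
2. per-tree and per-season random effects (u, v for production; w, z for the
   peak date) are drawn from their fitted normal distributions;
3. each tree-season gets an expected total  lambda_ij = exp(c1 + c2 dbh + u_i + v_j)
   and a Gaussian seasonal profile centred on  peak_ij = c3 + w_i + z_j  with
   SD sigma_resid, so that the daily curve integrates back to lambda_ij;
4. optionally, realized fruit counts are drawn per day-bin as independent
   Poisson variates with mean lambda_ij(t) * dt.

lambda is calibrated to *trapped* fruits, exactly as the models were; a
user-supplied multiplier converts to whole-tree production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dbh import DbhDistribution, sample_dbh
from .phenology import ModelIFit, ModelIIFit
from .pointprocess import DensitySurface, simulate_poisson
from .window import SpatialWindow

__all__ = [
    "SimulatedForest",
    "RandomEffectVectors",
    "FruitLandscape",
    "simulate_forest",
    "draw_random_effects",
    "expected_season_total",
    "expected_fruit_intensity",
    "simulate_landscape",
]

SEASON_DAYS = 365


@dataclass(frozen=True)
class SimulatedForest:
    """Simulated stem positions and sizes (no real tree is ever included)."""

    x: np.ndarray
    y: np.ndarray
    dbh: np.ndarray
    window: SpatialWindow

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def tree_ids(self) -> np.ndarray:
        return np.array([f"sim{k:05d}" for k in range(self.n)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.tree_ids, "x": self.x, "y": self.y, "dbh": self.dbh})


@dataclass(frozen=True)
class RandomEffectVectors:
    """Independent mean-zero tree/season effects for production and peak."""

    u: np.ndarray   # per-tree production effect, log scale
    v: np.ndarray   # per-season production effect, log scale
    w: np.ndarray   # per-tree peak shift, days
    z: np.ndarray   # per-season peak shift, days


@dataclass
class FruitLandscape:
    """Per-tree, per-season, per-day expected (and optional realized) fruit."""

    forest: SimulatedForest
    days: np.ndarray                    # day grid, days since July 1
    expected: np.ndarray                # (n_trees, n_seasons, n_days) fruits/day
    effects: RandomEffectVectors
    season_totals: np.ndarray           # (n_trees, n_seasons) lambda_ij
    realized: Optional[np.ndarray] = None  # Poisson draws per (tree, season, bin)

    @property
    def n_seasons(self) -> int:
        return self.expected.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (tree_id, season, day, expected[, realized])."""
        nt, ns, nd = self.expected.shape
        ids = self.forest.tree_ids
        rec = {
            "tree_id": np.repeat(ids, ns * nd),
            "season": np.tile(np.repeat(np.arange(ns), nd), nt),
            "day": np.tile(self.days, nt * ns),
            "expected": self.expected.ravel(),
        }
        if self.realized is not None:
            rec["realized"] = self.realized.ravel()
        return pd.DataFrame(rec)

    def day_frame(self, season: int, day_index: int) -> pd.DataFrame:
        """One map frame: tree positions with that day's expected fruit."""
        df = self.forest.to_frame()
        df["expected"] = self.expected[:, season, day_index]
        if self.realized is not None:
            df["realized"] = self.realized[:, season, day_index]
        return df


def simulate_forest(
    window: SpatialWindow,
    intensity: DensitySurface,
    dbh_model: DbhDistribution,
    rng: np.random.Generator,
) -> SimulatedForest:
    """Draw tree positions from the fitted intensity and sizes from the
    rank-transform DBH sampler."""
    pat = simulate_poisson(intensity, window, rng)
    if pat.n == 0:
        return SimulatedForest(np.empty(0), np.empty(0), np.empty(0), window)
    dbh = sample_dbh(dbh_model, pat.n, rng)
    return SimulatedForest(pat.x, pat.y, dbh, window)


def draw_random_effects(
    n: int, s: int, model_I: ModelIFit, model_II: ModelIIFit, rng: np.random.Generator
) -> RandomEffectVectors:
    """u ~ N(0, sd_u^2)^n, v ~ N(0, sd_v^2)^s, w ~ N(0, sd_w^2)^n,
    z ~ N(0, sd_z^2)^s, all independent."""
    return RandomEffectVectors(
        u=model_I.sd_u * rng.standard_normal(n),
        v=model_I.sd_v * rng.standard_normal(s),
        w=model_II.sd_w * rng.standard_normal(n),
        z=model_II.sd_z * rng.standard_normal(s),
    )


def expected_season_total(dbh, u, v, model_I: ModelIFit):
    """lambda_ij = exp(c1 + c2*dbh_i + u_i + v_j), fruits per season."""
    return np.exp(model_I.c1 + model_I.c2 * np.asarray(dbh, float) + u + v)


def expected_fruit_intensity(t, lambda_ij, peak_ij, sigma_resid: float):
    """Gaussian seasonal curve: lambda_ij(t) =
    lambda_ij * exp(-(t - peak)^2 / 2 sigma^2) / (sigma sqrt(2 pi))."""
    if sigma_resid <= 0:
        raise ValueError("sigma_resid must be > 0")
    t = np.asarray(t, dtype=float)
    norm = 1.0 / (sigma_resid * np.sqrt(2.0 * np.pi))
    return lambda_ij * norm * np.exp(-((t - peak_ij) ** 2) / (2.0 * sigma_resid**2))


def simulate_landscape(
    forest: SimulatedForest,
    model_I: ModelIFit,
    model_II: ModelIIFit,
    s: int,
    rng: np.random.Generator,
    time_step: float = 1.0,
    realize: bool = False,
    trap_to_tree: float = 1.0,
) -> FruitLandscape:
    """Simulate ``s`` seasons of daily fruit availability for one forest.

    The day grid covers a 365-day season from July 1 at ``time_step``
    resolution.  ``trap_to_tree`` rescales trap-calibrated totals to
    whole-tree production if desired.  With ``realize`` the landscape also
    carries independent Poisson counts per (tree, season, bin) with mean
    lambda_ij(t) * dt.
    """
    if s < 1:
        raise ValueError("need at least one season")
    if time_step <= 0 or time_step > SEASON_DAYS:
        raise ValueError("time_step must be in (0, 365]")
    n = forest.n
    days = np.arange(0.0, SEASON_DAYS, time_step) + 0.5 * time_step
    eff = draw_random_effects(n, s, model_I, model_II, rng)
    lam = trap_to_tree * expected_season_total(
        forest.dbh[:, None], eff.u[:, None], eff.v[None, :], model_I
    )                                                       # (n, s)
    peak = model_II.c3 + eff.w[:, None] + eff.z[None, :]     # (n, s)
    expected = expected_fruit_intensity(
        days[None, None, :], lam[:, :, None], peak[:, :, None], model_II.sigma_resid
    )
    realized = None
    if realize:
        realized = rng.poisson(expected * time_step)
    return FruitLandscape(forest=forest, days=days, expected=expected,
                          effects=eff, season_totals=lam, realized=realized)
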