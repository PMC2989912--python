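"""Stem-size (DBH) distribution via rank-transformation to normality.

The reference DBH sample (typically the union of all ground-surveyed stems)
is mapped to standard-normal scores by rank; simulated trees draw a standard
normal deviate and invert the score map by monotone linear interpolation.
Tails extrapolate linearly but are clamped to within 10% beyond the observed
range, so a simulated forest never contains absurdly large stems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DbhDistribution", "fit_dbh_distribution", "sample_dbh"]


@dataclass(frozen=True)
class DbhDistribution:
    """Empirical quantile <-> normal-score map for DBH (mm)."""

    dbh: np.ndarray     # sorted reference values, mm
    scores: np.ndarray  # matching standard-normal scores (midrank-based)

    @property
    def n_ref(self) -> int:
        return int(self.dbh.size)

    @property
    def lower_clamp(self) -> float:
        return float(self.dbh[0] * 0.9)

    @property
    def upper_clamp(self) -> float:
        return float(self.dbh[-1] * 1.1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dbh": self.dbh, "score": self.scores})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DbhDistribution":
        return cls(np.asarray(df["dbh"], float), np.asarray(df["score"], float))


def fit_dbh_distribution(dbhs) -> DbhDistribution:
    """Build the rank-to-normal score map from a reference sample.

    Ties get midranks, so the map is monotone nondecreasing even for
    duplicate-heavy census data.  Requires >= 10 positive values.
    """
    d = np.asarray(dbhs, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 10:
        raise ValueError(f"need >= 10 DBH values to fit the quantile map, got {d.size}")
    if (d <= 0).any():
        raise ValueError("all DBH values must be > 0")
    order = np.argsort(d, kind="stable")
    d = d[order]
    ranks = stats.rankdata(d, method="average")  # midranks for ties
    scores = stats.norm.ppf((ranks - 0.5) / d.size)
    return DbhDistribution(d, scores)


def sample_dbh(model: DbhDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw *n* DBH values (mm) by inverting the score map at N(0,1) deviates.

    Interpolation is linear in (score, dbh) space; outside the reference score
    range the last segment is extrapolated linearly, then clamped to
    [0.9*min, 1.1*max].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    z = rng.standard_normal(n)
    s, d = model.scores, model.dbh
    if d.size == 1 or d[0] == d[-1]:
        return np.full(n, float(d[0]))
    # np.interp clamps; handle extrapolation with the terminal segment slopes
    out = np.interp(z, s, d)
    lo, hi = z < s[0], z > s[-1]
    if lo.any():
        slope = (d[1] - d[0]) / (s[1] - s[0]) if s[1] > s[0] else 0.0
        out[lo] = d[0] + slope * (z[lo] - s[0])
    if hi.any():
        slope = (d[-1] - d[-2]) / (s[-1] - s[-2]) if s[-1] > s[-2] else 0.0
        out[hi] = d[-1] + slope * (z[hi] - s[-1])
    return np.clip(out, model.lower_clamp, model.upper_clamp)
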