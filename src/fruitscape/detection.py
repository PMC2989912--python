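"""Aerial detectability of canopy trees as a logistic function of stem size.

Large-crowned emergents are visible in aerial photographs while smaller stems
are hidden below the canopy, so an aerial survey is a size-biased thinning of
the true pattern.  The model is a logistic GLM,

    p(visible | dbh) = expit(beta0 + beta1 * dbh),

fit by maximum likelihood when visibility labels exist, or calibrated so that
the mean detection probability over a DBH sample matches a known overall
visibility fraction (e.g. 14.7% of stems above 200 mm DBH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "AerialDetectionModel",
    "DetectionResults",
    "fit_detection_glm",
    "detection_probability",
    "calibrate_detection",
    "SeparationError",
]


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist; use a penalized fit."""


@dataclass(frozen=True)
class DetectionResults:
    """Fitted logistic visibility model."""

    beta0: float                   # log-odds intercept
    beta1: float                   # log-odds per mm DBH
    fit_meta: dict = field(default_factory=dict)

    def predict(self, dbh) -> np.ndarray:
        """P(visible) at the given DBH (mm); always in (0, 1)."""
        dbh = np.asarray(dbh, dtype=float)
        return special.expit(self.beta0 + self.beta1 * dbh)

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "beta1": self.beta1, "fit_meta": dict(self.fit_meta)}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionResults":
        return cls(float(d["beta0"]), float(d["beta1"]), dict(d.get("fit_meta", {})))


class AerialDetectionModel:
    """Logistic visibility-vs-DBH model (statsmodels Logit under the hood)."""

    def __init__(self, dbh, visible):
        self.dbh = np.asarray(dbh, dtype=float)
        self.visible = np.asarray(visible, dtype=float)
        if self.dbh.shape != self.visible.shape:
            raise ValueError("dbh and visible must have equal length")
        n1 = int(self.visible.sum())
        if n1 < 2 or (self.visible.size - n1) < 2:
            raise ValueError(
                "need >= 2 visible and >= 2 hidden trees to fit the detection model"
            )

    def fit(self) -> DetectionResults:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        X = sm.add_constant(self.dbh)
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(self.visible, X).fit(disp=0)
        except (PerfectSeparationWarning, Exception) as exc:
            if "separation" not in str(exc).lower() and not isinstance(
                exc, PerfectSeparationWarning
            ):
                raise
            raise SeparationError(
                "perfect separation between visible and hidden trees; "
                "the MLE diverges — consider a penalized (ridge/Firth) fit"
            ) from exc
        if not np.all(np.isfinite(res.bse)):
            raise SeparationError(
                "quasi-separation: infinite standard errors; consider a penalized fit"
            )
        null = sm.Logit(self.visible, np.ones_like(self.visible)[:, None]).fit(disp=0)
        lr = 2.0 * (res.llf - null.llf)
        meta = {
            "loglik": float(res.llf),
            "loglik_null": float(null.llf),
            "lr_stat": float(lr),
            "lr_pvalue": float(stats.chi2.sf(lr, df=1)),
            "se_beta0": float(res.bse[0]),
            "se_beta1": float(res.bse[1]),
            "n": int(self.visible.size),
        }
        return DetectionResults(float(res.params[0]), float(res.params[1]), meta)


def fit_detection_glm(trees) -> DetectionResults:
    """Fit the visibility GLM from labeled :class:`~fruitscape.io.TreeRecord`s."""
    labeled = [t for t in trees if t.visible_aerial is not None and t.dbh is not None]
    if not labeled:
        raise ValueError("no records carry both a DBH and a visibility label")
    dbh = np.array([t.dbh for t in labeled])
    vis = np.array([t.visible_aerial for t in labeled], dtype=float)
    return AerialDetectionModel(dbh, vis).fit()


def detection_probability(model: DetectionResults, dbh) -> np.ndarray:
    """Convenience alias for ``model.predict(dbh)``."""
    return model.predict(dbh)


def calibrate_detection(
    target_fraction: float,
    dbh_sample,
    beta1: float,
    dbh_threshold: float | None = 200.0,
    tol: float = 1e-8,
) -> DetectionResults:
    """Solve for beta0 so the mean detection probability over *dbh_sample*
    equals *target_fraction*.

    By default only stems above ``dbh_threshold`` (200 mm) enter the average,
    matching how overall visibility fractions are reported for canopy-sized
    trees.  The root is bracketed in beta0 in [-50, 50] and solved to *tol*
    on the fraction.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    d = np.asarray(dbh_sample, dtype=float)
    if dbh_threshold is not None:
        d = d[d > dbh_threshold]
    if d.size == 0:
        raise ValueError("dbh_sample empty (after thresholding)")

    def gap(b0: float) -> float:
        return float(special.expit(b0 + beta1 * d).mean() - target_fraction)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("no beta0 in [-50, 50] attains the target fraction")
    b0 = optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16)
    # polish until within tol on the fraction (brentq is already far tighter)
    if abs(gap(b0)) > tol:
        raise RuntimeError("calibration did not reach the requested tolerance")
    meta = {"calibrated": True, "target_fraction": target_fraction,
            "dbh_threshold": dbh_threshold, "n_sample": int(d.size)}
    return DetectionResults(float(b0), float(beta1), meta)
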