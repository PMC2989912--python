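"""Data model, delimited-text readers/writers and run configuration.

Census and trap data travel as plain CSV with fixed headers; the season
clock counts days since the July 1 that opens the season (day 0 = July 1),
so the fruiting peak of a Neotropical dry-season fruiter falls near day 209
(late January).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .window import SpatialWindow

__all__ = [
    "TreeRecord",
    "PhenologyRecord",
    "PointPattern",
    "RunConfig",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "read_tree_table",
    "write_tree_table",
    "read_phenology_table",
    "write_phenology_table",
    "load_config",
    "BCI_DEFAULTS",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Rows violate a domain invariant; message lists offending rows."""


class ConfigError(ValueError):
    """Invalid configuration value."""


SEASON_LENGTH_DAYS = 365.0

#: Fitted parameter set for Dipteryx oleifera on Barro Colorado Island, used
#: as defaults whenever a config does not override them.  Units: c2 per mm
#: DBH; c3, sd_w, sd_z, sigma_resid in days since July 1; sigma_kernel in m.
BCI_DEFAULTS: dict[str, float] = {
    "c1": -0.12,          # log fruits/season intercept (model I)
    "c2": 1.50e-3,        # log fruits/season per mm DBH (model I)
    "sd_u": 0.49,         # between-tree SD, log scale (model I)
    "sd_v": 0.87,         # between-season SD, log scale (model I)
    "c3": 209.3,          # mean fruit-fall date, days since July 1 (model II)
    "sd_w": 13.31,        # between-tree SD of the peak date, days (model II)
    "sd_z": 8.51,         # between-season SD of the peak date, days (model II)
    "sigma_resid": 19.62, # within tree-season SD of fall dates, days (model II)
    "sigma_kernel": 172.0,  # Gaussian kernel bandwidth for the density covariate, m
    "detect_fraction": 0.147,  # overall aerial visibility among DBH > 200 mm stems
    "detect_slope": 0.003,     # logistic detectability slope, log-odds per mm DBH
}


@dataclass(frozen=True)
class TreeRecord:
    """A mapped stem: position (m), DBH (mm) and optional aerial visibility."""

    tree_id: str
    x: Optional[float] = None
    y: Optional[float] = None
    dbh: Optional[float] = None
    visible_aerial: Optional[bool] = None
    source: str = "plot50"

    def __post_init__(self):
        if self.dbh is not None and not self.dbh > 0:
            raise ValidationError(f"tree {self.tree_id}: dbh must be > 0, got {self.dbh}")


@dataclass(frozen=True)
class PhenologyRecord:
    """One trap visit for one tree: fruits counted `count` on season day `day`."""

    tree_id: str
    season_id: str
    day: float      # days since the July 1 opening the season, in [0, 365]
    count: int      # fruits trapped at that visit, >= 0

    def __post_init__(self):
        if not (0.0 <= self.day <= SEASON_LENGTH_DAYS):
            raise ValidationError(
                f"tree {self.tree_id} season {self.season_id}: day {self.day} outside [0, 365]"
            )
        if self.count < 0 or int(self.count) != self.count:
            raise ValidationError(
                f"tree {self.tree_id} season {self.season_id}: count must be a non-negative integer"
            )


@dataclass(frozen=True)
class PointPattern:
    """Point locations observed in a window."""

    x: np.ndarray
    y: np.ndarray
    window: SpatialWindow

    def __post_init__(self):
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.size and not self.window.contains(x, y).all():
            bad = np.nonzero(~self.window.contains(x, y))[0]
            raise ValidationError(f"points outside window at indices {bad.tolist()[:10]}")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @classmethod
    def from_trees(cls, trees: Sequence[TreeRecord], window: SpatialWindow) -> "PointPattern":
        placed = [t for t in trees if t.x is not None and t.y is not None]
        return cls(
            np.array([t.x for t in placed], dtype=float),
            np.array([t.y for t in placed], dtype=float),
            window,
        )


@dataclass
class RunConfig:
    """Pipeline configuration with the BCI parameter set as defaults."""

    rng_seed: int = 0
    grid_cell: float = 25.0                      # m, density-surface resolution
    sigma_grid: list = field(default_factory=lambda: [50.0, 100.0, 150.0, 200.0, 300.0, 400.0])
    n_envelope_sims: int = 100
    n_bootstrap: int = 1000
    bci_defaults: dict = field(default_factory=lambda: dict(BCI_DEFAULTS))

    def __post_init__(self):
        for key in ("sd_u", "sd_v", "sd_w", "sd_z", "sigma_resid", "sigma_kernel"):
            if self.bci_defaults.get(key, 0.0) < 0:
                raise ConfigError(f"parameter {key} must be >= 0, got {self.bci_defaults[key]}")
        frac = self.bci_defaults.get("detect_fraction", 0.147)
        if not (0.0 < frac < 1.0):
            raise ConfigError(f"detect_fraction must be in (0, 1), got {frac}")
        if any(s <= 0 for s in self.sigma_grid):
            raise ConfigError("all sigma_grid values must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TREE_COLUMNS = ("id", "x", "y", "dbh")


def read_tree_table(path, window: Optional[SpatialWindow] = None, source: str = "plot50") -> list[TreeRecord]:
    """Read a tree census CSV (columns ``id,x,y,dbh[,visible]``).

    Positions are validated against *window* when one is given; malformed rows
    raise :class:`ValidationError` naming the offending line numbers (header is
    line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TREE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    errors: list[str] = []
    records: list[TreeRecord] = []
    has_vis = "visible" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        x = None if pd.isna(row.x) else float(row.x)
        y = None if pd.isna(row.y) else float(row.y)
        dbh = None if pd.isna(row.dbh) else float(row.dbh)
        vis = None
        if has_vis:
            v = getattr(row, "visible")
            vis = None if pd.isna(v) else bool(int(v))
        if dbh is not None and dbh <= 0:
            errors.append(f"line {line}: dbh = {dbh} (must be > 0)")
            continue
        if window is not None and x is not None and y is not None:
            if not bool(window.contains(x, y)):
                errors.append(f"line {line}: point ({x}, {y}) outside window")
                continue
        records.append(TreeRecord(str(row.id), x, y, dbh, vis, source=source))
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def write_tree_table(path, trees: Iterable[TreeRecord]) -> None:
    rows = []
    for t in trees:
        rows.append(
            {
                "id": t.tree_id,
                "x": t.x,
                "y": t.y,
                "dbh": t.dbh,
                "visible": None if t.visible_aerial is None else int(t.visible_aerial),
            }
        )
    pd.DataFrame(rows, columns=["id", "x", "y", "dbh", "visible"]).to_csv(path, index=False)


def read_phenology_table(path) -> list[PhenologyRecord]:
    """Read trap records (columns ``tree_id,season_id,day,count``); ``day`` is
    days since the July 1 opening the season."""
    df = pd.read_csv(path)
    required = ("tree_id", "season_id", "day", "count")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    errors, records = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            records.append(
                PhenologyRecord(str(row.tree_id), str(row.season_id), float(row.day), int(row.count))
            )
        except ValidationError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def write_phenology_table(path, records: Iterable[PhenologyRecord]) -> None:
    pd.DataFrame(
        [{"tree_id": r.tree_id, "season_id": r.season_id, "day": r.day, "count": r.count} for r in records],
        columns=["tree_id", "season_id", "day", "count"],
    ).to_csv(path, index=False)


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML/JSON config; absent fields fall back to the BCI defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if text.lstrip().startswith("{") else yaml.safe_load(text)) or {}
    if overrides:
        data = {**data, **overrides}
    params = dict(BCI_DEFAULTS)
    params.update(data.pop("parameters", {}) or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(bci_defaults=params, **data)
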