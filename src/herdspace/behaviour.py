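"""Location time budgets: minute-averaged positions, zone allocation, daily
budgets and bootstrap confidence intervals per trial group.

Raw ~0.11 Hz fixes are averaged to one coordinate per cow-minute, each minute
is allocated to a named axis-aligned pen zone (half-open rectangles; anything
unmatched is "other"), and per-cow-day hours per zone are summarised per
group with percentile bootstrap CIs (within-cow or all-rows resampling).
Zone dwell time is reported, not behaviour: a minute in the cubicle zone is
lying-area time, not verified lying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError

OUT_OF_PEN = "out_of_pen"
OTHER = "other"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ConfigurationError(f"degenerate rectangle {self}")

    def contains(self, x, y):
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    @property
    def area(self):
        return (self.x1 - self.x0) * (self.y1 - self.y0)


class ZoneMap:
    """Named zone rectangles per pen plus the pen bounding boxes.

    ``zones[pen][zone] -> list[Rect]``; points inside the pen but in no named
    rectangle map to "other", points outside the pen bounding box to
    "out_of_pen".
    """

    def __init__(self, zones: dict, bounds: dict):
        self.zones = {pen: {z: [Rect(*r) if not isinstance(r, Rect) else r
                                for r in rects]
                            for z, rects in zmap.items()}
                      for pen, zmap in zones.items()}
        self.bounds = {pen: Rect(*b) if not isinstance(b, Rect) else b
                       for pen, b in bounds.items()}

    def rectangles(self, zone: str, pen: str) -> list:
        if zone == OTHER:
            return []
        return self.zones.get(pen, {}).get(zone, [])

    def zone_names(self, pen: str) -> list:
        names = list(self.zones[pen])
        if OTHER not in names:
            names.append(OTHER)
        return names

    def assign(self, x, y, pen: str) -> np.ndarray:
        """Vectorised zone assignment; first matching zone wins (zones are
        non-overlapping by construction)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, OTHER, dtype=object)
        inside = self.bounds[pen].contains(x, y)
        out[~inside] = OUT_OF_PEN
        for zone, rects in self.zones[pen].items():
            for rect in rects:
                hit = inside & rect.contains(x, y) & (out == OTHER)
                out[hit] = zone
        return out

    def sample_points(self, zone: str, pen: str, n: int,
                      rng: np.random.Generator, inset: float = 0.0):
        """Uniform points within a zone's rectangles (area-weighted), shrunk
        by ``inset`` metres per side where geometry allows."""
        if zone == OTHER:
            rects = self._other_free_space(pen)
        else:
            rects = self.zones[pen][zone]
        areas = np.array([r.area for r in rects], dtype=float)
        pick = rng.choice(len(rects), size=n, p=areas / areas.sum())
        x = np.empty(n)
        y = np.empty(n)
        for i, rect in enumerate(rects):
            m = pick == i
            dx = min(inset, (rect.x1 - rect.x0) / 4)
            dy = min(inset, (rect.y1 - rect.y0) / 4)
            x[m] = rng.uniform(rect.x0 + dx, rect.x1 - dx, int(m.sum()))
            y[m] = rng.uniform(rect.y0 + dy, rect.y1 - dy, int(m.sum()))
        return x, y

    def _other_free_space(self, pen: str) -> list:
        """Crude free-space rectangles for "other": the pen interior strip
        between named zones (the default layouts keep a clear central strip)."""
        if OTHER in self.zones[pen]:
            return self.zones[pen][OTHER]
        raise ConfigurationError(
            f'pen {pen!r} has no explicit "other" rectangles to sample from')

    @classmethod
    def from_dict(cls, data: dict) -> "ZoneMap":
        return cls(zones={pen: {z: [tuple(r) for r in rects]
                                for z, rects in d["zones"].items()}
                          for pen, d in data.items()},
                   bounds={pen: tuple(d["bounds"])
                           for pen, d in data.items()})

    @classmethod
    def from_yaml(cls, path) -> "ZoneMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {pen: {"bounds": [self.bounds[pen].x0, self.bounds[pen].y0,
                                 self.bounds[pen].x1, self.bounds[pen].y1],
                      "zones": {z: [[r.x0, r.y0, r.x1, r.y1] for r in rects]
                                for z, rects in zmap.items()}}
                for pen, zmap in self.zones.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def default_zonemap() -> ZoneMap:
    """Synthetic but schema-complete pen geometry for both pens.

    33 m x 15 m pens; feed face (32.4 m) along the bottom, a cubicle block
    along the top, robot/water/brush boxes on the right, an explicit central
    "other" passageway strip, and a loafing area only in the high-space pen.
    """
    def pen(with_loafing: bool) -> dict:
        zones = {
            "feed_face": [(0.0, 0.0, 32.4, 2.0)],
            "cubicles": [(0.0, 10.0, 28.0, 15.0)],
            "robot": [(28.5, 10.0, 33.0, 13.0)],
            "water": [(28.5, 8.0, 30.4, 9.0), (28.5, 6.5, 30.4, 7.5)],
            "brush": [(31.0, 6.5, 33.0, 8.5)],
            "other": [(0.0, 2.0, 28.0, 10.0)] if not with_loafing
            else [(0.0, 2.0, 22.0, 10.0)],
        }
        if with_loafing:
            zones["loafing"] = [(22.0, 2.0, 28.0, 10.0)]
        return {"bounds": (0.0, 0.0, 33.0, 15.0), "zones": zones}

    return ZoneMap.from_dict({"high": pen(True), "control": pen(False)})


def assign_zone(point: tuple, zonemap: ZoneMap, pen: str) -> str:
    """Zone name for a single point (min edge inclusive, max edge exclusive)."""
    return str(zonemap.assign(point[0], point[1], pen)[0])


def minute_average_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Mean coordinate per cow per wall-clock minute (floor to minute).

    Minutes with no fix simply have no row (missing).  Input needs
    cow_lactation_id, t_s (seconds), x_m, y_m.
    """
    df = fixes[["cow_lactation_id", "t_s", "x_m", "y_m"]].copy()
    df["minute"] = (df["t_s"] // 60).astype(np.int64)
    out = (df.groupby(["cow_lactation_id", "minute"], sort=True)
           [["x_m", "y_m"]].mean().reset_index())
    return out


def compute_daily_budgets(minutes: pd.DataFrame, zonemap: ZoneMap,
                          pens: pd.DataFrame | dict,
                          coverage_threshold: float = 0.8) -> pd.DataFrame:
    """Per-cow-day hours in each zone plus the coverage fraction.

    ``pens`` maps cow_lactation_id to its pen (dict or roster frame with
    group column).  Cow-days with coverage below the threshold are dropped.
    Zone-hours per cow-day always sum to observed minutes / 60.
    """
    if isinstance(pens, pd.DataFrame):
        pens = dict(zip(pens["cow_lactation_id"], pens["group"]))
    parts = []
    for cow, sub in minutes.groupby("cow_lactation_id", sort=True):
        pen = pens[cow]
        zones = zonemap.assign(sub["x_m"].to_numpy(), sub["y_m"].to_numpy(),
                               pen)
        day = (sub["minute"] // 1440).astype(int)
        tab = (pd.DataFrame({"day": day, "zone": zones})
               .groupby(["day", "zone"], sort=True).size()
               .unstack(fill_value=0))
        for z in zonemap.zone_names(pen):
            if z not in tab:
                tab[z] = 0
        hours = tab / 60.0
        hours["coverage"] = tab.sum(axis=1) / 1440.0
        hours.insert(0, "cow_lactation_id", cow)
        hours.insert(1, "group", pen)
        parts.append(hours.reset_index())
    budgets = pd.concat(parts, ignore_index=True).fillna(0.0)
    return budgets.loc[budgets["coverage"] >= coverage_threshold].reset_index(
        drop=True)


@dataclass(frozen=True)
class BootstrapCI:
    zone: str
    group: str
    mean: float
    lower: float
    upper: float
    method: str
    n_reps: int


def bootstrap_budget_ci(budgets: pd.DataFrame, group: str, zones,
                        method: str = "within_cow", n_reps: int = 500,
                        seed: int | np.random.Generator = 0,
                        alpha: float = 0.05) -> list[BootstrapCI]:
    """Percentile bootstrap CIs of the group-mean hours per zone.

    method "within_cow": resample each cow's cow-days with replacement (every
    cow stays represented with its own weight); "all_rows": resample cow-days
    from the pooled group table.
    """
    if method not in ("within_cow", "all_rows"):
        raise DomainError(f"unknown bootstrap method {method!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sub = budgets.loc[budgets["group"] == group]
    n = len(sub)
    if n == 0:
        raise DomainError(f"no budget rows for group {group!r}")
    if n == 1:
        warnings.warn("single cow-day: degenerate CI equal to the point value",
                      stacklevel=2)
    values = {z: sub[z].to_numpy(dtype=float) for z in zones}
    if method == "all_rows":
        idx = rng.integers(0, n, size=(n_reps, n))
    else:
        cows = pd.Categorical(sub["cow_lactation_id"])
        idx = np.empty((n_reps, n), dtype=np.int64)
        for code in range(len(cows.categories)):
            pos = np.nonzero(cows.codes == code)[0]
            draws = rng.integers(0, pos.size, size=(n_reps, pos.size))
            idx[:, pos] = pos[draws]
    out = []
    for z in zones:
        reps = values[z][idx].mean(axis=1)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        out.append(BootstrapCI(zone=z, group=group,
                               mean=float(values[z].mean()),
                               lower=float(lo), upper=float(hi),
                               method=method, n_reps=n_reps))
    return out
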