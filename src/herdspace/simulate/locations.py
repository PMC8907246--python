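"""Simulated geolocation fixes from daily zone-occupancy schedules.

Each cow-day's hours per zone are drawn around the group schedule, laid out
as shuffled bouts over the 1440 minutes, and position fixes are emitted at
~9-second intervals inside the scheduled zone's rectangle with Gaussian
positional jitter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..behaviour import ZoneMap
from ..config import BehaviourTruth
from ..errors import ConfigurationError

_BOUT_MINUTES = 40


def _daily_zone_minutes(schedule: dict, lying_sd_hours: float,
                        rng: np.random.Generator) -> dict:
    """Integer minutes per zone summing to 1440; the cubicle (lying) total is
    jittered around its schedule and the remainder rescaled over other zones."""
    lying_target = schedule.get("cubicles", 0.0)
    lying = float(np.clip(rng.normal(lying_target, lying_sd_hours), 4.0, 22.0))
    others = {z: h for z, h in schedule.items() if z != "cubicles"}
    other_total = sum(others.values())
    scale = (24.0 - lying) / other_total if other_total else 0.0
    minutes = {z: int(round(h * scale * 60)) for z, h in others.items()}
    minutes["cubicles"] = 1440 - sum(minutes.values())
    return minutes


def _minute_zone_sequence(minutes: dict, rng: np.random.Generator) -> np.ndarray:
    bouts = []
    for zone, m in minutes.items():
        while m > 0:
            take = min(_BOUT_MINUTES, m)
            bouts.append((zone, take))
            m -= take
    order = rng.permutation(len(bouts))
    seq = []
    for i in order:
        zone, take = bouts[i]
        seq.extend([zone] * take)
    return np.array(seq)


def simulate_locations(roster: pd.DataFrame, zonemap: ZoneMap,
                       truth: BehaviourTruth, rng: np.random.Generator,
                       n_days: int = 5) -> pd.DataFrame:
    """Location fixes for the tracked cow subset.

    Returns a table with cow_lactation_id, t_s (seconds from the start of the
    tracking window), x_m, y_m.  Fix counts per minute are Poisson at the
    configured mean rate; a dropout rate removes whole minutes at random.
    """
    for grp in roster["group"].unique():
        if grp not in truth.schedules:
            raise ConfigurationError(f"no schedule for group {grp!r}")
    rate_per_min = 60.0 / truth.fix_interval_s
    rows = []
    for row in roster.itertuples(index=False):
        schedule = truth.schedules[row.group]
        for zone in schedule:
            if zone != "other" and not zonemap.rectangles(zone, row.group):
                raise ConfigurationError(
                    f"schedule zone {zone!r} missing from zonemap for pen "
                    f"{row.group!r}")
        for day in range(n_days):
            minutes = _daily_zone_minutes(schedule, truth.lying_sd_hours, rng)
            seq = _minute_zone_sequence(minutes, rng)
            counts = rng.poisson(rate_per_min, 1440)
            if truth.dropout_rate > 0:
                counts[rng.random(1440) < truth.dropout_rate] = 0
            total = int(counts.sum())
            if total == 0:
                continue
            minute_idx = np.repeat(np.arange(1440), counts)
            t = (day * 86400 + minute_idx * 60
                 + rng.uniform(0.0, 60.0, total))
            zones = seq[minute_idx]
            x = np.empty(total)
            y = np.empty(total)
            for zone in np.unique(zones):
                mask = zones == zone
                pts = zonemap.sample_points(zone, row.group, int(mask.sum()),
                                            rng, inset=0.6)
                x[mask], y[mask] = pts
            x += rng.normal(0.0, truth.position_sd_m, total)
            y += rng.normal(0.0, truth.position_sd_m, total)
            order = np.argsort(t, kind="stable")
            rows.append(pd.DataFrame({
                "cow_lactation_id": row.cow_lactation_id,
                "t_s": t[order], "x_m": x[order], "y_m": y[order],
            }))
    if not rows:
        return pd.DataFrame(columns=["cow_lactation_id", "t_s", "x_m", "y_m"])
    return pd.concat(rows, ignore_index=True)


def simulate_time_budgets(n_cows: int, n_days: int, schedule: dict,
                          lying_sd_hours: float, rng: np.random.Generator,
                          group: str = "high",
                          between_cow_fraction: float = 0.5) -> pd.DataFrame:
    """Cow-day time budgets drawn directly at the budget level (no fixes).

    Used for bootstrap-calibration studies where the positional layer is
    irrelevant.  ``between_cow_fraction`` splits the total lying-hours
    variance between a stable cow effect and independent day-to-day noise
    (0 makes all cow-days independent draws).
    """
    cow_sd = lying_sd_hours * np.sqrt(between_cow_fraction)
    day_sd = lying_sd_hours * np.sqrt(1.0 - between_cow_fraction)
    others = {z: h for z, h in schedule.items() if z != "cubicles"}
    other_total = sum(others.values())
    rows = []
    for c in range(n_cows):
        cow_eff = rng.normal(0.0, cow_sd)
        for d in range(n_days):
            lying = float(np.clip(
                schedule["cubicles"] + cow_eff + rng.normal(0.0, day_sd),
                4.0, 22.0))
            scale = (24.0 - lying) / other_total if other_total else 0.0
            rec = {"cow_lactation_id": f"B{c:03d}", "day": d, "group": group,
                   "cubicles": lying, "coverage": 1.0}
            rec.update({z: h * scale for z, h in others.items()})
            rows.append(rec)
    return pd.DataFrame(rows)
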