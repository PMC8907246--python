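"""Simulated oestrus, service and conception events.

Services occur on the oestrous-cycle grid after a voluntary waiting period;
each detected heat is served, and each service conceives with a per-group
probability derived from a baseline per-service probability and a group
hazard scale (``p_g = 1 - (1 - p0)^scale``), i.e. discrete-time proportional
hazards on the cycle grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ReproductionTruth


def group_conception_prob(truth: ReproductionTruth, group: str) -> float:
    scale = truth.hazard_scale.get(group, 1.0)
    return 1.0 - (1.0 - truth.base_conception_prob) ** scale


def median_time_to_conception(truth: ReproductionTruth, group: str) -> float:
    """Closed-form median of the generating process (detected services only):
    voluntary wait + (median service number) * mean cycle length."""
    p_eff = group_conception_prob(truth, group) * 1.0
    p_service = truth.detection_sensitivity * p_eff
    k = int(np.ceil(np.log(0.5) / np.log(1.0 - p_service)))
    return truth.voluntary_wait_days + k * truth.cycle_mean


def _cycle_length(truth: ReproductionTruth, rng: np.random.Generator) -> float:
    c = rng.normal(truth.cycle_mean, truth.cycle_sd)
    return float(np.clip(c, truth.cycle_min, truth.cycle_max))


def simulate_reproduction_events(roster: pd.DataFrame,
                                 truth: ReproductionTruth,
                                 rng: np.random.Generator,
                                 max_dim: int = 305,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Services and conception outcomes for cows open at entry.

    Returns (services, conceptions): services has one row per insemination
    (cow_lactation_id, dim, conceived, group); conceptions one row per cow
    with conception_dim (NaN for cows still open at exit — censored
    downstream).
    """
    service_rows, conception_rows = [], []
    for row in roster.itertuples(index=False):
        conception_dim = np.nan
        if not row.pregnant_at_entry:
            p = group_conception_prob(truth, row.group)
            end_dim = min(max_dim, row.entry_dim + row.exit_day - 1)
            heat = truth.voluntary_wait_days + rng.uniform(
                0.0, truth.cycle_mean)
            heat = max(heat, float(row.entry_dim))
            while heat <= end_dim:
                if rng.random() < truth.detection_sensitivity:
                    conceived = rng.random() < p
                    service_rows.append({
                        "cow_lactation_id": row.cow_lactation_id,
                        "dim": int(round(heat)),
                        "conceived": int(conceived),
                        "group": row.group,
                    })
                    if conceived:
                        conception_dim = float(int(round(heat)))
                        break
                heat += _cycle_length(truth, rng)
        conception_rows.append({"cow_lactation_id": row.cow_lactation_id,
                                "group": row.group,
                                "conception_dim": conception_dim})
    services = pd.DataFrame(service_rows,
                            columns=["cow_lactation_id", "dim", "conceived",
                                     "group"])
    return services, pd.DataFrame(conception_rows)


def simulate_tte_exponential(n_per_arm: int, hazard_ratio: float,
                             base_rate: float, censor_time: float,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Continuous-time two-arm survival data with a known hazard ratio.

    Exponential event times at ``base_rate`` (reference arm) and
    ``base_rate * hazard_ratio`` (treated arm), administratively censored.
    Used for proportional-hazards recovery checks.
    """
    rows = []
    for arm, rate in (("control", base_rate),
                      ("high", base_rate * hazard_ratio)):
        t = rng.exponential(1.0 / rate, n_per_arm)
        event = t <= censor_time
        rows.append(pd.DataFrame({
            "group": arm,
            "time": np.where(event, t, censor_time),
            "event": event.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)
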