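"""Simulated daily milk volume, rumination and monthly milk-recording data."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import LactationTruth
from ..lactation import milkbot_predict

#: Fraction of milk-recording samples with a failed (zero) constituent assay.
ZERO_CONSTITUENT_RATE = 40 / 828


def simulate_milk_rumination(roster: pd.DataFrame, truth: LactationTruth,
                             rng: np.random.Generator,
                             max_dim: int = 305) -> pd.DataFrame:
    """One row per cow-day in milk: volume (L) and rumination (min).

    Volume = lactation curve + group fixed effects + cow intercept
    (Normal, configured variance) + residual noise, floored at zero.
    Rumination uses the linear group-by-DIM structure with its own cow
    intercept and noise.
    """
    frames = []
    cow_sd = np.sqrt(truth.cow_variance)
    res_sd = np.sqrt(truth.residual_variance)
    rum_cow_sd = np.sqrt(truth.rumination_cow_variance)
    rum_res_sd = np.sqrt(truth.rumination_residual_variance)
    for row in roster.itertuples(index=False):
        last_dim = min(max_dim, row.entry_dim + row.exit_day - 1)
        dims = np.arange(row.entry_dim, last_dim + 1)
        if dims.size == 0:
            continue
        cow_int = rng.normal(0.0, cow_sd)
        rum_int = rng.normal(0.0, rum_cow_sd)
        vol = (milkbot_predict(truth.milkbot, dims)
               + truth.fixed.predict(row.parity_group, dims)
               + cow_int + rng.normal(0.0, res_sd, dims.size))
        rum = (truth.rumination_fixed.predict(row.parity_group, dims)
               + rum_int + rng.normal(0.0, rum_res_sd, dims.size))
        frames.append(pd.DataFrame({
            "cow_lactation_id": row.cow_lactation_id,
            "dim": dims,
            "volume_l": np.maximum(vol, 0.0),
            "rumination_min": np.maximum(rum, 0.0),
            "parity_group": row.parity_group,
            "group": row.group,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_milk_recording(milk: pd.DataFrame, rng: np.random.Generator,
                            interval_days: int = 30,
                            zero_rate: float = ZERO_CONSTITUENT_RATE,
                            ) -> pd.DataFrame:
    """Monthly milk-recording constituent percentages per cow.

    Samples every ~30 days of each cow's daily series; fat/protein
    percentages drawn around breed-typical means, with a small fraction of
    failed assays recorded as fat = protein = 0.
    """
    rows = []
    for cow, sub in milk.groupby("cow_lactation_id", sort=True):
        sub = sub.sort_values("dim")
        start = int(rng.integers(5, interval_days + 5))
        picks = sub[(sub["dim"] - sub["dim"].iloc[0] - start)
                    % interval_days == 0] if len(sub) else sub
        if picks.empty:
            picks = sub.iloc[:1]
        for r in picks.itertuples(index=False):
            failed = rng.random() < zero_rate
            fat = 0.0 if failed else max(0.5, rng.normal(4.1, 0.45))
            prot = 0.0 if failed else max(0.5, rng.normal(3.35, 0.22))
            rows.append({"cow_lactation_id": cow, "dim": int(r.dim),
                         "fat_pct": round(fat, 2), "protein_pct": round(prot, 2),
                         "volume_l": r.volume_l, "group": r.group})
    return pd.DataFrame(rows)
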