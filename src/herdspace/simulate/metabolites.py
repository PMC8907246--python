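"""Simulated transition-cow BHB/NEFA blood panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import MetaboliteTruth
from ..reproduction import BHB_HIGH, NEFA_HIGH

#: Sampling windows (days after parturition): panels 1-3.
WINDOWS = ((7, 14), (15, 21), (22, 28))


def _draw(median, sigma, threshold, high_prevalence, n,
          rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws forming a mixture: below-threshold body with
    probability 1 - prevalence, at-or-above-threshold tail otherwise."""
    base = median * np.exp(rng.normal(0.0, sigma, n))
    high = rng.random(n) < high_prevalence
    values = np.where(high,
                      np.maximum(base, threshold) * rng.uniform(1.0, 1.6, n),
                      np.minimum(base, threshold * 0.99))
    return np.round(values, 3)


def simulate_metabolites(roster: pd.DataFrame, truth: MetaboliteTruth,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Three BHB/NEFA panels per cow at the post-parturition windows."""
    rows = []
    for row in roster.itertuples(index=False):
        for w, (lo, hi) in enumerate(WINDOWS, start=1):
            day = int(rng.integers(lo, hi + 1))
            rows.append({"cow_lactation_id": row.cow_lactation_id,
                         "group": row.group, "window": w, "day_pp": day})
    panel = pd.DataFrame(rows)
    n = len(panel)
    panel["bhb_mmol_l"] = _draw(truth.bhb_median, truth.bhb_sigma, BHB_HIGH,
                                truth.bhb_high_prevalence, n, rng)
    panel["nefa_mmol_l"] = _draw(truth.nefa_median, truth.nefa_sigma,
                                 NEFA_HIGH, truth.nefa_high_prevalence, n, rng)
    return panel
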