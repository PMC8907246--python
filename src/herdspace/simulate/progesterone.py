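"""Simulated milk-progesterone trajectories with known profile classes.

Each cow gets a piecewise luteal template drawn for its assigned class
(Normal, DOV, or an Abnormal subtype), sampled on the thrice-weekly
collection schedule between 14 and 84 days in milk, with multiplicative
lognormal assay noise calibrated to the stated coefficient of variation and
truncation at the top of the assay standard range.

Template durations leave a margin over the classification thresholds so the
class is identifiable from the thrice-weekly samples: the longest gap in the
weekly sampling pattern is 4 days, so a sampled run can appear up to ~8 days
shorter than the underlying phase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ProgesteroneTruth

#: Weekly sampling pattern: Monday day, Wednesday day, Thursday evening.
SAMPLE_WEEKDAYS = (0, 2, 3)


def sample_days(first_dim: int, last_dim: int, offset: int) -> np.ndarray:
    """Collection DIMs for a cow whose calving fell ``offset`` days before a
    Monday."""
    days = np.arange(first_dim, last_dim + 1)
    return days[np.isin((days + offset) % 7, SAMPLE_WEEKDAYS)]


def _luteal_intervals(profile_class: str, subtype: str | None,
                      truth: ProgesteroneTruth, rng: np.random.Generator,
                      ) -> list[tuple[float, float]]:
    """True luteal phases as (start_day, end_day) out to the last sample day.

    Normal cycling uses luteal phases of 18.5-20.5 d with 4.6-6.0 d
    inter-luteal lows (cycle length 23-26 d, inside the normal 18-26 d
    range): a sampled luteal run then always spans > 10 d but never
    > 21 d, and every low window contains at least one sample (4
    consecutive days always include a collection day) so adjacent
    cycles can never merge into an apparent prolonged phase.
    """
    end = float(truth.last_dim)

    def normal_cycles(start):
        phases = []
        t = start
        while t < end:
            lut = rng.uniform(18.5, 20.5)
            phases.append((t, min(t + lut, end + 5)))
            t += lut + rng.uniform(4.6, 6.0)
        return phases

    if profile_class == "Normal":
        return normal_cycles(rng.uniform(20.0, 38.0))
    if profile_class == "DOV":
        return normal_cycles(rng.uniform(50.0, 70.0))
    rise = rng.uniform(22.0, 34.0)
    if subtype == "cessation":
        first_end = rise + rng.uniform(18.5, 20.5)
        resume = first_end + rng.uniform(22.0, 26.0)   # low gap > 12 d sampled
        return [(rise, first_end)] + normal_cycles(resume)
    if subtype == "prolonged_luteal":
        # > 31 d true length so the sampled span always exceeds 21 d
        pl_end = rise + rng.uniform(31.0, 38.0)
        return [(rise, pl_end)] + normal_cycles(pl_end + rng.uniform(4.6, 6.0))
    if subtype == "short_luteal":
        first_end = rise + rng.uniform(18.5, 20.5)
        short_start = first_end + rng.uniform(4.6, 6.0)
        short_end = short_start + rng.uniform(5.0, 8.0)
        return [(rise, first_end), (short_start, short_end)] + normal_cycles(
            short_end + rng.uniform(4.6, 6.0))
    raise ValueError(f"unknown profile class {profile_class}/{subtype}")


def simulate_progesterone(roster: pd.DataFrame, truth: ProgesteroneTruth,
                          rng: np.random.Generator, noise: bool = True,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Progesterone series for every cow plus their generating labels.

    Returns ``(samples, labels)``: samples has cow_lactation_id, dim,
    p4_ng_ml; labels has cow_lactation_id, profile_class, subtype.
    """
    classes = list(truth.class_mix)
    class_p = np.array([truth.class_mix[c] for c in classes])
    subtypes = list(truth.subtype_mix)
    sub_p = np.array([truth.subtype_mix[s] for s in subtypes])
    log_sd = float(np.sqrt(np.log1p(truth.assay_cv ** 2)))

    sample_rows, label_rows = [], []
    for row in roster.itertuples(index=False):
        cls = str(rng.choice(classes, p=class_p))
        sub = str(rng.choice(subtypes, p=sub_p)) if cls == "Abnormal" else None
        phases = _luteal_intervals(cls, sub, truth, rng)
        plateau = rng.uniform(truth.plateau_low, truth.plateau_high)
        days = sample_days(truth.first_dim, truth.last_dim,
                           int(rng.integers(0, 7)))
        in_phase = np.zeros(days.size, dtype=bool)
        for s, e in phases:
            in_phase |= (days >= s) & (days <= e)
        values = np.where(in_phase, plateau, truth.baseline_ng_ml)
        if noise:
            values = values * np.exp(rng.normal(0.0, log_sd, days.size)
                                     - log_sd ** 2 / 2)
        values = np.minimum(values, truth.truncation_ng_ml)
        sample_rows.append(pd.DataFrame({
            "cow_lactation_id": row.cow_lactation_id,
            "dim": days, "p4_ng_ml": values,
        }))
        label_rows.append({"cow_lactation_id": row.cow_lactation_id,
                           "group": row.group,
                           "profile_class": cls, "subtype": sub})
    return (pd.concat(sample_rows, ignore_index=True),
            pd.DataFrame(label_rows))
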