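"""Simulated trial roster: matched cow pairs under stratified allocation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import HerdConfig

#: Entry-DIM matching tolerance by parity: +-3 d up to 2nd parity, +-5 d after.
def pairing_tolerance(parity: int) -> int:
    return 3 if parity <= 2 else 5


def simulate_roster(config: HerdConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One matched pair per pair_id: equal parity, entry DIM within tolerance,
    a fair coin assigning which member gets the high-space pen.

    Columns: cow_lactation_id, pair_id, group, parity, parity_group,
    entry_dim, pregnant_at_entry, exit_day.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parities = np.array(sorted(config.parity_mix))
    probs = np.array([config.parity_mix[p] for p in parities])
    rows = []
    for pair in range(config.n_pairs):
        parity = int(rng.choice(parities, p=probs))
        tol = pairing_tolerance(parity)
        base_dim = int(rng.integers(4, config.max_entry_dim + 1))
        partner_dim = int(np.clip(base_dim + rng.integers(-tol, tol + 1),
                                  1, None))
        high_first = bool(rng.integers(0, 2))
        groups = ("high", "control") if high_first else ("control", "high")
        pregnant_pair = rng.random() < config.pregnant_pair_fraction
        pregnant_member = int(rng.integers(0, 2))
        # pair exits when the first member reaches dry-off (~305 DIM)
        dry_noise = int(rng.integers(-14, 15))
        for member, (grp, edim) in enumerate(zip(groups,
                                                 (base_dim, partner_dim))):
            exit_day = int(min(config.trial_days,
                               max(1, 305 - edim + dry_noise)))
            rows.append({
                "cow_lactation_id": f"P{pair:03d}{'H' if grp == 'high' else 'C'}",
                "pair_id": pair,
                "group": grp,
                "parity": parity,
                "parity_group": ("primiparous-" if parity == 1
                                 else "multiparous-") + grp,
                "entry_dim": edim,
                "pregnant_at_entry": bool(pregnant_pair
                                          and member == pregnant_member),
                "exit_day": exit_day,
            })
    return pd.DataFrame(rows)
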