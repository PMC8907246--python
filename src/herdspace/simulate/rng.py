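"""Seeded RNG streams, one independent child stream per generator.

Each generator draws from its own SeedSequence child so that adding or
re-running one generator never perturbs another's draws.
"""

from __future__ import annotations

import numpy as np

STREAMS = ("roster", "milk", "recording", "reproduction", "progesterone",
           "locations", "metabolites", "blinding")


def child_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, mutually independent Generators derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(STREAMS, children)}
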