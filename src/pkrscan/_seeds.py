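"""Deterministic fan-out of one master seed into per-module child seeds.

One CLI-level seed reproduces a whole run: children are drawn from the
master's ``numpy.random.SeedSequence`` state and kept below 2**31 so they
stay valid seeds for any downstream generator.
"""

from __future__ import annotations

import numpy as np


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (each in [0, 2**31)) from one master."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s >> 1) for s in state]
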