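"""Named random streams derived from one master seed.

Every source of randomness (neural noise, task events, genetic operators)
gets its own independent generator so that changing one consumer never
perturbs the others.
"""

from __future__ import annotations

import numpy as np

DEFAULT_NAMES = ("noise", "task", "ga")


def named_streams(seed: int, names: tuple[str, ...] = DEFAULT_NAMES) -> dict[str, np.random.Generator]:
    """Split ``seed`` into one independent PCG64 stream per name."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}
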