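"""Named random substreams derived from a single root seed.

Every stochastic stage (connectome geometry, frequency schedule, initial
phases, permutation tests, ...) draws from its own child generator so that
changing one stage's consumption pattern does not perturb the others.
"""

from __future__ import annotations

import numpy as np

# Fixed, order-independent tags for the package's named substreams.
_STREAM_TAGS = {
    "connectome": 1,
    "schedule": 2,
    "init_phases": 3,
    "permutations": 4,
    "analysis": 5,
}


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return the deterministic child generator for a named stage."""
    try:
        tag = _STREAM_TAGS[name]
    except KeyError:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAM_TAGS)}")
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(tag,))
    return np.random.Generator(np.random.PCG64(ss))


def child_seed(root_seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(substream(root_seed, name).integers(0, 2**31 - 1))
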