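"""Named, independent random substreams.

The model distinguishes two seed roles: a *connectivity* seed that controls
network construction (soma placement and wiring) and an *input* seed that
controls the stochastic long-range drive.  Each role is split into named
substreams so that, e.g., soma placement and connection sampling are
statistically independent even when derived from the same connectivity seed.
"""

from __future__ import annotations

import numpy as np

# Stable integer tags for the named substreams.  Geometry is folded into the
# connectivity seed role; inputs use their own role.
_STREAMS = {
    "geometry": 0x67656F,  # soma placement
    "wiring": 0x776972,  # local connection sampling
    "border": 0x626F72,  # Monte-Carlo border correction
    "placement": 0x706C61,  # synapse placement on dendrites
    "longrange": 0x6C7267,  # long-range unit-to-target assignment
    "rates": 0x726174,  # per-unit rate draws
    "trains": 0x747261,  # Poisson spike trains
    "analysis": 0x616E61,  # subsampling / embeddings
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Streams with different names are independent; the same (seed, name)
    pair always yields an identical stream.
    """
    try:
        tag = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown random substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))


def child_seed(seed: int, name: str, index: int = 0) -> int:
    """A deterministic 31-bit integer seed derived from (seed, name, index)."""
    rng = substream(seed, name)
    if index:
        vals = rng.integers(0, 2**31 - 1, size=index + 1)
        return int(vals[index])
    return int(rng.integers(0, 2**31 - 1))
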