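"""Deterministic seeding: one base seed spawns independent named substreams.

Every stochastic operation in the package takes an integer seed and is a pure
function of (inputs, seed).  Experiments derive all their seeds from a single
base seed through :func:`substream_seed`, so reruns are bit-for-bit
reproducible and substreams are statistically independent of each other.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

# Registry of named substreams.  The integer codes are part of the on-disk
# provenance contract: changing them changes every derived seed.
STREAMS = {
    "trajectory": 0,
    "tuning": 1,
    "spikes-train": 2,
    "spikes-fusion": 3,
    "spikes-validation": 4,
    "spikes-test": 5,
    "ann-init": 6,
    "trajectory-train": 7,
    "trajectory-fusion": 8,
    "trajectory-validation": 9,
    "trajectory-test": 10,
    "pseudo-decoder": 11,
    "generic": 12,
}


def substream_seed(base_seed: int, name: str, index: int = 0) -> int:
    """Derive a 64-bit integer seed for the named substream.

    ``index`` distinguishes repeated uses of the same stream (e.g. one test
    trajectory per trial).
    """
    if name not in STREAMS:
        raise ParameterError(f"unknown substream name {name!r}; known: {sorted(STREAMS)}")
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(STREAMS[name], index))
    return int(ss.generate_state(2, dtype=np.uint32).view(np.uint64)[0])


def substream_rng(base_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """A ``numpy.random.Generator`` for the named substream."""
    return np.random.default_rng(substream_seed(base_seed, name, index))
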