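"""Deterministic random-number stream splitting.

Every stochastic stage of the pipeline receives its own independent stream
derived from one user-supplied run seed via a counter-based splitting scheme
(numpy ``SeedSequence`` spawn keys), so re-running a single stage reproduces
its piece of a full run bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "stage_key"]


def stage_key(name: str) -> int:
    """Stable 32-bit key for a named pipeline stage."""
    return zlib.crc32(name.encode("utf-8"))


def spawn_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for ``seed`` split by the given stage keys.

    String keys are hashed with :func:`stage_key`; integer keys are used
    as-is. The same (seed, keys) pair always yields the same stream, and
    distinct key tuples yield statistically independent streams.
    """
    spawn_key = tuple(
        stage_key(k) if isinstance(k, str) else int(k) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    return np.random.default_rng(ss)
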