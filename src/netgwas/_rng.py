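"""Deterministic seed derivation.

All randomness in the package flows from one integer master seed.  Sub-streams
(per pipeline stage, per gene) are derived by hashing string tokens into a
``numpy.random.SeedSequence`` spawn key, so adding draws to one consumer never
shifts another consumer's stream, and serial and parallel runs agree.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_int_seed"]


def _token_key(token: str) -> int:
    # crc32 is stable across platforms and Python versions (unlike hash()).
    return zlib.crc32(token.encode("utf-8"))


def substream(master_seed: int, *tokens: str) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``tokens``."""
    key = tuple(_token_key(t) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))


def derive_int_seed(master_seed: int, *tokens: str) -> int:
    """A plain integer seed (< 2**31) derived from the master seed and tokens."""
    key = tuple(_token_key(t) for t in tokens)
    ss = np.random.SeedSequence(int(master_seed), spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
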