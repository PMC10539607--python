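"""Named random substreams derived from a single integer seed.

Every stage that consumes randomness asks for its own substream by name, so
re-running one stage in isolation reproduces exactly what the full pipeline
would have fed it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the deterministic generator for ``stage`` under ``seed``.

    The stage name is folded in through a CRC32 spawn key, so distinct stage
    names yield statistically independent streams while remaining stable
    across platforms and sessions.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
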