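"""Named-substream seed fan-out.

A single master seed is expanded into independent, reproducible streams keyed
by stage name, so adding a stage to a pipeline never perturbs the randomness
consumed by earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), _tag(name)]))


def subseed(master_seed: int, name: str) -> int:
    """Derive a plain integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence([int(master_seed), _tag(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _tag(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))
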