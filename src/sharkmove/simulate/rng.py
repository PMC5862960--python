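"""Named, independent random streams derived from one user seed.

Each simulator component (movement, duty cycle, Argos, ...) draws from its
own stream so that, e.g., adding a receiver never perturbs the shark's path.
Streams are derived by spawning a ``SeedSequence`` with a stable key hashed
from the component name.
"""

from __future__ import annotations

import zlib

import numpy as np


def component_rng(seed: int, component: str) -> np.random.Generator:
    """A reproducible generator for a named component under ``seed``."""
    key = zlib.crc32(component.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
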