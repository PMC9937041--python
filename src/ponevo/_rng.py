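"""Seed management: one master seed spawns named, independent child streams.

Every stochastic operation in the package derives its generator through
:func:`child_rng`, keyed by a stable operation name, so adding a new
generator never perturbs the stream another operation sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _name_key(name: str) -> int:
    # CRC32 is stable across platforms and Python versions.
    return zlib.crc32(name.encode("utf-8"))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for operation ``name`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed < 2**31, for APIs that want a plain int."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
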