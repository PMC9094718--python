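"""Deterministic random-number stream derivation.

One master seed drives a whole run; every module draws from a sub-stream
derived from (seed, label path), so a single stage can be regenerated in
isolation and parallel/sequential execution orders give identical results.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng", "derive_int_seed"]

_MASK = 0x7FFFFFFF  # keep derived entropy words below 2**31


def _label_word(labels: tuple) -> int:
    return zlib.crc32("/".join(str(x) for x in labels).encode()) & _MASK


def derive_seed_sequence(master_seed: int, *labels) -> np.random.SeedSequence:
    """SeedSequence for the sub-stream identified by ``labels``."""
    return np.random.SeedSequence([int(master_seed) & _MASK, _label_word(labels)])


def derive_rng(master_seed: int, *labels) -> np.random.Generator:
    """Generator for the sub-stream identified by ``labels``."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *labels))


def derive_int_seed(master_seed: int, *labels) -> int:
    """A plain integer seed (< 2**31) for APIs that want one."""
    return int(derive_seed_sequence(master_seed, *labels).generate_state(1)[0] & _MASK)
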