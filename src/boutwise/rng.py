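"""Seed management.

Every run owns a single root seed. Each pipeline stage (or repeated unit
within a stage) derives its own independent stream by hashing a stage name
into a ``numpy`` :class:`~numpy.random.SeedSequence` alongside the root
seed. The scheme is:

    child = SeedSequence([root_seed, blake2s(stage_name)[:4] as uint32])

so stages can be re-run separately, in any order, and still reproduce the
exact streams of a full pipeline run with the same root seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_seed_sequence", "stage_rng"]


def _stage_key(stage: str) -> int:
    digest = hashlib.blake2s(stage.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def stage_seed_sequence(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive the named child seed sequence for *stage* from *root_seed*."""
    return np.random.SeedSequence([int(root_seed), _stage_key(stage)])


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named stage."""
    return np.random.default_rng(stage_seed_sequence(root_seed, stage))
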