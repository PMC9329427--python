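"""Shared helpers: seed derivation and light validation."""

from __future__ import annotations

import numpy as np

# Seeds handed to numpy must stay in [0, 2**31) so they round-trip through
# every container (JSON manifests, CLI flags) without surprises.
_SEED_MOD = 2**31


def child_seed(seed: int, *tags) -> int:
    """Derive a reproducible child seed from a parent seed and a tag path.

    The derivation is a SeedSequence spawn keyed on the hashed tag path, so
    distinct stages of a run consume independent streams while everything
    remains a pure function of the top-level seed.
    """
    key = [int(seed) % _SEED_MOD]
    for t in tags:
        if isinstance(t, str):
            key.extend(b for b in t.encode())
        else:
            key.append(int(t) % _SEED_MOD)
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % _SEED_MOD


def rng_from(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tags))


def as_float_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale raster")
    return img
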