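"""Small shared numerics: RNG spawning and Benjamini-Hochberg correction."""

from __future__ import annotations

import zlib

import numpy as np

MISSING = np.nan


def child_rng(
    seed: "int | np.random.Generator | np.random.SeedSequence | None", key: str
) -> np.random.Generator:
    """Derive a component-isolated Generator from a root seed.

    Each component of the pipeline draws from its own stream so that adding
    draws in one stage does not shift the randomness of another. A Generator
    passed directly is used as-is. The key is hashed with crc32 so streams
    are stable across processes (str hash() is salted per interpreter run).
    """
    if isinstance(seed, np.random.Generator):
        return seed
    spawn_key = (zlib.crc32(key.encode()),)
    if isinstance(seed, np.random.SeedSequence):
        ss = np.random.SeedSequence(
            entropy=seed.entropy,
            spawn_key=tuple(seed.spawn_key) + spawn_key,
        )
    else:
        ss = np.random.SeedSequence(seed, spawn_key=spawn_key)
    return np.random.default_rng(ss)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), NaN-safe.

    NaN entries stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / (np.arange(m) + 1.0)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q
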