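"""Small shared numerical helpers."""

from __future__ import annotations

import functools

import numpy as np

#: sentinel for statistics that are undefined on the given data (e.g. Tajima's D
#: with S = 0).  Propagated explicitly, never silently coerced to 0.
UNDEFINED = float("nan")


@functools.lru_cache(maxsize=None)
def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator for sample size n."""
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    return float(np.sum(1.0 / np.arange(1, n)))


@functools.lru_cache(maxsize=None)
def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


def is_defined(x: float) -> bool:
    return x == x  # NaN-safe


def rng_from(seed, *stream: str) -> np.random.Generator:
    """Derive a named, reproducible substream from a base seed.

    Every stage of a run pulls its randomness from ``rng_from(seed, "stage",
    ...)`` so stages can be re-run independently yet reproducibly.
    """
    ss = np.random.SeedSequence(int(seed) % (2**31), spawn_key=tuple(
        int.from_bytes(s.encode(), "little") % (2**31) for s in stream
    ))
    return np.random.default_rng(ss)
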