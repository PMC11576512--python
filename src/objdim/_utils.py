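"""Small shared helpers: validation, RNG handling, vectorized correlation."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def check_count(name: str, value: int, minimum: int = 1) -> None:
    if int(value) != value or value < minimum:
        raise ValueError(f"{name} must be an integer >= {minimum}, got {value!r}")


def spawn_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; integers are used as seeds, Generators pass through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_seed(seed: int, offset: int) -> int:
    """Derive a stream-specific child seed below 2**31 from a base seed."""
    ss = np.random.SeedSequence([int(seed), int(offset)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % MAX_SEED)


def columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matched columns of two (n, k) arrays.

    Columns with zero variance in either input yield NaN rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matched rows of two (k, n) arrays."""
    return columnwise_pearson(np.asarray(a).T, np.asarray(b).T)


def held_out_r2(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Per-column R^2 of predictions against observations, relative to the
    observed column mean (may be negative)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ss_res = ((obs - pred) ** 2).sum(axis=0)
    ss_tot = ((obs - obs.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot == 0, np.nan, r2)
    return r2
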