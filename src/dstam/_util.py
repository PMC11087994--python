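"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used in reported percentages).

    ``round_half_away(6.25, 1) == 6.3`` whereas banker's rounding gives 6.2.
    """
    if np.isnan(x):
        return float("nan")
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_half_up_int(x: float) -> int:
    """Round a nonnegative quantity half-up to an integer."""
    if x < 0:
        raise ValueError(f"expected a nonnegative value, got {x}")
    return int(math.floor(x + 0.5))


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``.

    Hamilton / largest-remainder apportionment: floors plus one extra unit to
    the cells with the largest fractional parts, so the result sums to
    ``total`` exactly.  Ties go to the lower index for determinism.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be nonnegative")
    if weights.size == 0:
        if total:
            raise ValueError("cannot allocate a positive total to zero cells")
        return np.zeros(0, dtype=np.int64)
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    s = weights.sum()
    if s == 0:
        quota = np.full(weights.shape, total / weights.size)
    else:
        quota = weights * (total / s)
    alloc = np.floor(quota).astype(np.int64)
    short = int(total - alloc.sum())
    if short > 0:
        frac = quota - alloc
        # stable argsort descending on fractional part, index ascending on ties
        order = np.lexsort((np.arange(frac.size), -frac))
        alloc[order[:short]] += 1
    return alloc


def isotonic_rows(values: np.ndarray) -> np.ndarray:
    """Non-decreasing (pool-adjacent-violators) repair along the last axis.

    Equal-weight PAVA applied independently to each row; rows already sorted
    are returned untouched, so the common no-violation case is cheap.
    """
    out = np.array(values, dtype=float, copy=True)
    flat = out.reshape(-1, out.shape[-1])
    bad = np.nonzero((np.diff(flat, axis=1) < 0).any(axis=1))[0]
    for i in bad:
        flat[i] = _pava_1d(flat[i])
    return out


def _pava_1d(y: np.ndarray) -> np.ndarray:
    # classic stack-based PAVA, unit weights
    means: list[float] = []
    counts: list[int] = []
    for v in y:
        means.append(float(v))
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, c2 = means.pop(), counts.pop()
            m1, c1 = means.pop(), counts.pop()
            c = c1 + c2
            means.append((m1 * c1 + m2 * c2) / c)
            counts.append(c)
    return np.repeat(means, counts)
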