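"""Space-filling design of experiments over material-parameter ranges.

Latin hypercube sampling stratifies each parameter range into ``n``
equal-probability bins and draws exactly one sample per bin per dimension;
the pairing of bins across dimensions is then improved by a maximin
hill-climb (random within-column swaps accepted only when they increase
the minimal pairwise distance in the unit cube), which preserves the
one-per-bin marginal property exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = ["ParameterRanges", "DOEPlan", "latin_hypercube", "maximin_optimize"]


class DOEError(ValueError):
    """Invalid DOE configuration."""


@dataclass(frozen=True)
class ParameterRanges:
    """Ordered list of (name, low, high, unit) sampling ranges."""

    names: Tuple[str, ...]
    lows: Tuple[float, ...]
    highs: Tuple[float, ...]
    units: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise DOEError("parameter names must be unique")
        if not (len(self.names) == len(self.lows) == len(self.highs) == len(self.units)):
            raise DOEError("ragged range specification")
        for name, lo, hi in zip(self.names, self.lows, self.highs):
            if not lo < hi:
                raise DOEError(f"range for {name!r} must satisfy low < high")

    @classmethod
    def from_items(
        cls, items: Iterable[Sequence]
    ) -> "ParameterRanges":
        """Build from an iterable of (name, low, high[, unit]) tuples."""
        names, lows, highs, units = [], [], [], []
        for item in items:
            name, lo, hi = item[0], float(item[1]), float(item[2])
            unit = str(item[3]) if len(item) > 3 else ""
            names.append(name)
            lows.append(lo)
            highs.append(hi)
            units.append(unit)
        return cls(tuple(names), tuple(lows), tuple(highs), tuple(units))

    @property
    def n_dims(self) -> int:
        return len(self.names)

    def to_unit(self, samples: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lows)
        hi = np.asarray(self.highs)
        return (np.asarray(samples, dtype=float) - lo) / (hi - lo)

    def from_unit(self, unit: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lows)
        hi = np.asarray(self.highs)
        return lo + np.asarray(unit, dtype=float) * (hi - lo)


@dataclass(frozen=True)
class DOEPlan:
    """A sampling plan in original units, with its seed and quality metric."""

    samples: np.ndarray  # (n_samples, n_dims)
    ranges: ParameterRanges
    seed: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != self.ranges.n_dims:
            raise DOEError("sample matrix shape does not match ranges")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def min_distance(self) -> float:
        """Minimal pairwise Euclidean distance in the unit cube."""
        u = self.ranges.to_unit(self.samples)
        return float(pdist(u).min())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.ranges.names))


def latin_hypercube(n: int, ranges: ParameterRanges, seed: int) -> DOEPlan:
    """Stratified Latin hypercube plan: one sample per bin per dimension.

    Each dimension is cut into ``n`` equal bins; bin order is an independent
    random permutation per dimension and the position within each bin is
    uniform jitter.  Deterministic given ``seed``.
    """
    if n < 2:
        raise DOEError("a Latin hypercube needs n >= 2 samples")
    rng = np.random.default_rng(seed)
    unit = np.empty((n, ranges.n_dims))
    for j in range(ranges.n_dims):
        perm = rng.permutation(n)
        unit[:, j] = (perm + rng.uniform(size=n)) / n
    return DOEPlan(samples=ranges.from_unit(unit), ranges=ranges, seed=seed)


def maximin_optimize(plan: DOEPlan, n_iter: int, seed: int) -> DOEPlan:
    """Improve a plan's maximin distance by within-column swaps.

    Each iteration proposes swapping one column's values between two random
    rows; the swap is kept only if it strictly increases the minimal
    pairwise distance.  Column swaps permute bins within a dimension, so
    the Latin hypercube stratification is invariant.
    """
    if n_iter < 0:
        raise DOEError("n_iter must be >= 0")
    rng = np.random.default_rng(seed)
    unit = plan.ranges.to_unit(plan.samples).copy()
    n = unit.shape[0]
    best = float(pdist(unit).min())
    for _ in range(n_iter):
        j = int(rng.integers(unit.shape[1]))
        i1, i2 = rng.choice(n, size=2, replace=False)
        unit[[i1, i2], j] = unit[[i2, i1], j]
        d = float(pdist(unit).min())
        if d > best:
            best = d
        else:
            unit[[i1, i2], j] = unit[[i2, i1], j]  # revert
    return replace(plan, samples=plan.ranges.from_unit(unit))
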