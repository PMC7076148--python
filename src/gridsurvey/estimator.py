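"""Nonparametric design evaluation: ECDF, weighted ECDF, KS distance.

The estimand is the full distribution of population counts per settled cell.
The population ECDF

    F_m(x) = (1/m) * sum_i I{X_i <= x}

is compared with the design-weighted ECDF of a sample, in which each sampled
cell's indicator is weighted by its design weight W_i = 1/pi_i(SPPS).  Two
weighting modes are provided:

* ``normalized`` (default, Hajek form): jump heights W_i / sum(W), so the
  curve terminates at 1 and Kolmogorov-Smirnov distances live in [0, 1];
* ``as_printed``: jump heights W_i / n — the literal inverse-probability
  form, whose terminal value sum(W)/n generally differs from 1.  It is kept
  so the consequences of the un-normalized weighting are inspectable.

The Kolmogorov-Smirnov distance sup_x |F(x) - G(x)| between two step
functions is computed exactly over the union of their knots (checking each
knot and its left limit), never by grid approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepCDF", "ecdf", "wecdf", "ks_distance"]


@dataclass(frozen=True)
class StepCDF:
    """A right-continuous cumulative step function.

    ``support`` holds the strictly increasing jump locations, ``cum`` the
    function value at (and right of) each knot.  Below the first knot the
    function is 0; at and above the last knot it equals the terminal value
    ``cum[-1]`` (1 for an ECDF or a normalized WECDF).
    """

    support: np.ndarray
    cum: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        cum = np.asarray(self.cum, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "cum", cum)
        if support.ndim != 1 or support.size == 0:
            raise ValueError("support must be a non-empty 1-D array")
        if support.size != cum.size:
            raise ValueError("support and cum must have equal length")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(np.diff(cum) < -1e-12):
            raise ValueError("cumulative values must be non-decreasing")
        if cum[0] <= 0:
            raise ValueError("first jump must be positive")

    @property
    def terminal(self) -> float:
        return float(self.cum[-1])

    def __call__(self, x) -> np.ndarray:
        """Evaluate the step function (right-continuous)."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cum])
        return padded[idx]

    def left_limit(self, x) -> np.ndarray:
        """Evaluate the left limit F(x-)."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="left")
        padded = np.concatenate([[0.0], self.cum])
        return padded[idx]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({"value": self.support, "cumulative": self.cum})


def ecdf(values) -> StepCDF:
    """Empirical CDF of population counts: step (multiplicity)/m per value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf requires at least one value")
    support, counts = np.unique(values, return_counts=True)
    return StepCDF(support=support, cum=np.cumsum(counts) / values.size)


def wecdf(values, weights, mode: str = "normalized") -> StepCDF:
    """Design-weighted ECDF.

    normalized: jump of W_i / sum(W) at each X_i (terminal 1).
    as_printed: jump of W_i / n (terminal sum(W)/n, may exceed 1).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("wecdf requires at least one value")
    if values.shape != weights.shape:
        raise ValueError("values and weights must be aligned")
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("weights must be positive and finite")
    if mode not in ("normalized", "as_printed"):
        raise ValueError("mode must be 'normalized' or 'as_printed'")
    denom = weights.sum() if mode == "normalized" else float(values.size)
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    support, start = np.unique(v, return_index=True)
    jump = np.add.reduceat(w, start) / denom
    return StepCDF(support=support, cum=np.cumsum(jump))


def ks_distance(F: StepCDF, G: StepCDF) -> float:
    """Exact sup_x |F(x) - G(x)| for two step functions.

    Both functions are piecewise constant, so the supremum is attained at a
    knot of one of them or approached from the left of a knot; evaluating
    both functions and their left limits on the union of the two knot sets
    is exact.
    """
    knots = np.union1d(F.support, G.support)
    d_at = np.abs(F(knots) - G(knots))
    d_left = np.abs(F.left_limit(knots) - G.left_limit(knots))
    return float(max(d_at.max(), d_left.max()))
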