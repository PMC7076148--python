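"""Sample-size estimation by replicated Kolmogorov-Smirnov simulation.

For each stratum and each candidate sample size n, cells are drawn with
replacement proportionally to population size (multinomial PPS — the exact
sampling model of the per-draw probability, and the only mechanism that
allows n to exceed the number of distinct cells), the normalized weighted
ECDF of each draw is compared against the stratum's full ECDF, and the KS
distance is averaged over replications.  The resulting mean-distance curve
is characteristically non-monotone: deceptively low at extremely small n
(a single heavy cell places its whole unit mass near the top of the
distribution), then spiking, then decaying as n grows.  Sample-size
selection therefore discards the pre-peak regime (everything up to the
argmax of the mean curve) and returns the smallest remaining n whose mean
distance meets the chosen threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SettledCellFrame
from .stratify import Stratification

__all__ = [
    "KSCurve",
    "SizeSelectionEntry",
    "SizeSelection",
    "simulate_ks_curve",
    "select_sample_size",
    "allocate_sizes",
]


@dataclass
class KSCurve:
    """Mean (and sd) KS distance vs. candidate sample size for one stratum."""

    stratum: int
    n_grid: np.ndarray
    mean_D: np.ndarray
    sd_D: np.ndarray
    reps: int
    seed: int
    m_S: int
    degenerate: bool = False

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "n": self.n_grid,
                "mean_D": self.mean_D,
                "sd_D": self.sd_D,
            }
        )


def _stratum_ks_curve(
    pop: np.ndarray, n_grid: np.ndarray, reps: int, rng_for, sup_mode: str = "exact"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized replicated KS simulation for one stratum.

    ``pop`` are all stratum populations (zeros allowed; they enter the
    reference ECDF but cannot be drawn).  ``rng_for(n)`` yields the
    deterministic substream for a given candidate n.
    """
    knots, counts = np.unique(pop, return_counts=True)
    F = np.cumsum(counts) / pop.size

    pos_mask = pop > 0
    pos = pop[pos_mask]
    p = pos / pos.sum()
    inv_p = 1.0 / p
    order = np.argsort(pos, kind="stable")
    pos_sorted = pos[order]
    # group boundaries of equal values among sampleable cells, and the
    # position of each distinct positive value on the reference knot grid
    distinct_pos, starts = np.unique(pos_sorted, return_index=True)
    grid_idx = np.searchsorted(knots, distinct_pos)

    mean_D = np.empty(len(n_grid))
    sd_D = np.empty(len(n_grid))
    for a, n in enumerate(n_grid):
        rng = rng_for(int(n))
        counts_rep = rng.multinomial(int(n), p, size=reps)  # reps x m_pos
        weighted = counts_rep * inv_p  # pi_S and the stratum total cancel
        grouped = np.add.reduceat(weighted[:, order], starts, axis=1)
        jumps = np.zeros((reps, knots.size))
        jumps[:, grid_idx] = grouped
        G = np.cumsum(jumps, axis=1)
        G /= G[:, -1:]
        diff = np.abs(G - F[None, :])
        if sup_mode == "sampled_knots":
            diff[jumps <= 0] = 0.0
        D = diff.max(axis=1)
        mean_D[a] = D.mean()
        sd_D[a] = D.std(ddof=1) if reps > 1 else 0.0
    return mean_D, sd_D


def simulate_ks_curve(
    frame: SettledCellFrame,
    strat: Stratification,
    n_grid=range(1, 1001),
    reps: int = 1000,
    seed: int = 0,
    sup_mode: str = "exact",
) -> dict[int, KSCurve]:
    """Replicated KS curves for every stratum.

    For each (stratum, n): ``reps`` multinomial PPS draws, a normalized
    WECDF per draw, KS distance against the stratum's full population ECDF,
    arithmetic mean and sd across replications.  Substreams are derived
    deterministically from ``seed`` per (stratum, n), so any sub-curve is
    reproducible in isolation.

    Both step functions share the stratum's distinct population values as
    knots, so with the default ``sup_mode="exact"`` the supremum is
    evaluated exactly on that grid.  ``sup_mode="sampled_knots"`` instead
    takes the maximum only over the values present in the draw — a
    diagnostic mode, because it explains the dip often seen in mean-KS
    curves at extremely small n: with one PPS draw the single sampled value
    is almost surely a high-population cell where both curves are near 1,
    so the restricted maximum is deceptively small, then spikes as more of
    the support enters the sample.  The exact supremum has no such dip
    (at n = 1 it is at least 1/2) and decreases from the start.
    """
    if sup_mode not in ("exact", "sampled_knots"):
        raise ValueError("sup_mode must be 'exact' or 'sampled_knots'")
    frame.require_nonempty("KS simulation")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_grid = np.asarray(sorted(set(int(n) for n in n_grid)))
    if n_grid.min() < 1:
        raise ValueError("sample sizes must be >= 1")
    labels = strat.labels
    pop_all = frame.populations
    curves: dict[int, KSCurve] = {}
    for s in range(strat.k):
        pop = pop_all[labels == s]
        if pop.size == 0:
            raise ValueError(f"stratum {s} contains no cells")
        if (pop > 0).sum() == 0:
            raise ValueError(f"stratum {s} has no sampleable (positive) cells")
        degenerate = np.unique(pop).size < 2

        def rng_for(n: int, _s=s):
            return np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(_s, n))
            )

        mean_D, sd_D = _stratum_ks_curve(pop, n_grid, reps, rng_for, sup_mode)
        curves[s] = KSCurve(
            stratum=s,
            n_grid=n_grid.copy(),
            mean_D=mean_D,
            sd_D=sd_D,
            reps=reps,
            seed=seed,
            m_S=int(pop.size),
            degenerate=degenerate,
        )
    return curves


@dataclass
class SizeSelectionEntry:
    stratum: int
    threshold: float
    achieved: bool
    n: int | None
    fraction: float | None  # n / m_S
    mean_D_at_n: float | None
    min_attained: float  # smallest mean_D on the post-peak branch


@dataclass
class SizeSelection:
    threshold: float
    entries: dict[int, SizeSelectionEntry] = field(default_factory=dict)

    @property
    def all_achieved(self) -> bool:
        return all(e.achieved for e in self.entries.values())

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "strata": {
                str(s): {
                    "achieved": e.achieved,
                    "n": e.n,
                    "fraction": e.fraction,
                    "mean_D_at_n": e.mean_D_at_n,
                    "min_attained": e.min_attained,
                }
                for s, e in self.entries.items()
            },
        }


def select_sample_size(curve: KSCurve, threshold: float) -> SizeSelectionEntry:
    """Smallest post-peak n whose mean KS distance meets the threshold.

    The search is restricted to n strictly greater than the argmax of the
    mean curve, discarding the low-n regime where the distance is
    spuriously small before it spikes.  If no post-peak n qualifies, an
    explicit not-achievable entry reports the minimum attained distance.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    peak = int(np.argmax(curve.mean_D))
    post = slice(peak + 1, None)
    mean_post = curve.mean_D[post]
    n_post = curve.n_grid[post]
    if mean_post.size:
        ok = np.nonzero(mean_post <= threshold)[0]
        min_attained = float(mean_post.min())
    else:
        ok = np.array([], dtype=int)
        min_attained = float(curve.mean_D[peak])
    if ok.size == 0:
        return SizeSelectionEntry(
            stratum=curve.stratum,
            threshold=threshold,
            achieved=False,
            n=None,
            fraction=None,
            mean_D_at_n=None,
            min_attained=min_attained,
        )
    i = int(ok[0])
    n = int(n_post[i])
    return SizeSelectionEntry(
        stratum=curve.stratum,
        threshold=threshold,
        achieved=True,
        n=n,
        fraction=n / curve.m_S,
        mean_D_at_n=float(mean_post[i]),
        min_attained=min_attained,
    )


def allocate_sizes(curves: dict[int, KSCurve], threshold: float) -> SizeSelection:
    """Apply the per-stratum selection at one shared distance threshold.

    A single threshold allocates sample size so every stratum attains a
    similar sampling performance; more heterogeneous strata need larger n.
    """
    sel = SizeSelection(threshold=threshold)
    for s, curve in sorted(curves.items()):
        sel.entries[s] = select_sample_size(curve, threshold)
    return sel
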