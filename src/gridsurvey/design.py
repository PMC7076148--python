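"""Stratified probability-proportional-to-size design.

Each settled cell i in stratum S receives the composite selection
probability

    pi_i(SPPS) = pi_i(S) * pi_i(PPS),
    pi_i(S)    = n_S / m_S,
    pi_i(PPS)  = X_i / sum_{j in S} X_j,

with n_S the target number of sampled cells, m_S the settled-cell count of
the stratum and X_i the cell's population.  The design weight embedded in
the estimator is W_i = 1 / pi_i(SPPS).  By default pi(PPS) is normalized
within each stratum (draws are made per stratum independently); a
whole-frame denominator is available for the composite written with a single
global population total.

Cells with X_i = 0 get pi(PPS) = 0: they stay in the frame (they are settled)
but cannot be drawn and carry no weight.

Two draw mechanisms are provided: systematic PPS (cumulative-size,
random-start, without replacement — the field design, since a survey team
cannot visit a cell twice) and multinomial PPS (n_S independent draws with
replacement — the exact sampling model of the single-draw probability, used
by the sample-size simulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SettledCellFrame
from .stratify import Stratification

__all__ = ["ProbabilityScheme", "SampleDraw", "compute_probabilities", "draw_sample"]


@dataclass
class ProbabilityScheme:
    """Per-cell probabilities and weights, plus per-stratum bookkeeping.

    ``cells``: cell_id, stratum, population, pi_S, pi_PPS, pi_SPPS, weight
    (NaN where pi_SPPS = 0), sampleable.
    ``strata``: stratum, m_S, n_S, population_total.
    """

    cells: pd.DataFrame = field(repr=False)
    strata: pd.DataFrame = field(repr=False)
    denominator: str = "stratum"

    def stratum_cells(self, stratum: int) -> pd.DataFrame:
        return self.cells[self.cells["stratum"] == stratum]


def compute_probabilities(
    frame: SettledCellFrame,
    strat: Stratification,
    n_by_stratum: dict[int, int],
    denominator: str = "stratum",
) -> ProbabilityScheme:
    """Assign pi(S), pi(PPS), pi(SPPS) and design weights to every cell.

    Parameters
    ----------
    n_by_stratum
        Target sample size n_S per stratum id; 1 <= n_S <= m_S required.
    denominator
        "stratum" (default) normalizes pi(PPS) within each stratum so it sums
        to 1 there; "frame" divides by the whole-frame population total.
    """
    frame.require_nonempty("probability scheme")
    if denominator not in ("stratum", "frame"):
        raise ValueError("denominator must be 'stratum' or 'frame'")
    if len(strat.labels) != frame.m:
        raise ValueError("stratification does not cover the frame")
    labels = strat.labels
    pop = frame.populations
    frame_total = pop.sum()

    strata_rows = []
    pi_S = np.empty(frame.m)
    pi_PPS = np.empty(frame.m)
    for s in range(strat.k):
        in_s = labels == s
        m_S = int(in_s.sum())
        if m_S == 0:
            raise ValueError(f"stratum {s} contains no cells")
        total_S = pop[in_s].sum()
        if total_S <= 0:
            raise ValueError(f"stratum {s} has zero total population")
        n_S = int(n_by_stratum.get(s, 0))
        if not 1 <= n_S <= m_S:
            raise ValueError(f"stratum {s}: need 1 <= n_S <= m_S={m_S}, got n_S={n_S}")
        pi_S[in_s] = n_S / m_S
        denom = total_S if denominator == "stratum" else frame_total
        pi_PPS[in_s] = pop[in_s] / denom
        strata_rows.append(
            {"stratum": s, "m_S": m_S, "n_S": n_S, "population_total": total_S}
        )
    pi_SPPS = pi_S * pi_PPS
    sampleable = pi_SPPS > 0
    n_zero = int((~sampleable).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-population cell(s) are unsampleable "
            "(pi_PPS = 0, weight undefined)",
            stacklevel=2,
        )
    weight = np.where(sampleable, 1.0 / np.where(sampleable, pi_SPPS, 1.0), np.nan)
    cells = pd.DataFrame(
        {
            "cell_id": frame.cell_ids,
            "stratum": labels,
            "population": pop,
            "pi_S": pi_S,
            "pi_PPS": pi_PPS,
            "pi_SPPS": pi_SPPS,
            "weight": weight,
            "sampleable": sampleable,
        }
    )
    return ProbabilityScheme(
        cells=cells, strata=pd.DataFrame(strata_rows), denominator=denominator
    )


@dataclass
class SampleDraw:
    """A realized cell sample with design weights.

    ``records``: cell_id, stratum, weight, multiplicity (> 1 only possible
    for with-replacement draws and for systematic hits on cells larger than
    the sampling step).
    """

    method: str
    seed: int
    records: pd.DataFrame = field(repr=False)

    def n_in_stratum(self, stratum: int) -> int:
        r = self.records[self.records["stratum"] == stratum]
        return int(r["multiplicity"].sum())


def _systematic_pps(pop, n, rng):
    """Cumulative-size systematic selection: indices and multiplicities."""
    cum = np.cumsum(pop)
    total = cum[-1]
    step = total / n
    start = rng.uniform(0.0, step)
    points = start + step * np.arange(n)
    # cell i owns the half-open size interval (cum[i-1], cum[i]]
    idx = np.searchsorted(cum, points, side="left")
    return np.unique(idx, return_counts=True)


def draw_sample(
    scheme: ProbabilityScheme,
    method: str = "systematic",
    seed: int = 0,
    shuffle_order: bool = False,
) -> SampleDraw:
    """Draw n_S cells from every stratum, independently across strata.

    systematic
        Cells sorted by cell_id (row-major; ``shuffle_order=True`` randomizes
        instead), cumulative population computed, and n_S equally spaced
        points with a random start select the cells whose cumulative
        intervals contain them.  Any cell with X_i >= step is selected with
        certainty.
    multinomial
        n_S independent PPS draws with replacement; multiplicities recorded.
    """
    if method not in ("systematic", "multinomial"):
        raise ValueError("method must be 'systematic' or 'multinomial'")
    rng = np.random.default_rng(seed)
    out = []
    for srow in scheme.strata.itertuples(index=False):
        s, n_S = srow.stratum, srow.n_S
        sub = scheme.stratum_cells(s)
        sub = sub[sub["sampleable"]].sort_values("cell_id")
        pop = sub["population"].to_numpy()
        if method == "systematic":
            if len(sub) < n_S:
                raise ValueError(
                    f"stratum {s}: n_S={n_S} exceeds the {len(sub)} cells with "
                    "positive population (systematic draw is without replacement)"
                )
            order = rng.permutation(len(sub)) if shuffle_order else np.arange(len(sub))
            idx, mult = _systematic_pps(pop[order], n_S, rng)
            chosen = sub.iloc[order[idx]]
        else:
            p = pop / pop.sum()
            counts = rng.multinomial(n_S, p)
            idx = np.nonzero(counts)[0]
            mult = counts[idx]
            chosen = sub.iloc[idx]
        block = chosen[["cell_id", "stratum", "weight"]].copy()
        block["multiplicity"] = mult
        out.append(block.sort_values("cell_id"))
    records = pd.concat(out, ignore_index=True)
    return SampleDraw(method=method, seed=seed, records=records)
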