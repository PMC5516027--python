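"""Pan- and core-genome accumulation under random genome addition.

For each replicate, strains are added in a uniformly random order; pan(s) is
the number of distinct families among the first s strains and core(s) the
number present in all of them. Medians over replicates (1,000 by default)
summarize the curves. Because curve values are set cardinalities, the median
of an even number of replicates is taken as the lower median (the order
statistic at ceil(r/2)), keeping every summary an achievable integer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .families import FamilyMatrix


def _lower_median(values: np.ndarray) -> np.ndarray:
    """Lower median along axis 0: the order statistic at ceil(r/2)."""
    sorted_vals = np.sort(values, axis=0)
    r = values.shape[0]
    return sorted_vals[(r + 1) // 2 - 1]


@dataclass
class AccumulationResult:
    median_pan: np.ndarray  # step s=1..n
    median_core: np.ndarray
    pan: np.ndarray  # replicates x steps
    core: np.ndarray
    n_reps: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        steps = np.arange(1, self.median_pan.size + 1)
        return pd.DataFrame(
            {
                "step": steps,
                "median_pan": self.median_pan,
                "median_core": self.median_core,
                "pan_q1": np.percentile(self.pan, 25, axis=0, method="lower"),
                "pan_q3": np.percentile(self.pan, 75, axis=0, method="lower"),
                "core_q1": np.percentile(self.core, 25, axis=0, method="lower"),
                "core_q3": np.percentile(self.core, 75, axis=0, method="lower"),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _curves_for_orders(presence: np.ndarray, orders: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pan/core step values (orders x steps) for given strain orderings."""
    pan = np.empty(orders.shape, dtype=np.int64)
    core = np.empty(orders.shape, dtype=np.int64)
    for r, order in enumerate(orders):
        rows = presence[order]
        union = np.logical_or.accumulate(rows, axis=0)
        inter = np.logical_and.accumulate(rows, axis=0)
        pan[r] = union.sum(axis=1)
        core[r] = inter.sum(axis=1)
    return pan, core


def accumulation_curves(
    fm: FamilyMatrix, n_reps: int = 1000, seed: int | None = None
) -> AccumulationResult:
    """Randomized pan/core accumulation curves (medians over replicates)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    presence = fm.presence().to_numpy()
    if presence.size == 0:
        raise ValueError("family matrix is empty")
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    orders = np.array([rng.permutation(n) for _ in range(n_reps)])
    pan, core = _curves_for_orders(presence, orders)
    return AccumulationResult(
        median_pan=_lower_median(pan),
        median_core=_lower_median(core),
        pan=pan,
        core=core,
        n_reps=n_reps,
        seed=seed,
    )


def exhaustive_accumulation(fm: FamilyMatrix) -> AccumulationResult:
    """Exact accumulation medians over all n! strain orders (oracle, n <= 6)."""
    presence = fm.presence().to_numpy()
    n = presence.shape[0]
    if n > 6:
        raise ValueError("exhaustive enumeration limited to n_strains <= 6")
    orders = np.array(list(itertools.permutations(range(n))))
    pan, core = _curves_for_orders(presence, orders)
    return AccumulationResult(
        median_pan=_lower_median(pan),
        median_core=_lower_median(core),
        pan=pan,
        core=core,
        n_reps=orders.shape[0],
        seed=None,
    )


@dataclass
class OpennessReport:
    mean_increment: float
    heaps_kappa: float
    heaps_gamma: float
    final_increment: float
    verdict: str  # "open" | "closed"


def openness_assess(result: AccumulationResult) -> OpennessReport:
    """Openness of the pan-genome from the median accumulation curve.

    The mean increment is (pan(n) - pan(1)) / (n - 1); a Heaps-law power fit
    pan(s) ~ kappa * s^gamma is done by least squares on log-log scale. The
    pan-genome is called open when the curve is still rising at the final
    addition and the fitted exponent satisfies 0 < gamma < 1 (sub-linear but
    unbounded growth). The Heaps fit is an extension beyond the qualitative
    openness argument and is reported as such.
    """
    pan = np.asarray(result.median_pan, dtype=float)
    n = pan.size
    if n < 3:
        raise ValueError("need at least 3 accumulation steps")
    mean_increment = (pan[-1] - pan[0]) / (n - 1)
    final_increment = pan[-1] - pan[-2]
    steps = np.arange(1, n + 1, dtype=float)
    mask = pan > 0
    gamma, log_kappa = np.polyfit(np.log(steps[mask]), np.log(pan[mask]), 1)
    open_call = final_increment > 0 and 0 < gamma < 1
    return OpennessReport(
        mean_increment=float(mean_increment),
        heaps_kappa=float(math.exp(log_kappa)),
        heaps_gamma=float(gamma),
        final_increment=float(final_increment),
        verdict="open" if open_call else "closed",
    )


def shared_fraction(numerator: int, denominator: int) -> float:
    """Percentage numerator/denominator, half-up rounded to 2 decimals.

    E.g. 599 core families out of 69,882 total -> 0.86 (percent).
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
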