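"""Vargha-Delaney A-Test, effect classification, and replicate consistency.

The A-Test is the nonparametric effect-magnitude statistic used for every
comparison in this package: the probability that a random draw from sample 1
exceeds a random draw from sample 2, with ties counted at half weight.
A = 0.5 means no difference; values at or beyond 0.71 / 0.29 are the
conventional "large" (scientifically significant) effect.  The intermediate
bands follow the canonical Vargha-Delaney table (0.56 small, 0.64 medium,
mirrored below 0.5); band edges are inclusive on the larger-effect side so a
value sitting exactly on 0.71 classifies as large.

Consistency analysis selects the replicate count needed to tame run-to-run
stochasticity: a candidate count n is sufficient when independently seeded
subsets of n runs at identical parameters are statistically indistinguishable
(all pairwise-to-first A magnitudes inside the no-effect band) for both
responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .engine import ConditionResult, RESPONSES, run_replicates

# |A - 0.5| band edges (lower edge inclusive): none < 0.06 <= small < 0.14
# <= medium < 0.21 <= large.  0.21 corresponds to A = 0.71 / 0.29.
MAGNITUDE_BANDS = {"none": 0.0, "small": 0.06, "medium": 0.14, "large": 0.21}


@dataclass(frozen=True)
class ATestResult:
    a: float
    magnitude: float  # |a - 0.5|, in [0, 0.5]
    category: str  # none | small | medium | large
    n1: int
    n2: int


def classify_effect(a: float) -> str:
    """Effect category of an A statistic (symmetric about 0.5)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"A statistic must be in [0, 1], got {a}")
    # snap away float representation error so a = 0.71 lands exactly on the
    # inclusive band edge
    m = round(abs(a - 0.5), 12)
    if m >= MAGNITUDE_BANDS["large"]:
        return "large"
    if m >= MAGNITUDE_BANDS["medium"]:
        return "medium"
    if m >= MAGNITUDE_BANDS["small"]:
        return "small"
    return "none"


def a_test(x: Sequence[float], y: Sequence[float]) -> ATestResult:
    """Vargha-Delaney A statistic of sample ``x`` versus sample ``y``.

    ``(#{x_i > y_j} + 0.5 * #{x_i = y_j}) / (n1 * n2)`` over all pairs,
    computed from exact integer pair counts (one final division), so tied
    data cannot introduce float-order nondeterminism.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("a_test requires two non-empty samples")
    ys = np.sort(y)
    gt = int(np.searchsorted(ys, x, side="left").sum())
    ge = int(np.searchsorted(ys, x, side="right").sum())
    eq = ge - gt
    n1, n2 = x.size, y.size
    a = float(Fraction(2 * gt + eq, 2 * n1 * n2))
    return ATestResult(
        a=a, magnitude=abs(a - 0.5), category=classify_effect(a), n1=n1, n2=n2
    )


def compare_conditions(cond: ConditionResult, baseline: ConditionResult) -> dict[str, ATestResult]:
    """A-Test of a condition against baseline for both per-run responses."""
    return {
        resp: a_test(cond.response(resp), baseline.response(resp))
        for resp in RESPONSES
    }


@dataclass
class ConsistencyResult:
    """Outcome of the replicate-consistency analysis.

    ``minimum_sufficient`` is ``None`` when no candidate replicate count
    passed (the "insufficient" sentinel); ``table`` always carries the full
    score table (candidate n, subset index, response, a, magnitude) so an
    insufficient outcome can still be inspected.
    """

    minimum_sufficient: int | None
    table: pd.DataFrame
    threshold: float = MAGNITUDE_BANDS["small"]

    @property
    def sufficient(self) -> bool:
        return self.minimum_sufficient is not None


def consistency_analysis(
    config: SimConfig,
    candidate_ns: Sequence[int],
    n_subsets: int = 20,
    base_seed: int = 0,
    runner: Callable[[SimConfig, int, int], ConditionResult] | None = None,
) -> ConsistencyResult:
    """Smallest replicate count at which same-parameter subsets agree.

    For each candidate n, ``n_subsets`` independently seeded subsets of n
    runs are generated at the unperturbed configuration; subsets 2..k are
    compared against subset 1 with the A-Test on both responses.  n is
    sufficient when the maximum magnitude over subsets and responses stays
    inside the no-effect band (|A - 0.5| < 0.06, both responses jointly).

    ``runner(config, n, seed) -> ConditionResult`` defaults to
    :func:`ppsim.engine.run_replicates` and is injectable for testing.
    """
    if len(candidate_ns) == 0:
        raise ValueError("candidate_ns must be non-empty")
    ns = list(candidate_ns)
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("candidate_ns must be strictly increasing")
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if runner is None:
        runner = lambda cfg, n, seed: run_replicates(cfg, n, seed)

    threshold = MAGNITUDE_BANDS["small"]
    rows = []
    minimum: int | None = None
    for ci, n in enumerate(ns):
        subsets = [
            runner(config, n, _subset_seed(base_seed, ci, j))
            for j in range(n_subsets)
        ]
        max_mag = 0.0
        for j in range(1, n_subsets):
            for resp in RESPONSES:
                res = a_test(subsets[j].response(resp), subsets[0].response(resp))
                rows.append(
                    {
                        "n": n,
                        "subset": j,
                        "response": resp,
                        "a": res.a,
                        "magnitude": res.magnitude,
                    }
                )
                max_mag = max(max_mag, res.magnitude)
        if minimum is None and max_mag < threshold:
            minimum = n
    return ConsistencyResult(
        minimum_sufficient=minimum,
        table=pd.DataFrame(rows),
        threshold=threshold,
    )


def _subset_seed(base_seed: int, candidate_index: int, subset_index: int) -> int:
    ss = np.random.SeedSequence(
        [int(base_seed), int(candidate_index), int(subset_index)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
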