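"""Four-way classification of enhancers by their H3K27ac response to hormone.

An enhancer whose quantification window overlaps no H3K27ac peak in either
condition is *no_response*.  Among the rest, with signals ``u`` (unstimulated)
and ``s`` (stimulated) and an epsilon floor on denominators:

* increasing — ``s / max(u, eps) >= 1.5`` and ``s`` strictly above the 25th
  percentile of stimulated signals;
* decreasing — relative reduction ``1 - s / max(u, eps) >= 0.33`` and ``u``
  strictly above the 25th percentile of unstimulated signals;
* constant — both signals at or above their 75th percentiles and
  ``|s - u| / max(u, eps) <= 0.10``;
* unclassified — anything meeting none of the above (e.g. 1.2-fold changes).

Percentiles are computed over peak-overlapping enhancers only, since
no-response signals are definitionally background.  Rules are evaluated in
the fixed order above; under the epsilon floor their bodies are mutually
exclusive, so order matters only for degenerate ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .discovery import Enhancer


class EnhancerCategory(str, Enum):
    INCREASING = "increasing"
    CONSTANT = "constant"
    DECREASING = "decreasing"
    NO_RESPONSE = "no_response"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the four response rules.

    fold_increase_min
        Minimum stimulated/unstimulated ratio for *increasing* (default 1.5,
        inclusive).
    reduction_min
        Minimum relative reduction for *decreasing* (default 0.33, i.e. a
        >= 33% drop, inclusive).
    constant_max_change
        Maximum |change|/unstimulated for *constant* (default 0.10).
    signal_floor
        Epsilon floor applied to ratio denominators.
    """

    fold_increase_min: float = 1.5
    reduction_min: float = 0.33
    constant_max_change: float = 0.10
    signal_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.fold_increase_min <= 1:
            raise ValueError("fold_increase_min must exceed 1")
        if not (0 < self.reduction_min < 1):
            raise ValueError("reduction_min must be in (0, 1)")
        if not (0 <= self.constant_max_change < self.reduction_min):
            raise ValueError("constant_max_change must be in [0, reduction_min)")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be > 0")


@dataclass
class CategorySummary:
    """Counts and fractions per category plus the quartile gates used."""

    total: int
    counts: dict[str, int]
    fractions: dict[str, float]
    quartiles: dict[str, float]  # q25_unstim, q25_stim, q75_unstim, q75_stim

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "quartiles": dict(self.quartiles),
        }


def quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile (index ``h = (n - 1) * q``)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty input is undefined")
    return float(np.quantile(arr, q, method="linear"))


def classify_enhancer(
    e: Enhancer,
    params: ClassificationParams,
    q25_unstim: float,
    q25_stim: float,
    q75_unstim: float,
    q75_stim: float,
) -> EnhancerCategory:
    """Assign one category given population quartile gates."""
    if e.signal_unstim is None or e.signal_stim is None:
        raise ValueError(f"enhancer {e.enhancer_id} has not been quantified")
    u, s = e.signal_unstim, e.signal_stim
    if u < 0 or s < 0:
        raise ValueError("signals must be >= 0")
    if not e.overlaps_h3k27ac_peak:
        return EnhancerCategory.NO_RESPONSE
    eps = params.signal_floor
    ratio = s / max(u, eps)
    if ratio >= params.fold_increase_min and s > q25_stim:
        return EnhancerCategory.INCREASING
    if 1.0 - ratio >= params.reduction_min and u > q25_unstim:
        return EnhancerCategory.DECREASING
    if (
        u >= q75_unstim
        and s >= q75_stim
        and abs(s - u) / max(u, eps) <= params.constant_max_change
    ):
        return EnhancerCategory.CONSTANT
    return EnhancerCategory.UNCLASSIFIED


def classify_all(
    enhancers: Sequence[Enhancer],
    params: ClassificationParams = ClassificationParams(),
) -> tuple[list[Enhancer], CategorySummary]:
    """Classify every enhancer and summarize category counts and fractions.

    Quartile gates are computed over the signals of peak-overlapping
    enhancers; at least four such enhancers are required.
    """
    classifiable = [e for e in enhancers if e.overlaps_h3k27ac_peak]
    if len(classifiable) < 4:
        raise ValueError(
            f"need >= 4 peak-overlapping enhancers to define quartiles, "
            f"got {len(classifiable)}"
        )
    unstim = [e.signal_unstim for e in classifiable]
    stim = [e.signal_stim for e in classifiable]
    quartiles = {
        "q25_unstim": quantile(unstim, 0.25),
        "q25_stim": quantile(stim, 0.25),
        "q75_unstim": quantile(unstim, 0.75),
        "q75_stim": quantile(stim, 0.75),
    }
    annotated = [
        replace(
            e,
            category=classify_enhancer(
                e,
                params,
                quartiles["q25_unstim"],
                quartiles["q25_stim"],
                quartiles["q75_unstim"],
                quartiles["q75_stim"],
            ).value,
        )
        for e in enhancers
    ]
    counts = {cat.value: 0 for cat in EnhancerCategory}
    for e in annotated:
        counts[e.category] += 1
    total = len(annotated)
    fractions = {cat: (n / total if total else 0.0) for cat, n in counts.items()}
    return annotated, CategorySummary(total, counts, fractions, quartiles)
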