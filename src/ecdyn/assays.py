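"""Bench quantification: ΔΔCt, ChIP-qPCR percent input, dual luciferase, FAIRE recovery.

All Ct arithmetic assumes an amplification efficiency of 2 (a perfect
doubling per cycle).  Triplicates are averaged before differencing;
replicate scatter can additionally be propagated to a fold-change SEM by the
delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class CtMeasurement:
    """qPCR cycle thresholds for a target and its reference gene, in replicate."""

    sample: str
    target_gene: str
    reference_gene: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, cts in (("ct_target", self.ct_target),
                          ("ct_reference", self.ct_reference)):
            cts = tuple(float(c) for c in cts)
            object.__setattr__(self, name, cts)
            if len(cts) < 1:
                raise ValueError(f"{name} needs >= 1 replicate")
            if any(not (0.0 < c < 45.0) for c in cts):
                raise ValueError(f"{name} values must lie in (0, 45)")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


@dataclass(frozen=True)
class LuciferaseMeasurement:
    """Firefly reading normalized by a cotransfected Renilla control."""

    construct: str
    condition: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.renilla <= 0:
            raise ValueError("renilla signal must be > 0")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


def ddct_relative_expression(
    treated: CtMeasurement, control: CtMeasurement
) -> float:
    """Relative expression 2^(-ΔΔCt) of treated vs control.

    ΔCt is the triplicate-mean target Ct minus the triplicate-mean reference
    Ct within each sample; ΔΔCt is treated minus control.
    """
    if (treated.target_gene != control.target_gene
            or treated.reference_gene != control.reference_gene):
        raise ValueError("treated and control must share target and reference genes")
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def ddct_fold_sem(treated: CtMeasurement, control: CtMeasurement) -> float:
    """Delta-method SEM of the 2^(-ΔΔCt) fold from replicate Ct scatter."""
    fold = ddct_relative_expression(treated, control)
    var = 0.0
    for cts in (treated.ct_target, treated.ct_reference,
                control.ct_target, control.ct_reference):
        arr = np.asarray(cts, dtype=float)
        if arr.size > 1:
            var += arr.var(ddof=1) / arr.size
    return float(fold * np.log(2.0) * np.sqrt(var))


def percent_input(
    ct_ip: float | Sequence[float],
    ct_input: float | Sequence[float],
    input_fraction: float = 0.01,
) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    ``100 * input_fraction * 2^(ct_input - ct_ip)``; Ct values may be single
    numbers or replicate lists (averaged first).
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError("input_fraction must lie in (0, 1]")
    ip = float(np.mean(ct_ip))
    inp = float(np.mean(ct_input))
    return float(100.0 * input_fraction * 2.0 ** (inp - ip))


def luciferase_fold(
    measure: LuciferaseMeasurement, backbone: LuciferaseMeasurement
) -> float:
    """Renilla-normalized firefly activity relative to the reporter backbone."""
    if backbone.ratio == 0:
        raise ValueError("backbone firefly/renilla ratio is zero")
    return measure.ratio / backbone.ratio


def faire_recovery_ratio(free_dna: float, total_dna: float) -> float:
    """Free/total DNA recovery ratio of a FAIRE-qPCR assay."""
    if total_dna <= 0:
        raise ValueError("total DNA quantity must be > 0")
    return free_dna / total_dna


def faire_recovery_from_ct(
    ct_free: float | Sequence[float], ct_total: float | Sequence[float]
) -> float:
    """Recovery ratio from Ct values: 2^(ct_total - ct_free)."""
    return float(2.0 ** (float(np.mean(ct_total)) - float(np.mean(ct_free))))
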