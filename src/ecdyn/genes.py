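"""Differential-expression calls and gene-level H3K27ac change comparison.

Genes are called up- or down-regulated by a symmetric 1.5-fold rule on a
two-condition abundance table.  Gene-level H3K27ac change is the log2 ratio
of input-normalized signal over the gene body extended 2 kb upstream of the
TSS (strand-aware; a promoter-only TSS±1 kb region is offered as an
alternative).  Group comparisons use the pooled-variance (Student) two-sample
t test — with triplicate groups this gives 4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import QuantParams
from .io import GeneModel, SignalTrack


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    expr_unstim: float
    expr_stim: float
    log2fc: float
    de_class: Literal["up", "down", "unchanged"]


@dataclass(frozen=True)
class GeneAcChange:
    gene_id: str
    ac_unstim: float
    ac_stim: float
    log2_change: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    significant: bool


def classify_de_genes(
    table: pd.DataFrame, fold: float = 1.5, floor: float = 0.5
) -> list[ExpressionRecord]:
    """Call genes up/down/unchanged by a symmetric fold rule (inclusive).

    ``table`` needs columns gene_id, expr_unstim, expr_stim.  Abundances are
    floored at ``floor`` before forming ratios so zeros stay finite.
    """
    required = {"gene_id", "expr_unstim", "expr_stim"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        u = max(float(row.expr_unstim), floor)
        s = max(float(row.expr_stim), floor)
        if s / u >= fold:
            de = "up"
        elif u / s >= fold:
            de = "down"
        else:
            de = "unchanged"
        records.append(
            ExpressionRecord(str(row.gene_id), u, s, float(np.log2(s / u)), de)
        )
    return records


def gene_region(
    gene: GeneModel,
    rule: Literal["body_plus_upstream", "promoter"] = "body_plus_upstream",
    upstream: int = 2000,
    promoter_flank: int = 1000,
) -> tuple[int, int]:
    """Genomic span used for gene-level signal, clipped at position 0."""
    if rule == "body_plus_upstream":
        if gene.strand == "+":
            start, end = gene.body.start - upstream, gene.body.end
        else:
            start, end = gene.body.start, gene.body.end + upstream
    elif rule == "promoter":
        start, end = gene.tss - promoter_flank, gene.tss + promoter_flank + 1
    else:
        raise ValueError(f"unknown region rule {rule!r}")
    start = max(start, 0)
    if end <= start:
        raise ValueError(f"degenerate region for gene {gene.gene_id}")
    return start, end


def _region_signal(
    chip: SignalTrack,
    input_ctrl: SignalTrack,
    chrom: str,
    start: int,
    end: int,
    input_floor: float,
) -> float:
    chip_rpm = chip.region_rpm(chrom, start, end)
    input_rpm = input_ctrl.region_rpm(chrom, start, end)
    return chip_rpm / max(input_rpm, input_floor)


def gene_ac_change(
    gene: GeneModel,
    chip_unstim: SignalTrack,
    chip_stim: SignalTrack,
    input_unstim: SignalTrack,
    input_stim: SignalTrack,
    region_rule: Literal["body_plus_upstream", "promoter"] = "body_plus_upstream",
    upstream: int = 2000,
    pseudocount: float = 0.5,
    params: QuantParams = QuantParams(),
) -> GeneAcChange:
    """log2 change of input-normalized H3K27ac over the gene's region."""
    start, end = gene_region(gene, region_rule, upstream=upstream)
    ac_u = _region_signal(
        chip_unstim, input_unstim, gene.chrom, start, end, params.input_floor
    )
    ac_s = _region_signal(
        chip_stim, input_stim, gene.chrom, start, end, params.input_floor
    )
    return GeneAcChange(
        gene_id=gene.gene_id,
        ac_unstim=ac_u,
        ac_stim=ac_s,
        log2_change=float(np.log2((ac_s + pseudocount) / (ac_u + pseudocount))),
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TTestResult:
    """Pooled-variance Student t test, two-sided, df = nx + ny - 2.

    Degenerate zero-variance inputs follow the conventions: equal means give
    t = 0, p = 1; unequal means give infinite |t|, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, significant=False)
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(t=float(t), df=df, p=0.0, significant=0.0 < alpha)
    se = np.sqrt(pooled_var * (1 / nx + 1 / ny))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), significant=bool(p < alpha))


def t_critical(alpha: float = 0.05, df: int = 4) -> float:
    """Two-sided critical value of Student's t at level ``alpha``."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def compare_ac_by_de_class(
    changes: Sequence[GeneAcChange],
    records: Sequence[ExpressionRecord],
    alpha: float = 0.05,
) -> dict:
    """Mean acetylation change per expression class plus the up-vs-down t test."""
    de_by_gene = {r.gene_id: r.de_class for r in records}
    groups: dict[str, list[float]] = {"up": [], "down": [], "unchanged": []}
    for c in changes:
        de = de_by_gene.get(c.gene_id)
        if de is not None:
            groups[de].append(c.log2_change)
    if len(groups["up"]) < 2 or len(groups["down"]) < 2:
        raise ValueError("need >= 2 genes in both the up and down classes")
    means = {
        cls: (float(np.mean(vals)) if vals else float("nan"))
        for cls, vals in groups.items()
    }
    ttest = two_sample_t(groups["up"], groups["down"], alpha=alpha)
    return {"group_means": means, "group_sizes": {k: len(v) for k, v in groups.items()},
            "ttest": ttest}
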