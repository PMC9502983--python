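"""FAIRE accessibility meta-profiles and per-enhancer accessibility changes.

Profiles are read-density matrices over symmetric flanks (default ±3 kb)
around enhancer summits, in RPM per bp, aggregated column-wise per response
category.  Per-enhancer accessibility change is the stimulated/unstimulated
RPM ratio over the standard 1.5 kb summit window; a fold at or above a
configurable threshold (default 1.2) counts as increased accessibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .discovery import Enhancer
from .io import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Enhancers x position-bins density matrix around summits (RPM/bp)."""

    ids: list[str]
    flank: int
    profile_bin: int
    matrix: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        ncols = 2 * self.flank // self.profile_bin
        if self.matrix.shape != (len(self.ids), ncols):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({len(self.ids)}, {ncols})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("profile densities must be >= 0")

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each column, in bp relative to the summit."""
        return np.arange(-self.flank, self.flank, self.profile_bin)


@dataclass(frozen=True)
class AccessibilityChange:
    """Windowed FAIRE density per condition and the resulting fold call."""

    enhancer_id: str
    faire_unstim: float
    faire_stim: float
    fold: float
    increased: bool


def profile_matrix(
    track: SignalTrack,
    enhancers: Sequence[Enhancer],
    flank: int = 3000,
    profile_bin: int = 50,
    condition: str = "",
) -> ProfileMatrix:
    """Per-enhancer read-density profile over ``[summit - flank, summit + flank)``.

    Entry (i, j) is the mean density (RPM/bp) of the track over column j's
    ``profile_bin`` bp span; spans beyond the chromosome contribute zero.
    """
    if flank % profile_bin != 0:
        raise ValueError("profile_bin must divide flank")
    if profile_bin % track.bin_size != 0:
        raise ValueError("profile_bin must be a multiple of the track bin_size")
    ncols = 2 * flank // profile_bin
    mat = np.zeros((len(enhancers), ncols))
    scale = 1e6 / (track.library_size * profile_bin)
    for i, e in enumerate(enhancers):
        left = e.summit - flank
        for j in range(ncols):
            a = left + j * profile_bin
            b = a + profile_bin
            if b <= 0:
                continue
            mat[i, j] = track.region_reads(e.interval.chrom, a, b) * scale
    return ProfileMatrix(
        ids=[e.enhancer_id for e in enhancers],
        flank=flank,
        profile_bin=profile_bin,
        matrix=mat,
        condition=condition,
    )


def aggregate_profile(
    m: ProfileMatrix, category_assignment: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Column-wise mean profile per category.

    Every row id must have a category; categories with no rows are omitted
    with a warning.
    """
    missing = [i for i in m.ids if i not in category_assignment]
    if missing:
        raise KeyError(f"no category for enhancer id(s) {missing[:5]}")
    cats = np.array([category_assignment[i] for i in m.ids])
    out: dict[str, np.ndarray] = {}
    for cat in dict.fromkeys(category_assignment.values()):
        mask = cats == cat
        if not mask.any():
            logger.warning("category %s has no profiled enhancers; omitted", cat)
            continue
        out[cat] = m.matrix[mask].mean(axis=0)
    return out


def accessibility_change(
    faire_unstim: SignalTrack,
    faire_stim: SignalTrack,
    enhancer: Enhancer,
    window: int = 1500,
    threshold: float = 1.2,
    floor: float = 0.5,
) -> AccessibilityChange:
    """Stim/unstim FAIRE fold over the summit window, with an epsilon floor."""
    if faire_unstim.bin_size != faire_stim.bin_size:
        raise ValueError("FAIRE tracks must share bin_size")
    half = window // 2
    chrom = enhancer.interval.chrom
    start, end = max(enhancer.summit - half, 0), enhancer.summit + half
    u = faire_unstim.region_rpm(chrom, start, end)
    s = faire_stim.region_rpm(chrom, start, end)
    fold = float(s / max(u, floor))
    return AccessibilityChange(
        enhancer_id=enhancer.enhancer_id,
        faire_unstim=float(u),
        faire_stim=float(s),
        fold=fold,
        increased=bool(fold >= threshold),
    )


def fraction_increased(
    changes: Sequence[AccessibilityChange],
    category_assignment: Mapping[str, str],
    category: str,
) -> float:
    """Fraction of a category's enhancers whose accessibility increased."""
    in_cat = [c for c in changes if category_assignment.get(c.enhancer_id) == category]
    if not in_cat:
        raise ValueError(f"no accessibility calls in category {category!r}")
    return sum(c.increased for c in in_cat) / len(in_cat)
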