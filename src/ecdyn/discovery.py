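"""Candidate-enhancer identification and windowed H3K27ac quantification.

Candidate enhancers are H3K4me1 peaks whose summit lies strictly more than a
minimum distance (default 1.5 kb) from every annotated TSS.  Each enhancer's
H3K27ac signal per condition is the input-normalized read density in a fixed
window (default 1.5 kb) centered on the summit: the ratio of ChIP to input
RPM, with the input floored at ``input_floor`` RPM to keep the ratio finite
over input-depleted windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import GeneModel, GenomicInterval, SignalTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    """Windowing and normalization parameters for enhancer quantification.

    window
        Width in bp of the summit-centered quantification window.
    min_tss_distance
        Summits at most this far (bp) from any TSS are rejected as promoter-
        proximal; the filter keeps strictly greater distances.
    input_floor
        Minimum input density (RPM) used as the normalization denominator.
    bin_size
        Track bin width in bp; ``window`` must be a multiple of it.
    """

    window: int = 1500
    min_tss_distance: int = 1500
    input_floor: float = 0.5
    bin_size: int = 10

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % self.bin_size != 0:
            raise ValueError("window must be positive and divisible by bin_size")
        if self.min_tss_distance < 0:
            raise ValueError("min_tss_distance must be >= 0")
        if self.input_floor <= 0:
            raise ValueError("input_floor must be > 0")


@dataclass
class Enhancer:
    """A candidate enhancer: interval, summit anchor and per-condition signal."""

    interval: GenomicInterval
    summit: int
    signal_unstim: float | None = None
    signal_stim: float | None = None
    overlaps_h3k27ac_peak: bool | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        for sig in (self.signal_unstim, self.signal_stim):
            if sig is not None and (not np.isfinite(sig) or sig < 0):
                raise ValueError("signals must be finite and >= 0")

    @property
    def enhancer_id(self) -> str:
        if self.interval.name:
            return self.interval.name
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"

    def window_span(self, params: QuantParams) -> tuple[int, int]:
        """The summit-centered quantification window, clipped at position 0."""
        half = params.window // 2
        start = self.summit - half
        if start < 0:
            logger.warning(
                "window for %s extends past chromosome start; clipped", self.enhancer_id
            )
            start = 0
        return start, self.summit + half


def distance_to_nearest_tss(position: int, genes: Sequence[GeneModel],
                            chrom: str | None = None) -> int:
    """Minimum |position - tss| over genes (restricted to ``chrom`` if given)."""
    tss = np.array(
        [g.tss for g in genes if chrom is None or g.chrom == chrom], dtype=np.int64
    )
    if tss.size == 0:
        raise ValueError("no genes available for TSS distance computation")
    return int(np.min(np.abs(tss - position)))


def enhancer_summit(peak: GenomicInterval, track: SignalTrack | None) -> int:
    """Summit of a peak: midpoint of its maximum-signal bin.

    Uses the stimulated H3K27ac track when available; ties resolve to the
    smallest coordinate; without a track (or with all-zero signal in the
    peak) the summit falls back to the floor of the interval midpoint.
    """
    if track is None:
        return peak.midpoint
    arr = track.values.get(peak.chrom)
    if arr is None:
        return peak.midpoint
    bs = track.bin_size
    lo = peak.start // bs
    hi = min(-(-peak.end // bs), len(arr))
    if lo >= hi:
        return peak.midpoint
    window = arr[lo:hi]
    if np.all(window == 0):
        return peak.midpoint
    best = lo + int(np.argmax(window))  # argmax takes the leftmost maximum
    summit = best * bs + bs // 2
    return int(np.clip(summit, peak.start, peak.end - 1))


def identify_enhancers(
    h3k4me1_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    params: QuantParams = QuantParams(),
    h3k27ac_stim_track: SignalTrack | None = None,
) -> list[Enhancer]:
    """TSS-distal H3K4me1 peaks, summit-anchored, ordered by coordinate.

    A peak is kept iff its summit is strictly more than
    ``params.min_tss_distance`` bp from every TSS on its chromosome (peaks on
    chromosomes with no annotated gene are trivially distal and kept).
    """
    kept: list[Enhancer] = []
    gene_chroms = {g.chrom for g in genes}
    for peak in h3k4me1_peaks:
        summit = enhancer_summit(peak, h3k27ac_stim_track)
        if peak.chrom in gene_chroms:
            dist = distance_to_nearest_tss(summit, genes, chrom=peak.chrom)
            if dist <= params.min_tss_distance:
                continue
        kept.append(Enhancer(interval=peak, summit=summit))
    kept.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return kept


def quantify_window_signal(
    chip: SignalTrack,
    input_ctrl: SignalTrack,
    chrom: str,
    summit: int,
    params: QuantParams = QuantParams(),
) -> float:
    """Input-normalized ChIP signal in the summit-centered window.

    Returns ``chip_rpm / max(input_rpm, input_floor)`` over
    ``[summit - window/2, summit + window/2)`` (clipped at position 0).
    The RPM ratio makes the statistic invariant to rescaling a track's
    values and library size by a common factor.
    """
    if chip.bin_size != input_ctrl.bin_size:
        raise ValueError("chip and input tracks must share bin_size")
    half = params.window // 2
    start, end = max(summit - half, 0), summit + half
    chip_rpm = chip.region_rpm(chrom, start, end)
    input_rpm = input_ctrl.region_rpm(chrom, start, end)
    return chip_rpm / max(input_rpm, params.input_floor)


def quantify_enhancers(
    enhancers: Sequence[Enhancer],
    chip_unstim: SignalTrack,
    chip_stim: SignalTrack,
    input_unstim: SignalTrack,
    input_stim: SignalTrack,
    params: QuantParams = QuantParams(),
) -> list[Enhancer]:
    """Fill per-condition input-normalized signals for every enhancer."""
    out = []
    for e in enhancers:
        out.append(
            replace(
                e,
                signal_unstim=quantify_window_signal(
                    chip_unstim, input_unstim, e.interval.chrom, e.summit, params
                ),
                signal_stim=quantify_window_signal(
                    chip_stim, input_stim, e.interval.chrom, e.summit, params
                ),
            )
        )
    return out


def annotate_h3k27ac_overlap(
    enhancers: Sequence[Enhancer],
    h3k27ac_peaks_unstim: Sequence[GenomicInterval],
    h3k27ac_peaks_stim: Sequence[GenomicInterval],
    params: QuantParams = QuantParams(),
) -> list[Enhancer]:
    """Flag enhancers whose quantification window touches an H3K27ac peak.

    Overlap of >= 1 bp with a peak from either condition sets the flag; the
    half-open convention means abutting intervals do not overlap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for peak in list(h3k27ac_peaks_unstim) + list(h3k27ac_peaks_stim):
        by_chrom.setdefault(peak.chrom, []).append((peak.start, peak.end))
    starts = {c: np.array([p[0] for p in ps]) for c, ps in by_chrom.items()}
    ends = {c: np.array([p[1] for p in ps]) for c, ps in by_chrom.items()}

    out = []
    for e in enhancers:
        w_start, w_end = e.window_span(params)
        chrom = e.interval.chrom
        if chrom in starts:
            hit = bool(np.any((starts[chrom] < w_end) & (ends[chrom] > w_start)))
        else:
            hit = False
        out.append(replace(e, overlaps_h3k27ac_peak=hit))
    return out
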