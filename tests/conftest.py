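import numpy as np
import pytest

from ecdyn.discovery import Enhancer
from ecdyn.io import GenomicInterval, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(values_by_chrom, bin_size=10, library_size=None):
    """SignalTrack from raw per-bin read counts; library defaults to the total."""
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    if library_size is None:
        library_size = sum(v.sum() for v in values.values()) or 1.0
    return SignalTrack(bin_size=bin_size, values=values, library_size=library_size)


def make_enhancer(chrom="chr1", start=1000, end=2000, summit=None, name=None,
                  signal_unstim=None, signal_stim=None, overlaps=None,
                  category=None):
    if summit is None:
        summit = (start + end) // 2
    return Enhancer(
        interval=GenomicInterval(chrom, start, end, name),
        summit=summit,
        signal_unstim=signal_unstim,
        signal_stim=signal_stim,
        overlaps_h3k27ac_peak=overlaps,
        category=category,
    )


def per_base_region_reads(track, chrom, start, end):
    """Brute-force oracle: expand bins to per-base density and sum."""
    arr = track.values.get(chrom)
    if arr is None:
        return 0.0
    per_base = np.repeat(arr / track.bin_size, track.bin_size)
    start = max(start, 0)
    end = min(end, len(per_base))
    if end <= start:
        return 0.0
    return float(per_base[start:end].sum())
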