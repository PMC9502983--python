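"""PWM scanning, degenerate-consensus matching and per-category enrichment.

Motifs are position weight matrices scored as log2 odds against a background
base composition (default uniform), with an additive pseudocount.  Category
enrichment is presence/absence based: a hypergeometric upper tail on the
number of sequences in a category carrying at least one hit, against all
enhancer sequences as the universe, Benjamini–Hochberg adjusted across
motifs.  A degenerate IUPAC consensus matcher covers direct searches for the
ecdysone response element (EcRE)-style sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# complement in index space: A<->T, C<->G, N->N
_COMP_INDEX = np.array([3, 2, 1, 0, 4])

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    out = np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int8,
                      count=len(seq))
    if np.any(out < 0):
        bad = sorted({b for b in seq if b not in _BASE_INDEX})
        raise ValueError(f"sequence contains non-ACGTN characters {bad}")
    return out


@dataclass(frozen=True)
class PWM:
    """A probability matrix over A, C, G, T with background and pseudocount."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 4:
            raise ValueError("PWM matrix must be (L, 4) with L >= 4")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds matrix; the 5th column (N) contributes 0 bits."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        with np.errstate(divide="ignore"):
            lo = np.log2(p / self.background)
        return np.column_stack([lo, np.zeros(len(self))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=1, keepdims=True), **kw)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence; ``offset`` is the forward-strand window start."""

    seq_id: str
    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    k: int  # category sequences with >= 1 hit
    n: int  # category size
    K: int  # all sequences with >= 1 hit
    N: int  # universe size
    p: float
    q: float
    fold: float


def read_jaspar(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR-format count/probability matrices via Bio.motifs."""
    from Bio import motifs as bio_motifs

    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            pwms.append(
                PWM.from_counts(m.matrix_id or m.name, counts, pseudocount=pseudocount)
            )
    return pwms


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every length-L window of an encoded sequence (vectorized)."""
    L = log_odds.shape[0]
    if encoded.size < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return log_odds[np.arange(L), windows].sum(axis=1)


def scan_pwm(
    seq: str,
    pwm: PWM,
    score_min: float | None = None,
    seq_id: str = "",
) -> list[MotifHit]:
    """All double-stranded PWM hits scoring at least ``score_min`` bits.

    ``score_min`` defaults to 80% of the motif's maximal score.  The reverse
    strand scores the reverse complement; ``offset`` always refers to the
    leftmost base of the matched window on the forward sequence.  N bases
    contribute zero bits.
    """
    if score_min is None:
        score_min = 0.8 * pwm.max_score
    encoded = _encode(seq)
    lo = pwm.log_odds
    L = len(pwm)
    hits: list[MotifHit] = []
    fwd = _window_scores(encoded, lo)
    # reverse-strand log-odds: reversed positions, complemented bases
    lo_rc = lo[::-1][:, _COMP_INDEX]
    rev = _window_scores(encoded, lo_rc)
    for offset in np.flatnonzero(fwd >= score_min):
        hits.append(MotifHit(seq_id, int(offset), "+", float(fwd[offset])))
    for offset in np.flatnonzero(rev >= score_min):
        hits.append(MotifHit(seq_id, int(offset), "-", float(rev[offset])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def match_ecre_consensus(
    seq: str,
    consensus: str,
    max_mismatch: int = 0,
    seq_id: str = "",
) -> list[MotifHit]:
    """Positions (both strands) matching a degenerate IUPAC consensus.

    A hit's score is the number of matching positions (length minus
    mismatches).  An N in the sequence only matches a consensus N.
    """
    consensus = consensus.upper()
    bad = sorted(set(consensus) - set(IUPAC_CODES))
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in consensus")
    encoded = _encode(seq)
    L = len(consensus)
    hits: list[MotifHit] = []
    if encoded.size < L:
        return hits

    def match_matrix(cons: str) -> np.ndarray:
        # (L, 5) booleans: does base index b satisfy consensus position l
        m = np.zeros((L, 5), dtype=bool)
        for l, code in enumerate(cons):
            allowed = IUPAC_CODES[code]
            for b in allowed:
                m[l, _BASE_INDEX[b]] = True
            m[l, 4] = allowed == IUPAC_CODES["N"]
        return m

    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    for strand, cons in (("+", consensus),
                         ("-", consensus.translate(_IUPAC_COMPLEMENT)[::-1])):
        mm = match_matrix(cons)
        matches = mm[np.arange(L), windows].sum(axis=1)
        for offset in np.flatnonzero(L - matches <= max_mismatch):
            hits.append(MotifHit(seq_id, int(offset), strand, float(matches[offset])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= max(0, n + K - N):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def sequences_with_hit(
    sequences: Mapping[str, str], pwm: PWM, score_min: float | None = None
) -> set[str]:
    return {
        sid for sid, seq in sequences.items()
        if scan_pwm(seq, pwm, score_min=score_min, seq_id=sid)
    }


def enrich_by_category(
    sequences: Mapping[str, str],
    category_assignment: Mapping[str, str],
    motifs: Sequence[PWM],
    category: str,
    score_min_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """Hypergeometric motif enrichment of one category against all sequences.

    Presence/absence of >= 1 hit per sequence feeds the test; p values are
    BH-adjusted across motifs and results are sorted by (p, motif_id).
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    fg_ids = {sid for sid in sequences if category_assignment.get(sid) == category}
    if not fg_ids:
        raise ValueError(f"category {category!r} has no sequences")
    N = len(sequences)
    n = len(fg_ids)
    raw: list[tuple[str, int, int, float, float]] = []
    for pwm in motifs:
        hit_ids = sequences_with_hit(
            sequences, pwm, score_min=score_min_fraction * pwm.max_score
        )
        K = len(hit_ids)
        k = len(hit_ids & fg_ids)
        p = hypergeom_upper_tail(k, N, K, n)
        fold = (k / n) / (K / N) if K > 0 else float("nan")
        raw.append((pwm.motif_id, k, K, p, fold))
    qvals = stats.false_discovery_control([r[3] for r in raw], method="bh")
    results = [
        EnrichmentResult(motif_id=mid, k=k, n=n, K=K, N=N, p=p, q=float(q), fold=fold)
        for (mid, k, K, p, fold), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.motif_id))
    return results
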