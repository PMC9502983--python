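"""Seeded synthetic dataset with the statistical structure the pipeline assumes.

The generator lays a toy genome out in fixed 10 kb slots, one candidate
enhancer and one gene per slot: the enhancer summit sits ~2 kb into the slot
and the gene TSS at 7 kb, so every planted enhancer is guaranteed TSS-distal
(> 4 kb) while a configurable fraction of decoy peaks is placed promoter-
proximal and must be rejected by discovery.  Each enhancer is assigned a
response category at exact configured counts; its H3K27ac ChIP signal is a
deterministic Gaussian-shaped read bump over Poisson background, with the
stimulated amplitude scaled by a category-specific fold drawn clear of the
classification thresholds.  Accessibility (FAIRE) bumps, motif plants,
promoter acetylation and expression responses of the slot's gene, and qPCR /
luciferase tables are all coupled to the planted category, and a ground-truth
table records every planted value.

Signal realism is deliberately minimal — Gaussian bumps plus Poisson
background, no read-level artifacts — because the generator's job is the
statistical structure of the analysis, not sequencing realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .motifs import IUPAC_CODES, PWM

CATEGORIES = ("increasing", "constant", "decreasing", "no_response", "unclassified")

#: Degenerate inverted-repeat consensus used as the EcRE stand-in for
#: synthetic tests (two AGGTCA-type half sites, 1 bp spacer).  The consensus
#: actually used for real silkworm data is a required user input.
SYNTHETIC_ECRE_CONSENSUS = "RGGTCANTGACCY"

_SLOT = 10_000
_SUMMIT_OFFSET = 2_000
_TSS_OFFSET = 7_000


def _pwm_from_consensus(motif_id: str, consensus: str, dominant: float = 0.94) -> PWM:
    """A sharp PWM whose argmax letters spell a (possibly degenerate) consensus."""
    rows = []
    for code in consensus.upper():
        allowed = sorted(IUPAC_CODES[code])
        col = np.full(4, (1.0 - dominant) / 3.0)
        if len(allowed) == 4:
            col = np.full(4, 0.25)
        else:
            rest = (1.0 - dominant) / (4 - len(allowed)) if len(allowed) < 4 else 0.0
            col = np.full(4, rest)
            for b in allowed:
                col["ACGT".index(b)] = dominant / len(allowed)
        rows.append(col / col.sum())
    return PWM(motif_id, np.array(rows))


def default_motif_panel() -> list[PWM]:
    """Synthetic PWM panel: hormone-receptor and repressor motifs plus fillers.

    The EcR-like matrix encodes the inverted-repeat response element; the
    Eip74-like matrix an ETS-type site.  The remaining three are neutral
    fillers planted at background rate only.  All matrices are synthetic
    approximations for testing, not database motifs.
    """
    return [
        _pwm_from_consensus("EcR_like", SYNTHETIC_ECRE_CONSENSUS),
        _pwm_from_consensus("Eip74_like", "ACCGGAAGT"),
        _pwm_from_consensus("BrC_like", "TTTAGTTTCA"),
        _pwm_from_consensus("Deaf1_like", "TTCGGGACTT"),
        _pwm_from_consensus("FtzF1_like", "GTCCAAGGCT"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Category fractions mirror the proportions the classification stage is
    expected to recover (13.6% increasing, 8.2% decreasing); fold ranges per
    category sit clear of the 1.5x / 33% / 10% rule thresholds so that, at
    the configured read depths, measurement noise rarely crosses a rule
    boundary.  Amplitudes are reads per bump; rates are reads per bin.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_700_000
    n_enhancers: int = 1000
    decoy_fraction: float = 0.05
    category_fractions: dict[str, float] = field(default_factory=lambda: {
        "increasing": 0.136,
        "decreasing": 0.082,
        "constant": 0.15,
        "no_response": 0.10,
        "unclassified": 0.532,
    })
    # log-normal location (median reads/bump) and log-sd per category
    amp_location: dict[str, float] = field(default_factory=lambda: {
        "increasing": 1200.0, "decreasing": 1800.0, "constant": 4000.0,
        "unclassified": 800.0, "no_response": 0.0,
    })
    amp_scale: dict[str, float] = field(default_factory=lambda: {
        "increasing": 0.35, "decreasing": 0.35, "constant": 0.30,
        "unclassified": 0.40, "no_response": 0.0,
    })
    fold_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "increasing": (1.8, 4.0), "decreasing": (0.30, 0.55),
        "constant": (0.98, 1.02), "unclassified": (1.12, 1.25),
        "no_response": (1.0, 1.0),
    })
    peak_sigma: float = 150.0
    background_rate: float = 0.05
    input_rate: float = 8.0
    bin_size: int = 10
    # condition-invariant acetylation mass per slot (reads); its stimulated
    # copy is rescaled so both conditions carry identical planted mass and
    # depth normalization cannot bias measured folds, emulating a genome
    # whose total acetylation is conserved across the stimulus
    static_amp: float = 2_000.0
    static_amp_scale: float = 0.20
    # FAIRE model
    faire_amp_location: float = 1000.0
    faire_amp_scale: float = 0.30
    faire_background_rate: float = 0.10
    faire_coupling: float = 0.55  # fraction of increasing enhancers that open
    faire_fold: float = 2.0
    faire_noresponse_amp: float = 400.0
    # motif planting rates: per-category rate with a baseline for the rest
    motif_plant_rates: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "EcR_like": {"increasing": 0.60, "default": 0.05},
        "Eip74_like": {"decreasing": 0.60, "default": 0.05},
    })
    # expression model
    expr_location: float = 100.0
    expr_scale: float = 0.8
    up_fold_range: tuple[float, float] = (1.8, 3.0)
    unchanged_fold_range: tuple[float, float] = (0.75, 1.33)
    promoter_amp_location: float = 1000.0
    promoter_amp_scale: float = 0.30
    # qPCR / luciferase model
    ct_sd: float = 0.08
    n_qpcr_genes: int = 3
    n_replicates: int = 3

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")
        if any(f < 0 for f in self.category_fractions.values()):
            raise ValueError("category fractions must be >= 0")
        for name in ("background_rate", "input_rate", "faire_background_rate",
                     "decoy_fraction", "ct_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_decoys(self) -> int:
        return int(round(self.decoy_fraction * self.n_enhancers))


@dataclass
class SimulatedDataset:
    """File bundle plus the planted ground truth."""

    outdir: Path
    paths: dict[str, Path]
    ground_truth: pd.DataFrame
    config: SimulationConfig


def _exact_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the configured fractions."""
    raw = {c: fractions.get(c, 0.0) * n for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def plant_motif(seq: str, motif: PWM | str, position: int) -> str:
    """Write a motif's consensus letters into a sequence at ``position``.

    PWMs plant their argmax letters; an IUPAC consensus plants the
    alphabetically first allowed base at degenerate positions.
    """
    letters = motif.consensus() if isinstance(motif, PWM) else "".join(
        sorted(IUPAC_CODES[c])[0] for c in motif.upper()
    )
    if position < 0 or position + len(letters) > len(seq):
        raise ValueError(
            f"motif of length {len(letters)} does not fit at {position} "
            f"in sequence of length {len(seq)}"
        )
    return seq[:position] + letters + seq[position + len(letters):]


def render_track(
    elements: list[tuple[str, int, float]],
    chrom_lengths: dict[str, int],
    sigma: float,
    background_rate: float,
    bin_size: int,
    rng: np.random.Generator,
) -> SignalTrack:
    """Gaussian read bumps over Poisson background, binned.

    ``elements`` are (chrom, position, amplitude) with amplitude in reads;
    each bump deposits its amplitude according to the normal CDF over bin
    edges within ±5σ.  ``library_size`` is the realized total read count.
    """
    values: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        arr = rng.poisson(background_rate, n_bins).astype(float)
        values[chrom] = arr
    for chrom, pos, amp in elements:
        if amp < 0:
            raise ValueError("bump amplitudes must be >= 0")
        if amp == 0.0:
            continue
        arr = values[chrom]
        # symmetric bin range about the center, so noiseless bumps mirror
        lo = max(int(np.floor((pos - 5 * sigma) / bin_size)), 0)
        hi = min(int(np.ceil((pos + 5 * sigma) / bin_size)), len(arr))
        edges = np.arange(lo, hi + 1) * bin_size
        mass = np.diff(norm.cdf(edges, loc=pos, scale=sigma))
        arr[lo:hi] += amp * mass
    library = float(sum(a.sum() for a in values.values()))
    if library <= 0:
        library = 1.0
    return SignalTrack(bin_size=bin_size, values=values, library_size=library)


def _random_genome(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> dict[str, bytearray]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        chrom: bytearray(bases[rng.integers(0, 4, size=length)].tobytes())
        for chrom, length in chrom_lengths.items()
    }


def _plant_into(genome: dict[str, bytearray], chrom: str, position: int, letters: str) -> None:
    genome[chrom][position:position + len(letters)] = letters.encode()


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Write the full synthetic bundle and its ground truth to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    slots_per_chrom = config.chrom_length // _SLOT
    n_slots = config.n_enhancers + config.n_decoys
    if n_slots > config.n_chroms * slots_per_chrom:
        raise ValueError(
            f"genome too small: {n_slots} elements need more than "
            f"{config.n_chroms * slots_per_chrom} slots of {_SLOT} bp"
        )
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }

    # --- element layout ---------------------------------------------------
    slot_chrom = []
    slot_start = []
    for i in range(n_slots):
        slot_chrom.append(f"chr{i // slots_per_chrom + 1}")
        slot_start.append((i % slots_per_chrom) * _SLOT)
    is_decoy = np.zeros(n_slots, dtype=bool)
    is_decoy[config.n_enhancers:] = True

    counts = _exact_counts(config.category_fractions, config.n_enhancers)
    labels = np.concatenate([
        np.repeat(cat, counts[cat]) for cat in CATEGORIES
    ])
    labels = labels[rng.permutation(config.n_enhancers)]

    # summits: jittered, snapped to the bin grid so bump bin-mass is symmetric
    jitter = rng.integers(-50, 51, size=n_slots) * config.bin_size
    summits = np.array(slot_start) + _SUMMIT_OFFSET + jitter
    # decoys sit promoter-proximal: midpoint 700 bp from their gene's TSS
    summits[is_decoy] = np.array(slot_start)[is_decoy] + _TSS_OFFSET - 700

    # --- per-enhancer planted parameters ---------------------------------
    amp_u = np.zeros(n_slots)
    fold = np.ones(n_slots)
    for i in range(config.n_enhancers):
        cat = labels[i]
        loc = config.amp_location[cat]
        if loc > 0:
            amp_u[i] = loc * np.exp(rng.normal(0.0, config.amp_scale[cat]))
        lo, hi = config.fold_range[cat]
        fold[i] = rng.uniform(lo, hi)
    amp_s = amp_u * fold

    # FAIRE: exact-count coupling among increasing enhancers
    faire_amp = config.faire_amp_location * np.exp(
        rng.normal(0.0, config.faire_amp_scale, size=n_slots)
    )
    faire_amp[config.n_enhancers:] = config.faire_noresponse_amp
    for i in range(config.n_enhancers):
        if labels[i] == "no_response":
            faire_amp[i] = config.faire_noresponse_amp
    faire_fold = np.ones(n_slots)
    inc_idx = np.flatnonzero(labels == "increasing")
    n_coupled = int(round(config.faire_coupling * inc_idx.size))
    coupled = rng.permutation(inc_idx)[:n_coupled]
    faire_fold[coupled] = config.faire_fold

    # --- genes and expression ---------------------------------------------
    gene_rows = []
    expr_rows = []
    promoter_elements_u: list[tuple[str, int, float]] = []
    promoter_elements_s: list[tuple[str, int, float]] = []
    expr_fold = np.ones(n_slots)
    gene_ids = []
    for i in range(n_slots):
        gid = f"gene_{i + 1:04d}"
        gene_ids.append(gid)
        chrom, s0 = slot_chrom[i], slot_start[i]
        tss = s0 + _TSS_OFFSET
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(2000, 2501))
        if strand == "+":
            start, end = tss, tss + body_len
        else:
            start, end = tss - body_len + 1, tss + 1
        gene_rows.append((gid, chrom, strand, start, end))

        cat = labels[i] if not is_decoy[i] else "unclassified"
        if cat == "increasing":
            f = rng.uniform(*config.up_fold_range)
        elif cat == "decreasing":
            f = 1.0 / rng.uniform(*config.up_fold_range)
        else:
            f = rng.uniform(*config.unchanged_fold_range)
        expr_fold[i] = f
        expr_u = config.expr_location * np.exp(rng.normal(0.0, config.expr_scale))
        expr_rows.append((gid, expr_u, expr_u * f))

        # promoter acetylation bump whose fold mirrors the expression response
        p_amp = config.promoter_amp_location * np.exp(
            rng.normal(0.0, config.promoter_amp_scale)
        )
        p_pos = tss + (500 if strand == "+" else -500)
        promoter_elements_u.append((chrom, p_pos, p_amp))
        promoter_elements_s.append((chrom, p_pos, p_amp * f))

    # --- coverage tracks ---------------------------------------------------
    def enhancer_elements(amps: np.ndarray) -> list[tuple[str, int, float]]:
        return [
            (slot_chrom[i], int(summits[i]), float(amps[i]))
            for i in range(n_slots)
            if amps[i] > 0 and not is_decoy[i]
        ]

    # static compartment: one condition-invariant bump per slot, placed well
    # clear of both the enhancer window and the gene region; its stimulated
    # copy is rescaled so total planted mass matches between conditions and
    # depth normalization cannot bias the measured folds
    static_amp = config.static_amp * np.exp(
        rng.normal(0.0, config.static_amp_scale, size=n_slots)
    )
    static_pos = [s0 + 3900 for s0 in slot_start]
    diff_u = (sum(e[2] for e in enhancer_elements(amp_u))
              + sum(e[2] for e in promoter_elements_u))
    diff_s = (sum(e[2] for e in enhancer_elements(amp_s))
              + sum(e[2] for e in promoter_elements_s))
    s_total = float(static_amp.sum())
    kappa_u = kappa_s = 1.0
    if s_total > 0:
        # inflate the lighter condition's static compartment (factor >= 1)
        if diff_u >= diff_s:
            kappa_s += (diff_u - diff_s) / s_total
        else:
            kappa_u += (diff_s - diff_u) / s_total
    static_u = [(slot_chrom[i], static_pos[i], float(static_amp[i] * kappa_u))
                for i in range(n_slots)]
    static_s = [(slot_chrom[i], static_pos[i], float(static_amp[i] * kappa_s))
                for i in range(n_slots)]

    chip_u = render_track(
        enhancer_elements(amp_u) + promoter_elements_u + static_u, chrom_lengths,
        config.peak_sigma, config.background_rate, config.bin_size, rng,
    )
    chip_s = render_track(
        enhancer_elements(amp_s) + promoter_elements_s + static_s, chrom_lengths,
        config.peak_sigma, config.background_rate, config.bin_size, rng,
    )
    input_u = render_track([], chrom_lengths, config.peak_sigma,
                           config.input_rate, config.bin_size, rng)
    input_s = render_track([], chrom_lengths, config.peak_sigma,
                           config.input_rate, config.bin_size, rng)
    faire_u = render_track(
        [(slot_chrom[i], int(summits[i]), float(faire_amp[i]))
         for i in range(n_slots) if not is_decoy[i]],
        chrom_lengths, config.peak_sigma, config.faire_background_rate,
        config.bin_size, rng,
    )
    faire_s = render_track(
        [(slot_chrom[i], int(summits[i]), float(faire_amp[i] * faire_fold[i]))
         for i in range(n_slots) if not is_decoy[i]],
        chrom_lengths, config.peak_sigma, config.faire_background_rate,
        config.bin_size, rng,
    )

    # --- peak calls ---------------------------------------------------------
    h3k4me1_peaks = []
    for i in range(n_slots):
        name = f"decoy_{i - config.n_enhancers + 1:04d}" if is_decoy[i] \
            else f"enh_{i + 1:04d}"
        h3k4me1_peaks.append(GenomicInterval(
            slot_chrom[i], int(summits[i]) - 500, int(summits[i]) + 500, name
        ))
    k27_peaks = [
        GenomicInterval(slot_chrom[i], int(summits[i]) - 400, int(summits[i]) + 400,
                        f"k27_{i + 1:04d}")
        for i in range(config.n_enhancers)
        if labels[i] != "no_response"
    ]

    # --- genome sequence and motif plants ----------------------------------
    genome = _random_genome(rng, chrom_lengths)
    panel = {p.motif_id: p for p in default_motif_panel()}
    plant_offsets = {"EcR_like": -300, "Eip74_like": 150}
    planted: dict[str, np.ndarray] = {}
    for motif_id, rates in config.motif_plant_rates.items():
        pwm = panel[motif_id]
        flags = np.zeros(n_slots, dtype=bool)
        for cat in CATEGORIES:
            idx = np.flatnonzero(labels == cat)  # decoys carry no label
            rate = rates.get(cat, rates.get("default", 0.0))
            n_plant = int(round(rate * idx.size))
            chosen = rng.permutation(idx)[:n_plant]
            flags[chosen] = True
        planted[motif_id] = flags
        offset = plant_offsets.get(motif_id, -600)
        for i in np.flatnonzero(flags):
            _plant_into(genome, slot_chrom[i],
                        int(summits[i]) + offset, pwm.consensus())

    # --- qPCR and luciferase tables -----------------------------------------
    up_idx = [i for i in range(config.n_enhancers) if labels[i] == "increasing"]
    qpcr_rows = []
    for i in up_idx[:config.n_qpcr_genes]:
        f = expr_fold[i]
        for sample, shift in (("control", 0.0), ("treated", -np.log2(f))):
            for rep in range(1, config.n_replicates + 1):
                ct_ref = 20.0 + rng.normal(0.0, config.ct_sd)
                ct_tgt = 24.0 + shift + rng.normal(0.0, config.ct_sd)
                qpcr_rows.append((gene_ids[i], sample, "RP49", rep,
                                  round(ct_tgt, 3), round(ct_ref, 3)))
    luc_rows = [("backbone", "unstim", 500.0, 1000.0),
                ("backbone", "stim", 500.0, 1000.0)]
    for j, i in enumerate(up_idx[:2], start=1):
        base = rng.uniform(2.0, 4.0)
        luc_rows.append((f"enh_construct_{j}", "unstim",
                         500.0 * base, 1000.0))
        luc_rows.append((f"enh_construct_{j}", "stim",
                         500.0 * base * expr_fold[i], 1000.0))

    # --- write bundle -------------------------------------------------------
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "h3k4me1_peaks": outdir / "h3k4me1_peaks.bed",
        "h3k27ac_unstim": outdir / "h3k27ac_unstim.bedgraph",
        "h3k27ac_stim": outdir / "h3k27ac_stim.bedgraph",
        "input_unstim": outdir / "input_unstim.bedgraph",
        "input_stim": outdir / "input_stim.bedgraph",
        "h3k27ac_peaks_unstim": outdir / "h3k27ac_peaks_unstim.bed",
        "h3k27ac_peaks_stim": outdir / "h3k27ac_peaks_stim.bed",
        "faire_unstim": outdir / "faire_unstim.bedgraph",
        "faire_stim": outdir / "faire_stim.bedgraph",
        "expression": outdir / "expression.tsv",
        "qpcr_ct": outdir / "qpcr_ct.tsv",
        "luciferase": outdir / "luciferase.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_fasta({c: s.decode() for c, s in genome.items()}, paths["genome"])
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, chrom, strand, start, end in sorted(gene_rows, key=lambda r: (r[1], r[3])):
            fh.write(f"{chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}\n")
    write_bed(h3k4me1_peaks, paths["h3k4me1_peaks"])
    write_bed(k27_peaks, paths["h3k27ac_peaks_unstim"])
    write_bed(k27_peaks, paths["h3k27ac_peaks_stim"])
    write_bedgraph(chip_u, paths["h3k27ac_unstim"])
    write_bedgraph(chip_s, paths["h3k27ac_stim"])
    write_bedgraph(input_u, paths["input_unstim"])
    write_bedgraph(input_s, paths["input_stim"])
    write_bedgraph(faire_u, paths["faire_unstim"])
    write_bedgraph(faire_s, paths["faire_stim"])
    pd.DataFrame(expr_rows, columns=["gene_id", "expr_unstim", "expr_stim"]).to_csv(
        paths["expression"], sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        qpcr_rows,
        columns=["gene_id", "sample", "reference_gene", "replicate",
                 "ct_target", "ct_reference"],
    ).to_csv(paths["qpcr_ct"], sep="\t", index=False)
    pd.DataFrame(
        luc_rows, columns=["construct", "condition", "firefly", "renilla"]
    ).to_csv(paths["luciferase"], sep="\t", index=False, float_format="%.6g")

    truth = pd.DataFrame({
        "enhancer_id": [iv.name for iv in h3k4me1_peaks],
        "chrom": slot_chrom,
        "summit": summits,
        "category": ["decoy" if is_decoy[i] else labels[i] for i in range(n_slots)],
        "h3k27ac_fold": fold,
        "faire_fold": faire_fold,
        "faire_increased": faire_fold > 1.0,
        "has_ecr_motif": planted.get("EcR_like", np.zeros(n_slots, bool)),
        "has_eip74_motif": planted.get("Eip74_like", np.zeros(n_slots, bool)),
        "gene_id": gene_ids,
        "expr_fold": expr_fold,
        "is_decoy": is_decoy,
    })
    truth.to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.6g")
    return SimulatedDataset(outdir=outdir, paths=paths, ground_truth=truth,
                            config=config)
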