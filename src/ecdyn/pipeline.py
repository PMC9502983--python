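"""End-to-end orchestration: identify → quantify → classify → profile → enrich → genes.

Each stage writes its outputs before the next stage reads them; the run
report echoes every parameter and records a SHA-256 checksum per output so
that re-runs are verifiably identical.  FAIRE, motif and expression stages
are optional — a missing input skips the stage and flags it in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .accessibility import (
    accessibility_change,
    aggregate_profile,
    fraction_increased,
    profile_matrix,
)
from .classification import CategorySummary, ClassificationParams, classify_all
from .discovery import (
    Enhancer,
    QuantParams,
    annotate_h3k27ac_overlap,
    identify_enhancers,
    quantify_enhancers,
)
from .genes import classify_de_genes, compare_ac_by_de_class, gene_ac_change
from .io import GenomicInterval, read_bed, read_bedgraph, read_fasta, read_tss_table, write_bed
from .motifs import enrich_by_category, read_jaspar
from .simulate import default_motif_panel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for a full run."""

    h3k4me1_peaks: Path
    genes: Path
    h3k27ac_unstim: Path
    h3k27ac_stim: Path
    input_unstim: Path
    input_stim: Path
    h3k27ac_peaks_unstim: Path
    h3k27ac_peaks_stim: Path
    outdir: Path
    faire_unstim: Path | None = None
    faire_stim: Path | None = None
    genome_fasta: Path | None = None
    motifs: Path | None = None  # JASPAR file; None = built-in synthetic panel
    expression: Path | None = None
    quant: QuantParams = field(default_factory=QuantParams)
    classify: ClassificationParams = field(default_factory=ClassificationParams)
    profile_flank: int = 3000
    profile_bin: int = 50
    faire_increase_fold: float = 1.2
    enrich_categories: tuple[str, ...] = ("increasing", "decreasing")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h3k4me1_peaks", "genes", "h3k27ac_unstim", "h3k27ac_stim",
                     "input_unstim", "input_stim", "h3k27ac_peaks_unstim",
                     "h3k27ac_peaks_stim", "faire_unstim", "faire_stim",
                     "genome_fasta", "motifs", "expression", "outdir"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        for name in ("h3k4me1_peaks", "genes", "h3k27ac_unstim", "h3k27ac_stim",
                     "input_unstim", "input_stim", "h3k27ac_peaks_unstim",
                     "h3k27ac_peaks_stim"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"required input {name}: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        quant = QuantParams(**raw.pop("quant", {}))
        classify = ClassificationParams(**raw.pop("classify", {}))
        return cls(quant=quant, classify=classify, **raw)

    def echo(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if dataclasses.is_dataclass(val):
                out[f.name] = dataclasses.asdict(val)
            elif isinstance(val, Path):
                out[f.name] = str(val)
            elif isinstance(val, tuple):
                out[f.name] = list(val)
            else:
                out[f.name] = val
        return out


@dataclass
class RunReport:
    stages: dict[str, str]
    checksums: dict[str, str]
    category_summary: dict | None
    fraction_increased: dict[str, float]
    top_enrichment: dict[str, dict]
    gene_dynamics: dict | None
    version: str
    parameters: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_enhancer_table(enhancers: Sequence[Enhancer], path: Path) -> None:
    rows = [
        {
            "enhancer_id": e.enhancer_id,
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "summit": e.summit,
            "signal_unstim": e.signal_unstim,
            "signal_stim": e.signal_stim,
            "overlaps_h3k27ac_peak": e.overlaps_h3k27ac_peak,
            "category": e.category,
        }
        for e in enhancers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_enhancer_table(path: str | Path) -> list[Enhancer]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(Enhancer(
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end),
                                     str(row.enhancer_id)),
            summit=int(row.summit),
            signal_unstim=None if pd.isna(row.signal_unstim) else float(row.signal_unstim),
            signal_stim=None if pd.isna(row.signal_stim) else float(row.signal_stim),
            overlaps_h3k27ac_peak=None if pd.isna(row.overlaps_h3k27ac_peak)
            else bool(row.overlaps_h3k27ac_peak),
            category=None if pd.isna(row.category) else str(row.category),
        ))
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.monotonic()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.monotonic() - t0)
            return result
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    checksums: dict[str, str] = {}
    fraction_inc: dict[str, float] = {}
    top_enrichment: dict[str, dict] = {}
    gene_dyn: dict | None = None

    @_stage("identify")
    def run_identify():
        peaks = read_bed(config.h3k4me1_peaks)
        genes = read_tss_table(config.genes)
        chip_s = read_bedgraph(config.h3k27ac_stim, config.quant.bin_size)
        enh = identify_enhancers(peaks, genes, config.quant, chip_s)
        return enh, genes, chip_s

    enhancers, genes, chip_stim = run_identify()
    stages["identify"] = "completed"

    @_stage("quantify")
    def run_quantify():
        chip_u = read_bedgraph(config.h3k27ac_unstim, config.quant.bin_size)
        inp_u = read_bedgraph(config.input_unstim, config.quant.bin_size)
        inp_s = read_bedgraph(config.input_stim, config.quant.bin_size)
        quantified = quantify_enhancers(
            enhancers, chip_u, chip_stim, inp_u, inp_s, config.quant
        )
        quantified = annotate_h3k27ac_overlap(
            quantified,
            read_bed(config.h3k27ac_peaks_unstim),
            read_bed(config.h3k27ac_peaks_stim),
            config.quant,
        )
        return quantified, chip_u, inp_u, inp_s

    enhancers, chip_unstim, input_unstim, input_stim = run_quantify()
    stages["quantify"] = "completed"

    @_stage("classify")
    def run_classify() -> tuple[list[Enhancer], CategorySummary]:
        annotated, summary = classify_all(enhancers, config.classify)
        write_enhancer_table(annotated, outdir / "categories.tsv")
        write_bed([dataclasses.replace(e.interval, name=e.enhancer_id,
                                       score=float(e.signal_stim or 0))
                   for e in annotated], outdir / "enhancers.bed")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        return annotated, summary

    enhancers, summary = run_classify()
    stages["classify"] = "completed"
    assignment = {e.enhancer_id: e.category for e in enhancers}

    if config.faire_unstim and config.faire_stim:
        @_stage("profile")
        def run_profile():
            faire_u = read_bedgraph(config.faire_unstim, config.quant.bin_size)
            faire_s = read_bedgraph(config.faire_stim, config.quant.bin_size)
            rows = []
            for cond, track in (("unstim", faire_u), ("stim", faire_s)):
                m = profile_matrix(track, enhancers, config.profile_flank,
                                   config.profile_bin, condition=cond)
                for cat, vec in aggregate_profile(m, assignment).items():
                    rows.append([cat, cond] + list(vec))
            ncols = 2 * config.profile_flank // config.profile_bin
            offsets = [
                -config.profile_flank + j * config.profile_bin for j in range(ncols)
            ]
            pd.DataFrame(rows, columns=["category", "condition"] + offsets).to_csv(
                outdir / "profiles.tsv", sep="\t", index=False, float_format="%.6g"
            )
            changes = [
                accessibility_change(faire_u, faire_s, e, config.quant.window,
                                     config.faire_increase_fold)
                for e in enhancers
            ]
            pd.DataFrame([dataclasses.asdict(c) for c in changes]).to_csv(
                outdir / "accessibility.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            return {
                cat: fraction_increased(changes, assignment, cat)
                for cat in ("increasing", "constant", "decreasing")
                if any(assignment[c.enhancer_id] == cat for c in changes)
            }

        fraction_inc = run_profile()
        stages["profile"] = "completed"
    else:
        stages["profile"] = "skipped: FAIRE tracks not provided"

    if config.genome_fasta:
        @_stage("enrich")
        def run_enrich():
            genome = read_fasta(config.genome_fasta)
            half = config.quant.window // 2
            seqs = {}
            for e in enhancers:
                chrom_seq = genome.get(e.interval.chrom, "")
                a, b = max(e.summit - half, 0), e.summit + half
                if b <= len(chrom_seq):
                    seqs[e.enhancer_id] = chrom_seq[a:b]
            motifs = (read_jaspar(config.motifs) if config.motifs
                      else default_motif_panel())
            top = {}
            for cat in config.enrich_categories:
                results = enrich_by_category(seqs, assignment, motifs, cat)
                pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                    outdir / f"enrichment_{cat}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                best = results[0]
                top[cat] = {"motif_id": best.motif_id, "p": best.p,
                            "q": best.q, "fold": best.fold}
            return top

        top_enrichment = run_enrich()
        stages["enrich"] = "completed"
    else:
        stages["enrich"] = "skipped: genome FASTA not provided"

    if config.expression:
        @_stage("gene_dynamics")
        def run_genes():
            table = pd.read_csv(config.expression, sep="\t")
            records = classify_de_genes(table)
            changes = [
                gene_ac_change(g, chip_unstim, chip_stim, input_unstim,
                               input_stim, params=config.quant)
                for g in genes
            ]
            merged = pd.merge(
                pd.DataFrame([dataclasses.asdict(c) for c in changes]),
                pd.DataFrame([dataclasses.asdict(r) for r in records]),
                on="gene_id",
            )
            merged.to_csv(outdir / "gene_changes.tsv", sep="\t", index=False,
                          float_format="%.6g")
            comp = compare_ac_by_de_class(changes, records)
            return {
                "group_means": comp["group_means"],
                "group_sizes": comp["group_sizes"],
                "ttest": dataclasses.asdict(comp["ttest"]),
            }

        gene_dyn = run_genes()
        stages["gene_dynamics"] = "completed"
    else:
        stages["gene_dynamics"] = "skipped: expression table not provided"

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "report.json":
            checksums[path.name] = _sha256(path)

    report = RunReport(
        stages=stages,
        checksums=checksums,
        category_summary=summary.as_dict(),
        fraction_increased=fraction_inc,
        top_enrichment=top_enrichment,
        gene_dynamics=gene_dyn,
        version=__version__,
        parameters=config.echo(),
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True, default=_jsonable)
    return report
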