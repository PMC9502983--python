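"""FAIRE accessibility around enhancer summits, per H3K27ac response class.

Runs the full pipeline on a small synthetic bundle, then prints the central
meta-profile density per category/condition and the fraction of each
category whose accessibility increased (fold >= 1.2 over the 1.5 kb summit
window) after stimulation.
"""

import tempfile
from pathlib import Path

import pandas as pd

from ecdyn.pipeline import PipelineConfig, run_pipeline
from ecdyn.simulate import SimulationConfig, generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=2_100_000,
                           n_enhancers=200)
    ds = generate_dataset(cfg, tmp / "data")
    report = run_pipeline(PipelineConfig(
        h3k4me1_peaks=ds.paths["h3k4me1_peaks"],
        genes=ds.paths["genes"],
        h3k27ac_unstim=ds.paths["h3k27ac_unstim"],
        h3k27ac_stim=ds.paths["h3k27ac_stim"],
        input_unstim=ds.paths["input_unstim"],
        input_stim=ds.paths["input_stim"],
        h3k27ac_peaks_unstim=ds.paths["h3k27ac_peaks_unstim"],
        h3k27ac_peaks_stim=ds.paths["h3k27ac_peaks_stim"],
        faire_unstim=ds.paths["faire_unstim"],
        faire_stim=ds.paths["faire_stim"],
        outdir=tmp / "run",
    ))

    profiles = pd.read_csv(tmp / "run" / "profiles.tsv", sep="\t")
    center = profiles.columns[2 + 60]  # column starting at the summit
    print("central FAIRE density (RPM/bp) at the summit, by category:")
    for _, row in profiles.iterrows():
        print(f"  {row.category:<13}{row.condition:<8}{row[center]:.3f}")
    print()
    print("fraction of enhancers with increased accessibility (fold >= 1.2):")
    for cat, frac in report.fraction_increased.items():
        print(f"  {cat:<13}{100 * frac:.1f}%")
    print()
    print("Increasing-H3K27ac enhancers open preferentially (the generator")
    print("couples 55% of them to a 2-fold accessibility gain); constant and")
    print("decreasing enhancers stay at their unstimulated accessibility.")
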