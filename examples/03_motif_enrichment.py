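"""Known-motif enrichment per enhancer category.

Scans enhancer sequences with a small PWM panel (an EcR-like inverted-repeat
response element, an Eip74-like ETS site, and neutral fillers) and tests
which motifs are over-represented among H3K27ac-increasing enhancers using a
hypergeometric presence/absence test with BH correction.
"""

import tempfile
from pathlib import Path

from ecdyn.io import read_fasta
from ecdyn.motifs import enrich_by_category, match_ecre_consensus
from ecdyn.simulate import (
    SYNTHETIC_ECRE_CONSENSUS,
    SimulationConfig,
    default_motif_panel,
    generate_dataset,
)

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=2_100_000,
                           n_enhancers=200)
    ds = generate_dataset(cfg, Path(tmp) / "data")
    genome = read_fasta(ds.paths["genome"])

    truth = ds.ground_truth.query("~is_decoy")
    seqs = {
        row.enhancer_id: genome[row.chrom][row.summit - 750:row.summit + 750]
        for row in truth.itertuples(index=False)
    }
    assignment = dict(zip(truth.enhancer_id, truth.category))

    results = enrich_by_category(seqs, assignment, default_motif_panel(),
                                 "increasing")
    print(f"{'motif':<12}{'hits in cat':>12}{'hits total':>12}"
          f"{'fold':>7}{'q':>12}")
    for r in results:
        print(f"{r.motif_id:<12}{r.k:>8}/{r.n:<4}{r.K:>8}/{r.N:<4}"
              f"{r.fold:>6.2f}{r.q:>12.2e}")

    n_ecre = sum(
        bool(match_ecre_consensus(seq, SYNTHETIC_ECRE_CONSENSUS, max_mismatch=1))
        for seq in seqs.values()
    )
    print()
    print(f"{n_ecre}/{len(seqs)} enhancer windows carry a degenerate-consensus")
    print(f"EcRE match ({SYNTHETIC_ECRE_CONSENSUS!r}, <=1 mismatch).")
    print("The receptor motif tops the increasing category because the")
    print("generator plants it in 60% of those enhancers vs 5% elsewhere.")
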