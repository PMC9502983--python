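import numpy as np
import pytest

from ecdyn.classification import classify_all
from ecdyn.discovery import QuantParams, annotate_h3k27ac_overlap, identify_enhancers, quantify_enhancers
from ecdyn.io import read_bed, read_bedgraph, read_fasta, read_tss_table
from ecdyn.motifs import scan_pwm
from ecdyn.simulate import (
    SYNTHETIC_ECRE_CONSENSUS,
    SimulationConfig,
    default_motif_panel,
    generate_dataset,
    plant_motif,
    render_track,
)


def small_config(**kw):
    defaults = dict(seed=7, n_chroms=1, chrom_length=700_000, n_enhancers=60,
                    n_qpcr_genes=2)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def run_classification(ds, bin_size=10):
    params = QuantParams(bin_size=bin_size)
    chip_s = read_bedgraph(ds.paths["h3k27ac_stim"], bin_size)
    enh = identify_enhancers(
        read_bed(ds.paths["h3k4me1_peaks"]),
        read_tss_table(ds.paths["genes"]),
        params,
        chip_s,
    )
    enh = quantify_enhancers(
        enh,
        read_bedgraph(ds.paths["h3k27ac_unstim"], bin_size),
        chip_s,
        read_bedgraph(ds.paths["input_unstim"], bin_size),
        read_bedgraph(ds.paths["input_stim"], bin_size),
        params,
    )
    enh = annotate_h3k27ac_overlap(
        enh,
        read_bed(ds.paths["h3k27ac_peaks_unstim"]),
        read_bed(ds.paths["h3k27ac_peaks_stim"]),
        params,
    )
    return classify_all(enh)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        ds1 = generate_dataset(small_config(), tmp_path / "a")
        ds2 = generate_dataset(small_config(), tmp_path / "b")
        for key, p1 in ds1.paths.items():
            assert p1.read_bytes() == ds2.paths[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        ds1 = generate_dataset(small_config(seed=7), tmp_path / "a")
        ds2 = generate_dataset(small_config(seed=8), tmp_path / "b")
        assert (ds1.paths["h3k27ac_stim"].read_bytes()
                != ds2.paths["h3k27ac_stim"].read_bytes())


class TestPlantMotif:
    def test_planted_consensus_is_found_by_scan(self):
        pwm = default_motif_panel()[1]  # sharp non-degenerate consensus
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        planted = plant_motif(seq, pwm, 100)
        assert any(h.offset == 100 and h.strand == "+" for h in scan_pwm(planted, pwm))

    def test_disrupting_the_planted_window_removes_the_hit(self):
        pwm = default_motif_panel()[1]
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        planted = plant_motif(seq, pwm, 100)
        L = len(pwm)
        shuffled = list(planted[100:100 + L])
        shuffled = "".join([shuffled[i] for i in [4, 2, 7, 0, 8, 5, 1, 6, 3][:L]])
        disrupted = planted[:100] + shuffled + planted[100 + L:]
        assert not any(h.offset == 100 and h.strand == "+"
                       for h in scan_pwm(disrupted, pwm))

    def test_degenerate_consensus_plants_deterministic_letters(self):
        out = plant_motif("T" * 20, SYNTHETIC_ECRE_CONSENSUS, 2)
        assert out[2:2 + len(SYNTHETIC_ECRE_CONSENSUS)] == "AGGTCAATGACCC"

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            plant_motif("ACGT", "AGGTCA", 2)

    def test_planting_rate_matches_configuration(self, tmp_path):
        cfg = small_config(
            n_chroms=1, chrom_length=2_100_000, n_enhancers=200,
            category_fractions={"increasing": 1.0, "decreasing": 0.0,
                                "constant": 0.0, "no_response": 0.0,
                                "unclassified": 0.0},
        )
        ds = generate_dataset(cfg, tmp_path / "d")
        genome = read_fasta(ds.paths["genome"])
        ecr = default_motif_panel()[0]
        truth = ds.ground_truth[~ds.ground_truth.is_decoy]
        n_hit = 0
        for row in truth.itertuples(index=False):
            window = genome[row.chrom][row.summit - 750:row.summit + 750]
            if scan_pwm(window, ecr):
                n_hit += 1
        rate = n_hit / len(truth)
        # 0.60 planted exactly; chance hits can only add a little
        assert 0.58 <= rate <= 0.70
        assert truth.has_ecr_motif.mean() == pytest.approx(0.60, abs=0.005)


class TestRenderTrack:
    def test_single_bump_argmax_at_planted_position(self, rng):
        track = render_track([("chr1", 5000, 500.0)], {"chr1": 10_000},
                             sigma=150.0, background_rate=0.0, bin_size=10,
                             rng=rng)
        assert abs(int(np.argmax(track.values["chr1"])) * 10 + 5 - 5000) <= 10

    def test_zero_amplitude_is_pure_poisson_background(self, rng):
        track = render_track([], {"chr1": 100_000}, sigma=150.0,
                             background_rate=2.0, bin_size=10, rng=rng)
        mean = track.values["chr1"].mean()
        assert mean == pytest.approx(2.0, abs=0.05)  # 10,000 bins

    def test_windowed_signal_is_linear_in_amplitude(self, rng):
        t1 = render_track([("chr1", 5000, 400.0)], {"chr1": 10_000}, 150.0,
                          0.0, 10, np.random.default_rng(5))
        t2 = render_track([("chr1", 5000, 800.0)], {"chr1": 10_000}, 150.0,
                          0.0, 10, np.random.default_rng(5))
        w1 = t1.region_reads("chr1", 4250, 5750)
        w2 = t2.region_reads("chr1", 4250, 5750)
        assert w2 == pytest.approx(2 * w1, rel=1e-9)

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            render_track([("chr1", 100, -1.0)], {"chr1": 1000}, 50.0, 0.0, 10, rng)


class TestGroundTruthRecovery:
    def test_saturated_increasing_config(self, tmp_path):
        cfg = small_config(
            category_fractions={"increasing": 1.0, "decreasing": 0.0,
                                "constant": 0.0, "no_response": 0.0,
                                "unclassified": 0.0},
        )
        ds = generate_dataset(cfg, tmp_path / "d")
        annotated, summary = run_classification(ds)
        # the strict bottom-quartile gate necessarily withholds ~25% of an
        # all-increasing population; nothing may land in any other class
        assert set(summary.counts) - {c for c, n in summary.counts.items() if n == 0} \
            <= {"increasing", "unclassified"}
        assert 0.70 <= summary.fractions["increasing"] <= 0.80

    def test_default_fraction_recovery_small_scale(self, tmp_path):
        cfg = small_config(n_chroms=1, chrom_length=2_100_000, n_enhancers=200,
                           seed=11)
        ds = generate_dataset(cfg, tmp_path / "d")
        annotated, summary = run_classification(ds)
        truth = ds.ground_truth.set_index("enhancer_id").category
        matched = [e for e in annotated if truth[e.enhancer_id] != "decoy"]
        acc = np.mean([e.category == truth[e.enhancer_id] for e in matched])
        assert acc >= 0.90
        # promoter-proximal decoys must have been rejected by discovery
        assert not any(e.enhancer_id.startswith("decoy") for e in annotated)

    def test_genome_too_small_raises(self, tmp_path):
        with pytest.raises(ValueError, match="too small"):
            generate_dataset(small_config(chrom_length=100_000), tmp_path / "d")
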