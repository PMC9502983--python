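import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from conftest import make_track, per_base_region_reads
from ecdyn.genes import (
    classify_de_genes,
    compare_ac_by_de_class,
    gene_ac_change,
    gene_region,
    t_critical,
    two_sample_t,
    GeneAcChange,
)
from ecdyn.io import GeneModel, GenomicInterval


def expr_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "expr_unstim", "expr_stim"])


class TestDeGenes:
    def test_symmetric_inclusive_fold_boundaries(self):
        records = classify_de_genes(
            expr_table([("a", 10, 15), ("b", 15, 10), ("c", 10, 12)])
        )
        assert [r.de_class for r in records] == ["up", "down", "unchanged"]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="expr_stim"):
            classify_de_genes(pd.DataFrame({"gene_id": [], "expr_unstim": []}))

    def test_condition_swap_is_an_involution(self, rng):
        table = expr_table([
            (f"g{i}", float(u), float(s))
            for i, (u, s) in enumerate(
                zip(rng.lognormal(3, 1, 50), rng.lognormal(3, 1, 50))
            )
        ])
        fwd = classify_de_genes(table)
        swapped = table.rename(
            columns={"expr_unstim": "expr_stim", "expr_stim": "expr_unstim"}
        )
        rev = classify_de_genes(swapped)
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert [r.de_class for r in rev] == [flip[r.de_class] for r in fwd]


def plus_gene(start=5000, end=8000):
    return GeneModel("g", "chr1", "+", start, GenomicInterval("chr1", start, end))


def minus_gene(start=5000, end=8000):
    return GeneModel("g", "chr1", "-", end - 1, GenomicInterval("chr1", start, end))


class TestGeneAcChange:
    def test_region_rule_strand_aware(self):
        assert gene_region(plus_gene()) == (3000, 8000)
        assert gene_region(minus_gene()) == (5000, 10000)
        assert gene_region(plus_gene(), "promoter") == (4000, 6001)

    def test_doubling_gives_log2_of_about_one(self):
        chip_u = make_track({"chr1": np.full(1500, 10.0)}, library_size=1e6)
        chip_s = make_track({"chr1": np.full(1500, 20.0)}, library_size=1e6)
        inp = make_track({"chr1": np.full(1500, 0.01)}, library_size=1e6)
        c = gene_ac_change(plus_gene(), chip_u, chip_s, inp, inp)
        # signals are large so the pseudocount barely matters
        assert c.log2_change == pytest.approx(1.0, abs=0.01)

    def test_unchanged_signal_gives_zero(self):
        chip = make_track({"chr1": np.full(1500, 10.0)}, library_size=1e6)
        inp = make_track({"chr1": np.full(1500, 1.0)}, library_size=1e6)
        c = gene_ac_change(plus_gene(), chip, chip, inp, inp)
        assert c.log2_change == 0.0

    def test_matches_per_base_oracle(self, rng):
        vals = {name: rng.uniform(0, 5, size=1500) for name in "abcd"}
        tracks = {k: make_track({"chr1": v}) for k, v in vals.items()}
        gene = minus_gene(4321, 7654)
        c = gene_ac_change(gene, tracks["a"], tracks["b"], tracks["c"], tracks["d"])
        start, end = gene_region(gene)

        def oracle_sig(chip, inp):
            cr = per_base_region_reads(chip, "chr1", start, end) * 1e6 / chip.library_size
            ir = per_base_region_reads(inp, "chr1", start, end) * 1e6 / inp.library_size
            return cr / max(ir, 0.5)

        ac_u = oracle_sig(tracks["a"], tracks["c"])
        ac_s = oracle_sig(tracks["b"], tracks["d"])
        assert c.log2_change == pytest.approx(
            np.log2((ac_s + 0.5) / (ac_u + 0.5)), rel=1e-9
        )


class TestTwoSampleT:
    def test_hand_computed_example(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4

    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert not res.significant

    def test_antisymmetry(self, rng):
        x = list(rng.normal(0, 1, 5))
        y = list(rng.normal(1, 1, 7))
        assert two_sample_t(x, y).t == -two_sample_t(y, x).t

    def test_zero_variance_unequal_means(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.significant

    def test_critical_value_alpha05_df4_rounds_to_2_78(self):
        assert round(t_critical(0.05, 4), 2) == 2.78

    @pytest.mark.parametrize("df", [2, 4, 10])
    def test_p_agrees_with_numerical_integration_of_t_density(self, df):
        # build sample pairs that realize a chosen t exactly, then compare the
        # returned two-sided p against direct quadrature of the t density
        n = (df + 2) // 2
        base = np.linspace(-1.0, 1.0, n)
        se = np.sqrt(base.var(ddof=1) * 2.0 / n)
        for t_target in (-10.0, -2.5, -0.3, 0.7, 4.2, 10.0):
            mu = t_target * se
            res = two_sample_t(base + mu, base)
            assert res.t == pytest.approx(t_target, rel=1e-10)
            tail, _ = quad(lambda x: stats.t.pdf(x, df), abs(t_target), np.inf)
            assert res.p == pytest.approx(2.0 * tail, abs=1e-8)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestCompareByDeClass:
    def _records(self, n_up, n_down, n_flat=0):
        rows = []
        rows += [(f"u{i}", 10.0, 20.0) for i in range(n_up)]
        rows += [(f"d{i}", 20.0, 10.0) for i in range(n_down)]
        rows += [(f"f{i}", 10.0, 10.0) for i in range(n_flat)]
        return classify_de_genes(expr_table(rows))

    def test_planted_effect_recovered(self, rng):
        records = self._records(50, 50)
        changes = [
            GeneAcChange(r.gene_id, 1, 1,
                         float(rng.normal(1.0 if r.de_class == "up" else -1.0, 0.5)))
            for r in records
        ]
        out = compare_ac_by_de_class(changes, records)
        assert out["group_means"]["up"] > 0 > out["group_means"]["down"]
        assert out["ttest"].p < 0.05

    def test_all_zero_changes_not_significant(self):
        records = self._records(5, 5)
        changes = [GeneAcChange(r.gene_id, 1, 1, 0.0) for r in records]
        out = compare_ac_by_de_class(changes, records)
        assert out["group_means"]["up"] == 0.0
        assert not out["ttest"].significant

    def test_permuted_labels_rarely_significant(self, rng):
        records = self._records(30, 30)
        values = rng.normal(0.0, 1.0, size=60)
        n_sig = 0
        n_perm = 300
        for _ in range(n_perm):
            v = rng.permutation(values)
            if two_sample_t(v[:30], v[30:]).p < 0.05:
                n_sig += 1
        assert n_sig / n_perm <= 0.09  # ~alpha plus seeded binomial slack

    def test_small_class_raises(self):
        records = self._records(1, 5)
        changes = [GeneAcChange(r.gene_id, 1, 1, 0.0) for r in records]
        with pytest.raises(ValueError):
            compare_ac_by_de_class(changes, records)
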