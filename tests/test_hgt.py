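import numpy as np
import pytest

from panflux.hgt import (
    anchor_match,
    codon_usage_windows,
    detect_outlier_windows,
    gc_windows,
    pca,
    sliding_window_starts,
)
from panflux.io_qc import GeneRecord
from panflux.simulate import SimConfig, simulate_genome_with_hgt


def _gene(gene_id, cds, start, strand="+"):
    return GeneRecord(
        gene_id=gene_id, strain="s", cds=cds, contig="c", start=start,
        end=start + len(cds), strand=strand,
    )


class TestGcWindows:
    def test_uniform_sequence_has_zero_deviation(self):
        df = gc_windows("ATGC" * 2500, window=5000)
        assert len(df) == 2
        assert df["gc"].tolist() == [0.5, 0.5]
        assert df["deviation"].tolist() == [0.0, 0.0]

    def test_half_at_half_g_deviations(self):
        df = gc_windows("A" * 5000 + "G" * 5000, window=5000)
        assert df["deviation"].tolist() == [-0.5, 0.5]

    def test_short_tail_merged_into_previous_window(self):
        df = gc_windows("A" * 12000, window=5000)  # tail of 2000 < half window
        assert df["end"].tolist() == [5000, 12000]

    def test_long_tail_kept_as_partial_window(self):
        df = gc_windows("A" * 13000, window=5000)
        assert df["end"].tolist() == [5000, 10000, 13000]

    def test_length_weighted_mean_deviation_is_zero(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.3, 0.2], size=23456))
        df = gc_windows(seq, window=5000)
        lengths = (df["end"] - df["start"]).to_numpy()
        assert abs(np.average(df["deviation"], weights=lengths)) < 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_windows("")


class TestCodonUsageWindows:
    def test_hand_counted_frequencies(self):
        fcu = codon_usage_windows(20000, [_gene("g", "ATGGCTGCTTAA", 100)])
        row = fcu.frequencies.iloc[0]
        assert row["ATG"] == pytest.approx(1 / 3)
        assert row["GCT"] == pytest.approx(2 / 3)
        assert row.sum() == pytest.approx(1.0)
        assert len(row) == 61

    def test_exact_half_overlap_excluded(self):
        gene = _gene("g", "AAA" * 2000, 17000)  # 6 kb gene, 3 kb in window 1
        fcu = codon_usage_windows(40000, [gene], window=20000, step=10000)
        assert fcu.windows["n_genes"].tolist() == [0, 1, 0]

    def test_window_tiling_arithmetic(self):
        assert sliding_window_starts(50000, 20000, 10000) == [
            (0, 20000), (10000, 30000), (20000, 40000), (30000, 50000),
        ]
        # 55 kb: final partial window of 15 kb (> half) retained
        assert sliding_window_starts(55000, 20000, 10000)[-1] == (40000, 55000)

    def test_ambiguous_codons_excluded_entirely(self):
        fcu = codon_usage_windows(20000, [_gene("g", "ATGNNNGCT", 0)])
        row = fcu.frequencies.iloc[0]
        assert row["ATG"] == pytest.approx(0.5)
        assert row["GCT"] == pytest.approx(0.5)

    def test_mismatched_gene_skipped_with_warning(self):
        bad = GeneRecord(gene_id="g", strain="s", cds="ATGGCT", contig="c",
                         start=0, end=100, strand="+")
        with pytest.warns(UserWarning, match="mismatch"):
            fcu = codon_usage_windows(20000, [bad])
        assert fcu.windows["n_genes"].tolist() == [0]


class TestPca:
    def test_identical_rows_give_zero_scores(self):
        import pandas as pd

        mat = pd.DataFrame(np.tile(np.full(61, 1 / 61), (5, 1)))
        with pytest.warns(UserWarning, match="identical"):
            result = pca(mat)
        assert np.allclose(result.scores.to_numpy(), 0)
        assert np.allclose(result.variance_fraction, 0)

    def test_two_distinct_rows_put_all_variance_on_pc1(self):
        import pandas as pd

        a = np.zeros(61); a[0] = 1.0
        b = np.zeros(61); b[1] = 1.0
        mat = pd.DataFrame([a, a, b, b])
        result = pca(mat)
        assert result.variance_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_and_variance_identities(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        x = rng.dirichlet(np.ones(61), size=50)
        result = pca(pd.DataFrame(x))
        assert result.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(result.variance_fraction) <= 1e-12).all()
        recon = result.scores.to_numpy() @ result.loadings
        assert np.allclose(recon, x - x.mean(axis=0), atol=1e-8)


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seq_seed=99)
    sim = simulate_genome_with_hgt(cfg)
    fcu = codon_usage_windows(len(sim.sequence), sim.genes)
    return sim, fcu, pca(fcu)


class TestDetection:
    def test_planted_region_recovered_within_one_step(self, planted):
        sim, fcu, result = planted
        gc = gc_windows(sim.sequence)
        calls = detect_outlier_windows(result, fcu, gc_table=gc)
        assert len(calls) == 1
        call = calls[0]
        mid = (call.start + call.end) // 2
        assert sim.region.start <= mid < sim.region.end
        assert abs(call.start - sim.region.start) <= 10000
        assert abs(call.end - sim.region.end) <= 10000
        assert abs(call.mean_gc - 0.46) < 0.02

    def test_infinite_threshold_gives_no_calls(self, planted):
        _, fcu, result = planted
        assert detect_outlier_windows(result, fcu, threshold=np.inf) == []

    def test_null_genome_gives_no_calls(self):
        cfg = SimConfig(seq_seed=7, donor_gc=0.5305)
        sim = simulate_genome_with_hgt(cfg)
        fcu = codon_usage_windows(len(sim.sequence), sim.genes)
        assert detect_outlier_windows(pca(fcu), fcu) == []


class TestAnchorMatch:
    def test_identical_genomes_one_full_chain(self):
        rng = np.random.default_rng(3)
        g = "".join(rng.choice(list("ACGT"), size=50000))
        chains = anchor_match(g, g, min_chain=5000)
        assert len(chains) == 1
        assert chains.loc[0, "astart"] == 0
        assert chains.loc[0, "aend"] == 50000
        assert chains.loc[0, "strand"] == "+"

    def test_unrelated_genomes_no_chains(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = "".join(rng.choice(list("ACGT"), size=100000))
            b = "".join(rng.choice(list("ACGT"), size=100000))
            assert anchor_match(a, b).empty

    def test_embedded_segment_recovered_on_both_genomes(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(list("ACGT"), size=100000))
        b = "".join(rng.choice(list("ACGT"), size=100000))
        b = b[:20000] + a[10000:60000] + b[20000:50000]
        chains = anchor_match(a, b)
        assert len(chains) == 1
        row = chains.iloc[0]
        assert abs(row["astart"] - 10000) <= 21 and abs(row["aend"] - 60000) <= 21
        assert abs(row["bstart"] - 20000) <= 21 and abs(row["bend"] - 70000) <= 21

    def test_reverse_complement_segment_found_on_minus_strand(self):
        from panflux.codons import revcomp

        rng = np.random.default_rng(13)
        a = "".join(rng.choice(list("ACGT"), size=60000))
        b = "".join(rng.choice(list("ACGT"), size=20000)) + revcomp(a[5000:25000])
        chains = anchor_match(a, b)
        assert len(chains) == 1
        assert chains.iloc[0]["strand"] == "-"

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            anchor_match("ACGT" * 100, "ACGT" * 100, k=20)

    def test_k_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            anchor_match("ACGT", "ACGT" * 100, k=21)
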