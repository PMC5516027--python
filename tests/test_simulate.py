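import numpy as np
import pytest

from panflux.codons import STOP_CODONS, gc_biased_codon_profile, SENSE_GC_COUNT
from panflux.simulate import (
    SimConfig,
    emit_family_sequences,
    gc_content,
    simulate_gene_content,
    simulate_genome_with_hgt,
    simulate_tree,
    tree_to_newick,
)


class TestSimConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate_loss"):
            SimConfig(rate_loss=-0.1)

    def test_region_must_fit_in_genome(self):
        with pytest.raises(ValueError, match="region_len"):
            SimConfig(region_len=100, genome_len=100)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            SimConfig(n_taxa=1)


class TestSimulateTree:
    def test_smallest_tree(self):
        tree = simulate_tree(2, seed=1)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        assert all(leaf.edge.length > 0 for leaf in leaves)

    def test_deterministic_per_seed(self):
        assert tree_to_newick(simulate_tree(8, 7)) == tree_to_newick(simulate_tree(8, 7))

    def test_different_seeds_differ(self):
        assert tree_to_newick(simulate_tree(8, 7)) != tree_to_newick(simulate_tree(8, 8))

    def test_all_branch_lengths_positive(self):
        tree = simulate_tree(12, 3)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0
        assert sum(1 for _ in tree.leaf_node_iter()) == 12

    def test_one_taxon_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=1)


class TestGeneContent:
    def test_no_event_limit(self):
        cfg = SimConfig(rate_gain=0, rate_loss=0, rate_expand=0, rate_reduce=0, root_families=5)
        tree = simulate_tree(cfg.n_taxa, cfg.tree_seed)
        content, log = simulate_gene_content(tree, cfg)
        for profile in content.values():
            assert profile == log.root_content
        assert log.events == {}

    def test_event_log_replays_to_leaf_profiles(self):
        cfg = SimConfig(rate_gain=3.0, rate_loss=0.1, rate_expand=0.05, rate_reduce=0.05)
        tree = simulate_tree(cfg.n_taxa, cfg.tree_seed)
        content, log = simulate_gene_content(tree, cfg)
        assert log.replay(tree) == content

    def test_mean_leaf_families_decrease_with_loss_rate(self):
        # monotone effect of the loss rate on surviving family counts
        means = []
        for rate_loss in (0.0, 0.5, 2.0):
            counts = []
            for seed in range(40):
                cfg = SimConfig(
                    n_taxa=4,
                    root_families=40,
                    rate_gain=0,
                    rate_loss=rate_loss,
                    rate_expand=0,
                    rate_reduce=0,
                    tree_seed=seed,
                    content_seed=seed + 1000,
                )
                tree = simulate_tree(cfg.n_taxa, cfg.tree_seed)
                content, _ = simulate_gene_content(tree, cfg)
                counts.extend(len(p) for p in content.values())
            means.append(np.mean(counts))
        assert means[0] > means[1] > means[2]

    def test_determinism(self):
        cfg = SimConfig()
        tree = simulate_tree(cfg.n_taxa, cfg.tree_seed)
        c1, l1 = simulate_gene_content(tree, cfg)
        c2, l2 = simulate_gene_content(simulate_tree(cfg.n_taxa, cfg.tree_seed), cfg)
        assert c1 == c2 and l1.events == l2.events


@pytest.fixture(scope="module")
def small_run():
    cfg = SimConfig(n_taxa=3, root_families=8, rate_gain=0.5, rate_loss=0.02,
                    rate_expand=0.02, rate_reduce=0.0, substitution_rate=0.05)
    tree = simulate_tree(cfg.n_taxa, cfg.tree_seed)
    content, _ = simulate_gene_content(tree, cfg)
    return cfg, tree, content


class TestEmitSequences:
    def test_zero_substitution_rate_gives_identical_members(self, small_run):
        cfg, tree, content = small_run
        cfg0 = SimConfig(**{**cfg.__dict__, "substitution_rate": 0.0})
        cds, _, truth = emit_family_sequences(content, tree, cfg0)
        by_family = {}
        for strain, records in cds.items():
            for gid, seq in records:
                by_family.setdefault(truth[gid], set()).add(seq)
        assert all(len(seqs) == 1 for seqs in by_family.values())

    def test_proteins_pass_qc_by_construction(self, small_run):
        cfg, tree, content = small_run
        cds, prots, _ = emit_family_sequences(content, tree, cfg)
        for strain in prots:
            for (gid, protein), (_, c) in zip(prots[strain], cds[strain]):
                assert len(protein) >= 50
                assert "*" not in protein
                assert len(c) == 3 * len(protein)
                for i in range(0, len(c) - 3, 3):
                    assert c[i : i + 3] not in STOP_CODONS

    def test_within_family_identity_exceeds_between(self, small_run):
        cfg, tree, content = small_run
        cds, prots, truth = emit_family_sequences(content, tree, cfg)
        prot_of = {gid: p for strain in prots for gid, p in prots[strain]}
        genes = sorted(prot_of)

        def identity(a, b):
            n = min(len(a), len(b))
            return sum(x == y for x, y in zip(a[:n], b[:n])) / n

        within, between = [], []
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1 :]:
                ident = identity(prot_of[g1], prot_of[g2])
                (within if truth[g1] == truth[g2] else between).append(ident)
        assert min(within) > max(between)


@pytest.fixture(scope="module")
def sim():
    return simulate_genome_with_hgt(SimConfig(genome_len=2_000_000, region_len=150_000))


class TestGenomeWithHgt:
    def test_region_gc_hits_target_band(self, sim):
        region_seq = sim.sequence[sim.region.start : sim.region.end]
        assert 0.45 <= gc_content(region_seq) <= 0.47

    def test_host_gc_hits_target_band(self, sim):
        host_seq = sim.sequence[: sim.region.start]
        assert abs(gc_content(host_seq) - 0.5305) < 0.01

    def test_genes_non_overlapping_in_bounds_stranded(self, sim):
        prev_end = 0
        for g in sorted(sim.genes, key=lambda g: g.start):
            assert 0 <= g.start < g.end <= len(sim.sequence)
            assert g.start >= prev_end
            assert g.strand in "+-"
            prev_end = g.end

    def test_cds_matches_genome_slice(self, sim):
        from panflux.codons import revcomp

        for g in sim.genes[:50]:
            sl = sim.sequence[g.start : g.end]
            assert g.cds == (sl if g.strand == "+" else revcomp(sl))

    def test_donor_profile_sums_to_one(self, sim):
        assert np.isclose(sum(sim.region.donor_profile), 1.0)

    def test_determinism_byte_identical(self):
        cfg = SimConfig(genome_len=100_000, region_len=20_000)
        a = simulate_genome_with_hgt(cfg)
        b = simulate_genome_with_hgt(cfg)
        assert a.sequence == b.sequence
        assert a.region == b.region


def test_gc_biased_profile_achieves_target():
    for target in (0.3, 0.4597, 0.5305, 0.7):
        profile = gc_biased_codon_profile(target)
        assert np.isclose(profile @ SENSE_GC_COUNT / 3.0, target, atol=1e-9)
        assert np.isclose(profile.sum(), 1.0)
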