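"""Synthetic data with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`simulate_tree` — a random rooted binary tree with branch lengths,
  standing in for an externally inferred species tree.
* :func:`simulate_gene_content` — gene-family copy numbers evolving along the
  tree under a Gillespie process with four event types (gain of a new family,
  loss of an existing one, copy-number expansion, copy-number reduction). The
  exact per-branch event log is returned so inference can be scored against
  truth.
* :func:`emit_family_sequences` — one ancestral CDS per family, mutated along
  root-to-leaf path lengths with stop-avoiding substitutions, so that
  clustering the resulting proteins back into families is non-trivial but
  solvable.
* :func:`simulate_genome_with_hgt` — a gene-dense host genome (default GC
  0.5305, the composition of a typical high-GC *Paenibacillus* chromosome)
  carrying one contiguous donor region of contrasting composition (default GC
  0.4597 over 150 kb in a 2 Mb genome), emulating a horizontally transferred
  island detectable from GC and codon-usage anomalies.

Gains draw fresh family ids from an unbounded pool (a lost family is never
re-gained), which keeps ground-truth event recovery free of homoplasy
ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .codons import (
    N_SENSE,
    SENSE_CODONS,
    codons_to_string,
    count_sense_codons,
    gc_biased_codon_profile,
    revcomp,
)
from .io_qc import GeneRecord

_ATG = SENSE_CODONS.index("ATG")


@dataclass
class SimConfig:
    """Simulation knobs; identical config + seeds gives byte-identical output.

    Rates are events per unit branch length: ``rate_gain`` is genome-wide
    (new-family arrivals), the other three apply per eligible family.
    """

    n_taxa: int = 8
    tree_seed: int = 1
    content_seed: int = 2
    seq_seed: int = 3
    rate_gain: float = 5.0
    rate_loss: float = 0.02
    rate_expand: float = 0.01
    rate_reduce: float = 0.01
    root_families: int = 200
    substitution_rate: float = 0.05
    host_gc: float = 0.5305
    donor_gc: float = 0.4597
    region_len: int = 150_000
    genome_len: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for name in ("rate_gain", "rate_loss", "rate_expand", "rate_reduce"):
            r = getattr(self, name)
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.root_families < 0:
            raise ValueError("root_families must be >= 0")
        if not (0 < self.host_gc < 1 and 0 < self.donor_gc < 1):
            raise ValueError("GC targets must be in (0, 1)")
        if self.region_len >= self.genome_len:
            raise ValueError("region_len must be smaller than genome_len")


@dataclass
class TrueEventLog:
    """Ground-truth events per branch (keyed by the branch's child node label)."""

    root_content: dict[str, int]
    events: dict[str, list[tuple[str, str]]]  # child label -> [(family, event)]

    def replay(self, tree: dendropy.Tree) -> dict[str, dict[str, int]]:
        """Re-apply the log from the root; returns per-leaf family counts."""
        leaves: dict[str, dict[str, int]] = {}

        def walk(node, state: dict[str, int]) -> None:
            label = _node_label(node)
            if node.parent_node is not None:
                state = dict(state)
                for fam, ev in self.events.get(label, []):
                    if ev == "gain":
                        state[fam] = 1
                    elif ev == "loss":
                        state.pop(fam, None)
                    elif ev == "expansion":
                        state[fam] += 1
                    elif ev == "reduction":
                        state[fam] -= 1
            if node.is_leaf():
                leaves[label] = {f: c for f, c in state.items() if c > 0}
            else:
                for child in node.child_nodes():
                    walk(child, state)

        walk(tree.seed_node, dict(self.root_content))
        return leaves

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class PlantedRegion:
    """Coordinates and codon profile of the simulated donor island."""

    start: int
    end: int
    donor_profile: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths.

    Topology is built by repeatedly joining two uniformly chosen subtrees
    (a random coalescent-style shape); branch lengths are Exp(mean 0.1) plus a
    0.01 floor so every branch is strictly positive. Leaves are labelled
    T1..Tn, internal nodes N1..N(n-1) in creation order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_taxa)])
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        nodes.append(node)
    next_internal = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.label = f"N{next_internal}"
        next_internal += 1
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

def _evolve_branch(
    state: dict[str, int],
    blen: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    counter: list[int],
) -> list[tuple[str, str]]:
    """Gillespie simulation of one branch; mutates ``state`` in place."""
    events: list[tuple[str, str]] = []
    t = 0.0
    while True:
        present = sorted(f for f, c in state.items() if c >= 1)
        multi = [f for f in present if state[f] >= 2]
        total = (
            cfg.rate_gain
            + len(present) * (cfg.rate_loss + cfg.rate_expand)
            + len(multi) * cfg.rate_reduce
        )
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= blen:
            break
        u = rng.uniform(0.0, total)
        if u < cfg.rate_gain:
            counter[0] += 1
            fam = f"G{counter[0]:05d}"
            state[fam] = 1
            events.append((fam, "gain"))
            continue
        u -= cfg.rate_gain
        if u < len(present) * cfg.rate_loss:
            fam = present[int(u / cfg.rate_loss)]
            del state[fam]
            events.append((fam, "loss"))
            continue
        u -= len(present) * cfg.rate_loss
        if u < len(present) * cfg.rate_expand:
            fam = present[int(u / cfg.rate_expand)]
            state[fam] += 1
            events.append((fam, "expansion"))
            continue
        u -= len(present) * cfg.rate_expand
        fam = multi[int(u / cfg.rate_reduce)]
        state[fam] -= 1
        events.append((fam, "reduction"))
    return events


def simulate_gene_content(
    tree: dendropy.Tree, config: SimConfig
) -> tuple[dict[str, dict[str, int]], TrueEventLog]:
    """Evolve family copy numbers along the tree.

    Returns (leaf profiles, event log): ``leaf profiles`` maps leaf label to
    {family: count > 0}; the log replays exactly to the leaf profiles.
    """
    rng = np.random.default_rng(config.content_seed)
    root_content = {f"F{i + 1:05d}": 1 for i in range(config.root_families)}
    counter = [0]
    events: dict[str, list[tuple[str, str]]] = {}
    leaves: dict[str, dict[str, int]] = {}

    def walk(node: dendropy.Node, state: dict[str, int]) -> None:
        if node.parent_node is not None:
            state = dict(state)
            ev = _evolve_branch(state, node.edge.length, config, rng, counter)
            if ev:
                events[_node_label(node)] = ev
        if node.is_leaf():
            leaves[_node_label(node)] = dict(state)
        else:
            for child in node.child_nodes():
                walk(child, state)

    walk(tree.seed_node, root_content)
    return leaves, TrueEventLog(root_content=root_content, events=events)


# ---------------------------------------------------------------------------
# family sequences
# ---------------------------------------------------------------------------

def _mutate_cds(cols: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_sub`` codon-level substitutions avoiding stop codons.

    Substitutions are drawn at the codon level: a mutated codon is replaced by
    a random *different* sense codon at Hamming distance 1 when possible,
    which is equivalent to single-base substitution with stop-avoiding
    resampling.
    """
    cols = cols.copy()
    if n_sub <= 0:
        return cols
    pos = rng.integers(0, cols.size * 3, size=n_sub)
    for p in pos:
        ci, within = divmod(int(p), 3)
        codon = list(SENSE_CODONS[cols[ci]])
        for _ in range(10):
            new_base = "ACGT"[rng.integers(0, 4)]
            if new_base == codon[within]:
                continue
            cand = codon.copy()
            cand[within] = new_base
            cand_s = "".join(cand)
            if cand_s in SENSE_CODONS:
                cols[ci] = SENSE_CODONS.index(cand_s)
                break
    return cols


def emit_family_sequences(
    content: dict[str, dict[str, int]],
    tree: dendropy.Tree,
    config: SimConfig,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, list[tuple[str, str]]], dict[str, str]]:
    """Per-strain CDS and protein FASTA records for the leaf family contents.

    Returns (cds_by_strain, protein_by_strain, true_family_of_gene). Headers
    are ``{strain}|{family}|{copy}``; every protein is 100-400 aa, starts with
    M and contains no internal stop by construction.
    """
    if not content:
        raise ValueError("content is empty")
    from Bio.Seq import Seq

    rng = np.random.default_rng(config.seq_seed)
    families = sorted({f for prof in content.values() for f in prof})
    depth = {leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}

    ancestral: dict[str, np.ndarray] = {}
    for fam in families:
        n_codons = int(rng.integers(100, 301))
        cols = rng.integers(0, N_SENSE, size=n_codons)
        cols[0] = _ATG
        ancestral[fam] = cols

    cds_by_strain: dict[str, list[tuple[str, str]]] = {}
    prot_by_strain: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}
    for strain in sorted(content):
        d = depth[strain]
        cds_list: list[tuple[str, str]] = []
        prot_list: list[tuple[str, str]] = []
        for fam in sorted(content[strain]):
            count = content[strain][fam]
            for copy in range(1, count + 1):
                cols = ancestral[fam]
                p_sub = 1.0 - np.exp(-config.substitution_rate * d)
                n_sub = int(rng.binomial(cols.size * 3, p_sub))
                mutated = _mutate_cds(cols, n_sub, rng)
                cds = codons_to_string(mutated)
                gene_id = f"{strain}|{fam}|{copy}"
                cds_list.append((gene_id, cds))
                prot_list.append((gene_id, str(Seq(cds).translate())))
                truth[gene_id] = fam
        cds_by_strain[strain] = cds_list
        prot_by_strain[strain] = prot_list
    return cds_by_strain, prot_by_strain, truth


# ---------------------------------------------------------------------------
# genome with planted HGT region
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    sequence: str
    genes: list[GeneRecord]
    region: PlantedRegion


def simulate_genome_with_hgt(config: SimConfig) -> SimulatedGenome:
    """A gene-dense single-contig genome with one planted donor island.

    Genes (100-500 codons) alternate with short intergenic gaps across the
    whole genome. Genes and gaps whose midpoint falls inside the nominal donor
    interval are drawn from the donor codon profile / GC; everything else from
    the host profile. The reported :class:`PlantedRegion` is snapped to the
    first/last donor segment so the compositional contrast is exact at its
    boundaries.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seq_seed)
    host_profile = gc_biased_codon_profile(cfg.host_gc)
    donor_profile = gc_biased_codon_profile(cfg.donor_gc)

    lo = int(0.1 * cfg.genome_len)
    hi = cfg.genome_len - cfg.region_len - lo
    if hi <= lo:
        nominal_start = (cfg.genome_len - cfg.region_len) // 2
    else:
        nominal_start = int(rng.integers(lo, hi))
    nominal_end = nominal_start + cfg.region_len

    # lay out alternating gap/gene segments
    segments: list[tuple[int, int, bool]] = []  # (start, end, is_gene)
    pos = 0
    while pos < cfg.genome_len:
        gap = int(rng.integers(60, 200))
        gap = min(gap, cfg.genome_len - pos)
        segments.append((pos, pos + gap, False))
        pos += gap
        if pos >= cfg.genome_len:
            break
        glen = int(rng.integers(100, 501)) * 3
        glen = min(glen, cfg.genome_len - pos)
        glen -= glen % 3
        if glen >= 3:
            segments.append((pos, pos + glen, True))
            pos += glen

    strands = rng.choice(np.array(["+", "-"]), size=len(segments))
    donor_flags = [
        nominal_start <= (s + e) // 2 < nominal_end for s, e, _ in segments
    ]

    chunks: list[str] = []
    genes: list[GeneRecord] = []
    gene_no = 0
    for (start, end, is_gene), strand, is_donor in zip(segments, strands, donor_flags):
        length = end - start
        if is_gene:
            profile = donor_profile if is_donor else host_profile
            cols = rng.choice(N_SENSE, size=length // 3, p=profile)
            cds = codons_to_string(cols)
            chunks.append(cds if strand == "+" else revcomp(cds))
            gene_no += 1
            genes.append(
                GeneRecord(
                    gene_id=f"gene{gene_no:05d}",
                    strain="sim",
                    cds=cds,
                    contig="chr1",
                    start=start,
                    end=end,
                    strand=str(strand),
                )
            )
        else:
            gc = cfg.donor_gc if is_donor else cfg.host_gc
            is_gc = rng.random(length) < gc
            pick = rng.integers(0, 2, size=length)
            bases = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
            chunks.append("".join(bases.tolist()))

    donor_segs = [seg for seg, flag in zip(segments, donor_flags) if flag]
    if donor_segs:
        region = PlantedRegion(
            start=donor_segs[0][0], end=donor_segs[-1][1], donor_profile=donor_profile.tolist()
        )
    else:
        region = PlantedRegion(
            start=nominal_start, end=nominal_end, donor_profile=donor_profile.tolist()
        )
    return SimulatedGenome(sequence="".join(chunks), genes=genes, region=region)


def gc_content(seq: str) -> float:
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq) if seq else 0.0
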