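"""Ortholog family construction: all-vs-all similarity, reciprocal best hits,
Markov clustering, and core/unique classification.

The family-building route mirrors the classic OrthoMCL design at desk scale:
cross-strain reciprocal best hits plus above-threshold within-strain hits
(paralog capture) define a weighted undirected graph, which Markov clustering
(inflation 1.5 by default) partitions into families. Genes absent from the
graph become singleton families, so the result is always a partition of all
retained genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_qc import GeneSet

HIT_COLUMNS = ["query", "subject", "qstrain", "sstrain", "score", "identity", "qcov"]

#: columns of the standard 12-column tabular hit format
BLAST_TAB_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aln) -> tuple[float, int, int]:
    """(identity, query aligned span, subject aligned span) of one alignment."""
    qa, sa = aln.aligned
    ident = 0
    cols = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        a = str(aln.target[qs:qe])
        b = str(aln.query[ss:se])
        ident += sum(x == y for x, y in zip(a, b))
        cols += qe - qs
    qspan = int(qa[-1][1] - qa[0][0]) if len(qa) else 0
    sspan = int(sa[-1][1] - sa[0][0]) if len(sa) else 0
    identity = ident / cols if cols else 0.0
    return identity, qspan, sspan


def all_vs_all_scores(
    gene_sets: dict[str, list[tuple[str, str]]] | list[GeneSet],
    scorer: str = "local",
    min_score: float = 50.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """All-vs-all protein similarity table.

    ``gene_sets`` maps strain -> [(gene_id, protein)] (a list of
    :class:`~panflux.io_qc.GeneSet` with protein sequences also works). The
    default scorer is Smith-Waterman with BLOSUM62 and affine gaps (-11/-1);
    hits with score < ``min_score`` or query coverage <= ``min_coverage`` are
    dropped, emulating the removal of poor alignments before clustering.

    Returns a directed table with one row per ordered (query, subject) pair
    that survives thresholds; self-hits are never emitted.
    """
    if scorer != "local":
        raise ValueError(f"unknown scorer {scorer!r}")
    if isinstance(gene_sets, list):
        gene_sets = {
            gs.strain: [(r.gene_id, r.protein) for r in gs.records if r.protein]
            for gs in gene_sets
        }
    if len(gene_sets) < 2:
        raise ValueError("need at least 2 strains")
    aligner = _make_aligner()
    genes = [
        (strain, gid, seq) for strain in sorted(gene_sets) for gid, seq in gene_sets[strain]
    ]
    rows = []
    for i in range(len(genes)):
        si, gi, pi = genes[i]
        for j in range(i + 1, len(genes)):
            sj, gj, pj = genes[j]
            score = aligner.score(pi, pj)
            if score < min_score:
                continue
            aln = aligner.align(pi, pj)[0]
            identity, qspan, sspan = _alignment_stats(aln)
            cov_i = qspan / len(pi)
            cov_j = sspan / len(pj)
            if cov_i > min_coverage:
                rows.append((gi, gj, si, sj, float(score), identity, cov_i))
            if cov_j > min_coverage:
                rows.append((gj, gi, sj, si, float(score), identity, cov_j))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def read_hit_table(
    path: str | Path, strain_of: dict[str, str], min_score: float = 50.0, min_coverage: float = 0.0
) -> pd.DataFrame:
    """Ingest an external 12-column tabular hit file into a SimilarityTable.

    ``strain_of`` maps gene ids to strains. Coverage is not derivable without
    sequence lengths, so rows carry qcov = alignment length / (qend - qstart + 1)
    proxy of 1.0; filter upstream if needed.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST_TAB_COLUMNS, comment="#")
    df = df[df["query"] != df["subject"]]
    df = df[df["bitscore"] >= min_score]
    out = pd.DataFrame(
        {
            "query": df["query"],
            "subject": df["subject"],
            "qstrain": df["query"].map(strain_of),
            "sstrain": df["subject"].map(strain_of),
            "score": df["bitscore"].astype(float),
            "identity": df["identity"].astype(float) / 100.0,
            "qcov": 1.0,
        }
    )
    if out[["qstrain", "sstrain"]].isna().any().any():
        missing = sorted(
            set(df.loc[out["qstrain"].isna(), "query"]) | set(df.loc[out["sstrain"].isna(), "subject"])
        )
        raise ValueError(f"genes with unknown strain: {missing[:5]}")
    # keep the best row per directed gene pair
    out = out.sort_values("score", ascending=False).drop_duplicates(["query", "subject"])
    return out[out["qcov"] >= min_coverage].reset_index(drop=True)


def reciprocal_best_hits(table: pd.DataFrame) -> nx.Graph:
    """Undirected homology graph from a directed similarity table.

    A cross-strain edge (a, b) exists iff b is among a's best-scoring hits in
    b's strain AND a is among b's best in a's strain (ties all kept). Every
    within-strain hit in the table adds a paralog edge. Edge weight is the
    mean of the two directed scores (or the single score if only one row).
    """
    if table.empty:
        raise ValueError("similarity table is empty")
    cross = table[table["qstrain"] != table["sstrain"]]
    within = table[table["qstrain"] == table["sstrain"]]
    score_of: dict[tuple[str, str], float] = {}
    for q, s, sc in cross[["query", "subject", "score"]].itertuples(index=False):
        key = (q, s)
        if key not in score_of or sc > score_of[key]:
            score_of[key] = sc
    # best hits per (query, subject strain), ties kept
    best: dict[tuple[str, str], set[str]] = {}
    grouped = cross.groupby(["query", "sstrain"], sort=False)["score"].transform("max")
    top = cross[cross["score"] >= grouped]
    for q, s, st in top[["query", "subject", "sstrain"]].itertuples(index=False):
        best.setdefault((q, st), set()).add(s)

    strain_of = dict(zip(table["query"], table["qstrain"]))
    strain_of.update(zip(table["subject"], table["sstrain"]))

    graph = nx.Graph()
    graph.add_nodes_from(strain_of)
    for (q, st), subjects in best.items():
        for s in subjects:
            if q < s and q in best.get((s, strain_of[q]), set()):
                w = np.mean([score_of[(q, s)], score_of.get((s, q), score_of[(q, s)])])
                graph.add_edge(q, s, weight=float(w))
    for q, s, sc in within[["query", "subject", "score"]].itertuples(index=False):
        if q == s:
            continue
        a, b = sorted((q, s))
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = float(np.mean([graph[a][b]["weight"], sc]))
        else:
            graph.add_edge(a, b, weight=float(sc))
    return graph


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> tuple[list[frozenset], bool]:
    """Markov clustering of a weighted graph.

    Adds self-loops (weight = the node's maximum incident edge weight),
    column-normalizes, then alternates expansion (matrix squaring) and
    inflation (elementwise power ``inflation`` followed by column
    renormalization) until the largest entry change drops below ``tol``.
    Clusters are the connected components of the converged matrix's support.

    Returns (clusters, converged). On non-convergence the partial clustering
    is returned with ``converged=False`` and a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn("MCL did not converge; returning partial clustering")

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [
        frozenset(nodes[i] for i in comp) for comp in nx.connected_components(support)
    ]
    return sorted(clusters, key=lambda c: sorted(c)[0]), converged


# ---------------------------------------------------------------------------
# family matrix and classification
# ---------------------------------------------------------------------------

@dataclass
class FamilyMatrix:
    """Strains x families count matrix plus family membership lists."""

    counts: pd.DataFrame  # index = strains, columns = family ids
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"family_id": fam, "strain": gid.split("|", 1)[0], "gene_id": gid}
            for fam, genes in self.members.items()
            for gid in genes
        ]
        pd.DataFrame(rows, columns=["family_id", "strain", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )


def build_family_matrix(
    clusters: list[frozenset],
    strain_of: dict[str, str],
) -> FamilyMatrix:
    """Assemble a FamilyMatrix from MCL clusters plus singleton leftovers.

    Every gene in ``strain_of`` ends up in exactly one family; genes missing
    from all clusters become singleton families.
    """
    clustered = set().union(*clusters) if clusters else set()
    all_clusters = [set(c) for c in clusters]
    for gene in sorted(set(strain_of) - clustered):
        all_clusters.append({gene})
    all_clusters.sort(key=lambda c: sorted(c)[0])
    strains = sorted(set(strain_of.values()))
    members: dict[str, list[str]] = {}
    data = np.zeros((len(strains), len(all_clusters)), dtype=int)
    sindex = {s: i for i, s in enumerate(strains)}
    fam_ids = []
    for k, genes in enumerate(all_clusters):
        fam = f"FAM{k + 1:05d}"
        fam_ids.append(fam)
        members[fam] = sorted(genes)
        for g in genes:
            data[sindex[strain_of[g]], k] += 1
    counts = pd.DataFrame(data, index=strains, columns=fam_ids)
    return FamilyMatrix(counts=counts, members=members)


@dataclass
class FamilyClassification:
    core: list[str]
    unique: list[str]
    histogram: dict[int, int]  # k strains -> number of families
    per_strain: pd.DataFrame  # n_families, n_unique, frac_genes_in_core


def classify_families(fm: FamilyMatrix) -> FamilyClassification:
    """Core/unique labels, shared-by-k histogram, and per-strain statistics.

    Core = present in every strain; unique = present in exactly one. The
    histogram counts families by the number of strains containing them, so
    the bin at k = n_strains is the core count and bin k = 1 the unique count.
    """
    if fm.counts.shape[1] == 0:
        raise ValueError("family matrix has no families")
    presence = fm.presence()
    k = presence.sum(axis=0)
    n_strains = presence.shape[0]
    core = sorted(k.index[k == n_strains])
    unique = sorted(k.index[k == 1])
    histogram = {int(i): int((k == i).sum()) for i in range(1, n_strains + 1) if (k == i).sum()}
    core_set = set(core)
    rows = []
    for strain in fm.strains:
        present = presence.loc[strain]
        fams = present.index[present]
        n_genes = int(fm.counts.loc[strain].sum())
        genes_in_core = int(fm.counts.loc[strain, sorted(core_set & set(fams))].sum())
        rows.append(
            {
                "strain": strain,
                "n_families": int(present.sum()),
                "n_unique": int(sum(1 for f in fams if f in set(unique))),
                "frac_genes_in_core": genes_in_core / n_genes if n_genes else 0.0,
            }
        )
    return FamilyClassification(
        core=core,
        unique=unique,
        histogram=histogram,
        per_strain=pd.DataFrame(rows).set_index("strain"),
    )
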