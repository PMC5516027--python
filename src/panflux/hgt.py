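"""Parametric detection of horizontally transferred regions.

Two compositional signals are scanned: GC content in non-overlapping 5 kb
windows (deviation from the global genome GC) and codon-usage frequencies in
20 kb windows sliding by 10 kb. Each codon-usage window pools the codons of
the genes that overlap it by more than half of their length, giving one row
of a windows x 61 frequency matrix; principal component analysis of that
matrix separates compositionally alien windows from the genome's main
cluster. Windows whose robust z-distance (median/MAD per axis on PC1-PC2)
exceeds a threshold are flagged, and runs of flagged windows are merged into
region calls.

A light-weight exact-match anchor chain (:func:`anchor_match`) provides the
two-genome comparison used to corroborate a shared island: k-mers unique in
both genomes become anchors, and collinear anchor runs form chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import count_sense_codons, N_SENSE, SENSE_CODONS, revcomp
from .io_qc import GeneRecord


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------

def gc_windows(genome: str, window: int = 5000) -> pd.DataFrame:
    """Per-window GC and deviation from global GC over a non-overlapping tiling.

    The final partial window is kept as its own window when it is at least
    half a window long, otherwise merged into the previous one.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not genome:
        raise ValueError("empty sequence")
    seq = genome.upper()
    is_gc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    global_gc = float(is_gc.mean())
    n = len(seq)
    starts = list(range(0, n, window))
    if len(starts) > 1 and n - starts[-1] < window / 2:
        starts.pop()
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    rows = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else n
        gc = (csum[e] - csum[s]) / (e - s)
        rows.append({"start": s, "end": e, "gc": gc, "deviation": gc - global_gc})
    df = pd.DataFrame(rows)
    df.attrs["global_gc"] = global_gc
    return df


# ---------------------------------------------------------------------------
# codon usage windows
# ---------------------------------------------------------------------------

@dataclass
class FcuMatrix:
    """Sliding-window codon-usage frequencies (rows sum to 1 when non-empty)."""

    frequencies: pd.DataFrame  # index = window id; 61 codon columns
    windows: pd.DataFrame  # window id -> start, end, n_genes, n_codons

    @property
    def nonempty(self) -> pd.DataFrame:
        keep = self.windows["n_codons"] > 0
        return self.frequencies.loc[keep[keep].index]


def sliding_window_starts(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window (start, end) pairs anchored at multiples of ``step``.

    The final partial window is retained iff it is at least half the window
    size.
    """
    spans = []
    s = 0
    while s + window <= length:
        spans.append((s, s + window))
        s += step
    if s < length and length - s > window / 2:  # final partial window
        spans.append((s, length))
    if not spans:
        spans = [(0, length)]
    return spans


def codon_usage_windows(
    genome_length: int,
    genes: list[GeneRecord],
    window: int = 20000,
    step: int = 10000,
    min_overlap: float = 0.5,
) -> FcuMatrix:
    """Windowed 61-dimension codon-usage frequency matrix.

    A gene contributes its full codon counts to a window iff the overlap
    between gene and window exceeds ``min_overlap`` of the gene's length
    (strictly greater). Stop codons and codons containing non-ACGT bases are
    excluded from both numerator and denominator.
    """
    spans = sliding_window_starts(genome_length, window, step)
    gene_counts = []
    coords = []
    for g in genes:
        if g.cds is None or len(g.cds) != g.end - g.start:
            warnings.warn(f"{g.gene_id}: CDS/coordinate length mismatch, skipped")
            continue
        gene_counts.append(count_sense_codons(g.cds))
        coords.append((g.start, g.end))
    counts = np.zeros((len(spans), N_SENSE))
    n_genes = np.zeros(len(spans), dtype=int)
    for (gs, ge), cvec in zip(coords, gene_counts):
        glen = ge - gs
        for w, (ws, we) in enumerate(spans):
            overlap = min(ge, we) - max(gs, ws)
            if overlap > min_overlap * glen:
                counts[w] += cvec
                n_genes[w] += 1
    totals = counts.sum(axis=1)
    freq = np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0)
    windows = pd.DataFrame(
        {
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "n_genes": n_genes,
            "n_codons": totals.astype(int),
        }
    )
    frequencies = pd.DataFrame(freq, columns=list(SENSE_CODONS))
    return FcuMatrix(frequencies=frequencies, windows=windows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # window id x components
    loadings: np.ndarray  # components x 61
    variance_fraction: np.ndarray


def pca(fcu: FcuMatrix | pd.DataFrame) -> PcaResult:
    """Principal components of the window x 61 frequency matrix.

    Columns are centered but not scaled to unit variance: the 61 frequencies
    are already commensurate, and unit scaling would inflate rare-codon
    noise. Empty windows are excluded before decomposition.
    """
    if isinstance(fcu, FcuMatrix):
        mat = fcu.nonempty
    else:
        mat = fcu
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 non-empty windows")
    x = mat.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-12:
        warnings.warn("all windows identical; variance fractions are zero")
        fractions = np.zeros_like(var)
    else:
        fractions = var / total
    # sign convention: make the largest-magnitude loading of each PC positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = pd.DataFrame(
        u * s, index=mat.index, columns=[f"PC{k + 1}" for k in range(s.size)]
    )
    return PcaResult(scores=scores, loadings=vt, variance_fraction=fractions)


# ---------------------------------------------------------------------------
# outlier windows -> HGT calls
# ---------------------------------------------------------------------------

@dataclass
class HgtCall:
    start: int
    end: int
    n_support_windows: int
    mean_gc: float
    deviation_score: float
    window_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        warnings.warn("MAD is zero; falling back to standard deviation")
        scale = values.std()
        if scale == 0:
            return np.zeros_like(values)
    return (values - med) / scale


def detect_outlier_windows(
    pca_result: PcaResult,
    fcu: FcuMatrix,
    gc_table: pd.DataFrame | None = None,
    threshold: float = 3.5,
    merge_gap: int = 1,
    min_windows: int = 3,
) -> list[HgtCall]:
    """Merge compositionally deviant codon-usage windows into region calls.

    A window is an outlier when its Euclidean robust z-distance on PC1-PC2
    exceeds ``threshold``. Runs of outliers separated by at most ``merge_gap``
    non-outlier windows become one call; calls supported by fewer than
    ``min_windows`` windows are dropped. The default of 3 is the smallest
    support that cannot be produced by one anomalous step-sized cell: with
    half-overlapping windows a single deviant 10 kb cell flags exactly two
    windows, while a genuine island of at least two cells flags three or
    more. Mean GC over the call span is taken from ``gc_table`` when given.
    """
    scores = pca_result.scores
    z1 = _robust_z(scores["PC1"].to_numpy())
    z2 = _robust_z(scores["PC2"].to_numpy()) if "PC2" in scores else np.zeros_like(z1)
    dist = np.sqrt(z1**2 + z2**2)
    window_ids = np.asarray(scores.index)
    outliers = window_ids[dist > threshold]
    if outliers.size == 0:
        return []
    dist_of = dict(zip(window_ids.tolist(), dist.tolist()))

    # group flagged windows, tolerating merge_gap skipped windows between them
    groups: list[list[int]] = [[int(outliers[0])]]
    for wid in outliers[1:]:
        if int(wid) - groups[-1][-1] <= merge_gap + 1:
            groups[-1].append(int(wid))
        else:
            groups.append([int(wid)])

    calls = []
    for grp in groups:
        if len(grp) < min_windows:
            continue
        start = int(fcu.windows.loc[grp[0], "start"])
        end = int(fcu.windows.loc[grp[-1], "end"])
        if len(grp) >= 3:
            # windows overlap by half; the outer half-window of each flank is
            # supported by a single window only, so report the >=2x-covered core
            start = int(fcu.windows.loc[grp[1], "start"])
            end = int(fcu.windows.loc[grp[-2], "end"])
        if gc_table is not None:
            sel = (gc_table["end"] > start) & (gc_table["start"] < end)
            mean_gc = float(gc_table.loc[sel, "gc"].mean()) if sel.any() else float("nan")
        else:
            mean_gc = float("nan")
        calls.append(
            HgtCall(
                start=start,
                end=end,
                n_support_windows=len(grp),
                mean_gc=mean_gc,
                deviation_score=float(np.mean([dist_of[w] for w in grp])),
                window_ids=grp,
            )
        )
    return calls


def calls_to_bed(calls: list[HgtCall], path: str | Path, contig: str = "chr1") -> None:
    with open(path, "w") as fh:
        for i, call in enumerate(calls, 1):
            fh.write(f"{contig}\t{call.start}\t{call.end}\thgt{i}\t{call.deviation_score:.3f}\n")


# ---------------------------------------------------------------------------
# exact-match anchor chains
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def anchor_match(
    genome_a: str,
    genome_b: str,
    k: int = 21,
    min_chain: int = 5000,
    max_gap: int = 2000,
) -> pd.DataFrame:
    """Collinear chains of unique exact k-mer matches between two genomes.

    Anchors are k-mers occurring exactly once in each genome (checking both
    strands of B). Anchors sorted by A-position are chained greedily: an
    anchor extends the current chain when it lies within ``max_gap`` on both
    genomes, moves forward on A, and is collinear on B for the chain's
    strand. Chains spanning less than ``min_chain`` bp on A are dropped.

    Returns a table with columns astart, aend, bstart, bend, strand, length
    (coordinates 0-based half-open; for '-' chains bstart/bend refer to the
    forward strand of B).
    """
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > len(genome_a) or k > len(genome_b):
        raise ValueError("k exceeds a genome length")
    a_pos = _unique_kmers(genome_a.upper(), k)
    b_fwd = _unique_kmers(genome_b.upper(), k)
    b_rc_seq = revcomp(genome_b.upper())
    b_rev = _unique_kmers(b_rc_seq, k)
    nb = len(genome_b)

    anchors = []  # (apos, bpos_fwd, strand)
    for kmer, ap in a_pos.items():
        fwd = kmer in b_fwd
        rev = kmer in b_rev
        if fwd and not rev:
            anchors.append((ap, b_fwd[kmer], "+"))
        elif rev and not fwd:
            # position of the match on B's forward strand
            anchors.append((ap, nb - k - b_rev[kmer], "-"))
    anchors.sort()

    chains: list[list[tuple[int, int, str]]] = []
    current: list[tuple[int, int, str]] = []
    for anchor in anchors:
        if not current:
            current = [anchor]
            continue
        pa, pb, pstrand = current[-1]
        ap, bp, strand = anchor
        da = ap - pa
        db = bp - pb if strand == "+" else pb - bp
        if strand == pstrand and 0 < da <= max_gap + k and 0 < db <= max_gap + k:
            current.append(anchor)
        else:
            chains.append(current)
            current = [anchor]
    if current:
        chains.append(current)

    rows = []
    for chain in chains:
        astart = chain[0][0]
        aend = chain[-1][0] + k
        if aend - astart < min_chain:
            continue
        strand = chain[0][2]
        bpositions = [b for _, b, _ in chain]
        bstart = min(bpositions)
        bend = max(bpositions) + k
        rows.append(
            {
                "astart": astart,
                "aend": aend,
                "bstart": bstart,
                "bend": bend,
                "strand": strand,
                "length": aend - astart,
            }
        )
    return pd.DataFrame(rows, columns=["astart", "aend", "bstart", "bend", "strand", "length"])
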