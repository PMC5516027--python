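"""Codon tables and codon-usage helpers shared by the simulator and the HGT scan.

The 61 sense codons (64 minus the three stops TAA/TAG/TGA) are kept in a fixed
lexicographic A<C<G<T order so that codon-usage matrices from different runs
are column-compatible.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61

_BASE_CODE = {b: i for i, b in enumerate(BASES)}
#: number of G/C bases in each sense codon, aligned with SENSE_CODONS
SENSE_GC_COUNT = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS])

# codon index (base-4 over ACGT) -> sense-codon column, -1 for stops
_SENSE_COLUMN = np.full(64, -1, dtype=np.int64)
for _i, _c in enumerate(SENSE_CODONS):
    _SENSE_COLUMN[16 * _BASE_CODE[_c[0]] + 4 * _BASE_CODE[_c[1]] + _BASE_CODE[_c[2]]] = _i

_CODE_OF_BYTE = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_CODE.items():
    _CODE_OF_BYTE[ord(_b)] = _i
    _CODE_OF_BYTE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def encode_bases(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes 0..3 (-1 for ambiguous bases)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_OF_BYTE[raw]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_sense_codons(cds: str) -> np.ndarray:
    """Count the 61 sense codons in an in-frame CDS.

    Stop codons and any codon containing a non-ACGT base are excluded from the
    count entirely (numerator and denominator of downstream frequencies).
    """
    codes = encode_bases(cds)
    n = (codes.size // 3) * 3
    codes = codes[:n].reshape(-1, 3)
    ok = (codes >= 0).all(axis=1)
    idx = codes[ok] @ np.array([16, 4, 1])
    cols = _SENSE_COLUMN[idx]
    cols = cols[cols >= 0]
    return np.bincount(cols, minlength=N_SENSE)


def gc_biased_codon_profile(target_gc: float) -> np.ndarray:
    """A 61-codon frequency vector whose expected base-level GC equals target_gc.

    Codons are re-weighted from uniform by exp(beta * gc_count); beta is solved
    so that sum(w_c * gc_c) / 3 == target_gc. Achievable targets lie strictly
    between 0 and 1 (the sense-codon table spans GC counts 0..3).
    """
    if not 0.0 < target_gc < 1.0:
        raise ValueError(f"target_gc must be in (0, 1), got {target_gc}")

    def expected_gc(beta: float) -> float:
        w = np.exp(beta * SENSE_GC_COUNT.astype(float))
        w /= w.sum()
        return float(w @ SENSE_GC_COUNT) / 3.0

    beta = brentq(lambda b: expected_gc(b) - target_gc, -50.0, 50.0)
    w = np.exp(beta * SENSE_GC_COUNT.astype(float))
    return w / w.sum()


_SENSE_BYTES = np.frombuffer("".join(SENSE_CODONS).encode("ascii"), dtype=np.uint8).reshape(
    N_SENSE, 3
)


def codons_to_string(cols: np.ndarray) -> str:
    """Concatenate sense-codon column indices into a nucleotide string."""
    cols = np.asarray(cols, dtype=np.int64).ravel()
    return _SENSE_BYTES[cols].tobytes().decode("ascii")
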