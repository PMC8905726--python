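"""Low-level sequence utilities shared across the pipeline.

Coordinates are 0-based half-open throughout the library; conversion to
1-based inclusive happens only in GFF3 serialization.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"
# 20 standard amino acids, used by the protein simulator.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMP)[::-1]


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the given GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0,1], got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA_ALPHABET))[rng.choice(4, size=length, p=p)])


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=length)])


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse an edlib extended cigar into (length, op) pairs."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_identity(a: str, b: str, denominator: str = "columns") -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment of a and b.

    denominator="columns": matches / alignment columns, terminal gap runs
    excluded, internal gaps counted as mismatch columns.
    denominator="shorter": matches / length of the shorter sequence (the
    convention of greedy centroid clusterers).
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    ops = cigar_ops(res["cigar"])
    # strip terminal gap runs
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    matches = sum(n for n, op in ops if op == "=")
    if denominator == "shorter":
        return 100.0 * matches / min(len(a), len(b))
    cols = sum(n for n, _ in ops)
    return 100.0 * matches / cols if cols else 0.0


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes; -1 for N/ambiguous."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized k-mer encoding.

    Returns (positions, codes) for every k-mer window free of non-ACGT
    characters; codes are unique uint64 per k-mer (k <= 31).
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    codes8 = encode_bases(seq)
    n = len(codes8) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    valid = codes8 >= 0
    # rolling window validity and value via cumulative tricks
    window_valid = np.ones(n, dtype=bool)
    vals = np.zeros(n, dtype=np.uint64)
    c = codes8.astype(np.uint64)
    for i in range(k):
        window_valid &= valid[i : i + n]
        vals = (vals << np.uint64(2)) | c[i : i + n]
    pos = np.nonzero(window_valid)[0]
    return pos.astype(np.int64), vals[window_valid]
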