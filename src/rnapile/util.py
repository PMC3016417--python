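"""Shared low-level sequence helpers.

All genomic coordinates in this package are 0-based, half-open. File writers
that emit 1-based formats (GFF3) convert at the boundary.
"""

from __future__ import annotations

import numpy as np

# A/C/G/T -> 0..3; anything else -> 5.  Code 4 is reserved for index
# separators so that an ambiguous read base never "matches" a separator.
BASE_CODES = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[_b + 32] = _i  # lowercase

SEPARATOR_CODE = np.uint8(4)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return BASE_CODES[np.frombuffer(seq, dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def common_prefix_len(a: np.ndarray, b: np.ndarray) -> int:
    n = min(len(a), len(b))
    ne = np.flatnonzero(a[:n] != b[:n])
    return n if ne.size == 0 else int(ne[0])


def common_suffix_len(a: np.ndarray, b: np.ndarray) -> int:
    n = min(len(a), len(b))
    ne = np.flatnonzero(a[len(a) - n:] != b[len(b) - n:])
    return n if ne.size == 0 else n - 1 - int(ne[-1])


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_census(genome: dict[str, str], k: int) -> dict[str, int]:
    """Exact count of every canonical k-mer on both strands of `genome`.

    Used by the read simulator to decide whether a read window is repetitive
    (maps to more than one genomic location).
    """
    census: dict[str, int] = {}
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            key = canonical_kmer(seq[i:i + k])
            census[key] = census.get(key, 0) + 1
    return census
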