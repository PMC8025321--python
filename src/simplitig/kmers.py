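"""k-mer encoding, canonicalization, and k-mer set construction.

A k-mer is packed into an unsigned integer at 2 bits per base with
A=0, C=1, G=2, T=3 and the first base in the most significant pair.
With this encoding, integer order on codes equals lexicographic order
on strings, so the canonical form (the lexicographic minimum of a k-mer
and its reverse complement) can be computed directly on codes.

The node set of a node-centric de Bruijn graph is held in a
:class:`KmerSet`: the distinct k-mers of the input (distinct canonical
k-mers in the bi-directed model), the k-mer length, and the strand model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

__all__ = [
    "MIN_K",
    "MAX_K",
    "StrandModel",
    "KmerSet",
    "reverse_complement",
    "canonical_form",
    "kmers_of_segment",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "canonical_code",
    "segments_of",
    "iter_codes",
    "build_kmer_set",
]

MIN_K = 1
MAX_K = 32  # a k-mer must fit a single 64-bit code

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_RC_TRANSLATION = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile("[^ACGT]+")


class StrandModel(str, Enum):
    """Strand handling: ``uni`` keeps k-mers as seen; ``bi`` folds each
    k-mer with its reverse complement onto the canonical (lexicographically
    smaller) form, the usual model for double-stranded sequencing data."""

    UNI = "uni"
    BI = "bi"


def _require_acgt(s: str) -> None:
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT character(s): {sorted(bad)!r}"
        )


def _require_k(k: int) -> None:
    if not MIN_K <= k <= MAX_K:
        raise ValueError(
            f"k={k} unsupported; supported k-mer lengths are [{MIN_K}, {MAX_K}]"
        )


def reverse_complement(s: str) -> str:
    """Reverse complement of an ACGT string; an involution."""
    _require_acgt(s)
    return s.translate(_RC_TRANSLATION)[::-1]


def canonical_form(s: str) -> str:
    """Lexicographic minimum of ``s`` and its reverse complement (A<C<G<T)."""
    rc = reverse_complement(s)
    return s if s <= rc else rc


def kmers_of_segment(s: str, k: int) -> list[str]:
    """All ``len(s) - k + 1`` consecutive k-mers of an ACGT string, in order.

    Returns an empty list when the segment is shorter than ``k``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _require_acgt(s)
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def encode_kmer(s: str) -> int:
    """Pack an ACGT string of length <= 32 into its 2-bit integer code."""
    _require_k(len(s))
    _require_acgt(s)
    code = 0
    for ch in s:
        code = (code << 2) | _BASE_CODE[ch]
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _require_k(k)
    if not 0 <= code < (1 << (2 * k)):
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement computed directly on a packed code."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> int:
    """Canonical (min of code and reverse-complement code) packed form."""
    return min(code, revcomp_code(code, k))


def segments_of(sequence: str) -> list[str]:
    """Uppercase a sequence and split it into maximal ACGT-only segments.

    Any non-ACGT character (N, IUPAC ambiguity codes, gaps, ...) acts as a
    separator, so extracted k-mers never span an ambiguous position.
    """
    return [seg for seg in _NON_ACGT.split(sequence.upper()) if seg]


def iter_codes(sequence: str, k: int, model: StrandModel) -> Iterator[int]:
    """Yield the packed (canonical in bi mode) code of every k-mer of a
    sequence, segment by segment, via a rolling 2-bit window.

    May yield duplicates; deduplication is the caller's concern.
    """
    _require_k(k)
    model = StrandModel(model)
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    bi = model is StrandModel.BI
    base_code = _BASE_CODE
    for seg in segments_of(sequence):
        if len(seg) < k:
            continue
        fw = rc = 0
        for i, ch in enumerate(seg):
            b = base_code[ch]
            fw = ((fw << 2) | b) & mask
            rc = (rc >> 2) | ((3 - b) << shift)
            if i >= k - 1:
                if bi:
                    yield fw if fw <= rc else rc
                else:
                    yield fw


@dataclass
class KmerSet:
    """Node set of a node-centric de Bruijn graph.

    ``codes`` is an insertion-ordered mapping used as an ordered set; in
    bi mode every member is its own canonical form. Equality ignores
    insertion order (sets compare as sets).
    """

    k: int
    model: StrandModel
    codes: dict[int, None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_k(self.k)
        self.model = StrandModel(self.model)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: int) -> bool:
        return code in self.codes

    def __iter__(self) -> Iterator[int]:
        return iter(self.codes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerSet):
            return NotImplemented
        return (
            self.k == other.k
            and self.model is other.model
            and set(self.codes) == set(other.codes)
        )

    def strings(self) -> list[str]:
        """Members decoded back to strings, in insertion order."""
        return [decode_kmer(c, self.k) for c in self.codes]


def build_kmer_set(
    sequences: Iterable[str], k: int, model: StrandModel | str
) -> KmerSet:
    """Extract the deduplicated k-mer set of a collection of sequences.

    Sequences are uppercased and split at non-ACGT characters; k-mers are
    taken per segment (never spanning a split) and canonicalized in bi
    mode. Records shorter than ``k`` simply contribute nothing.
    """
    _require_k(k)
    model = StrandModel(model)
    codes: dict[int, None] = {}
    for seq in sequences:
        for code in iter_codes(seq, k, model):
            codes[code] = None
    return KmerSet(k=k, model=model, codes=codes)
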