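"""NS/CL accounting, bound checks, and bits-per-k-mer storage rates.

For any representation that carries each of the ``n`` k-mers of a set
exactly once, the number of sequences NS and their cumulative length CL
are tied by the identity

    CL = n_kmers + (k - 1) * NS

so the two characteristics are optimized jointly: every merge of two
sequences across a (k-1)-overlap drops NS by 1 and CL by k-1. NS is
bounded by 1 and n_kmers (maximal fragmentation: every k-mer its own
sequence), and CL by n_kmers and k * n_kmers.

Storage cost is expressed in bits per distinct k-mer. Two accountings
are provided: payload-only (sequence characters, which admits the exact
>= 8 bit lower bound at one byte per base) and whole-file (FASTA headers
and newlines included). Compressed rates use a named standard compressor
(xz by default) and are reported next to the 2-bit reference, never
asserted against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import pandas as pd

from .kmers import KmerSet, StrandModel
from .represent import Representation

__all__ = [
    "RepresentationStats",
    "stats_of",
    "reduction_ratios",
    "bits_per_kmer",
    "compressed_bits_per_kmer",
    "stats_table",
    "write_stats",
]


@dataclass
class RepresentationStats:
    kind: str
    k: int
    model: str
    ns: int
    cl: int
    n_kmers: int
    eq1_residual: int
    ns_bounds_ok: bool
    cl_bounds_ok: bool
    bits_per_kmer_uncompressed: float | None = None
    bits_per_kmer_compressed: float | None = None


def stats_of(rep: Representation, kmer_set: KmerSet) -> RepresentationStats:
    """NS, CL, the CL = n + (k-1)*NS residual, and bound flags.

    The representation and the k-mer set must agree on k and strand model.
    The uncompressed bits-per-k-mer column is the payload rate 8*CL/n.
    """
    if rep.k != kmer_set.k:
        raise ValueError(f"k mismatch: representation {rep.k} vs set {kmer_set.k}")
    if StrandModel(rep.model) is not kmer_set.model:
        raise ValueError(
            f"strand model mismatch: {rep.model!r} vs {kmer_set.model!r}"
        )
    ns, cl, n = rep.ns, rep.cl, len(kmer_set)
    residual = cl - (n + (rep.k - 1) * ns)
    ns_ok = (1 <= ns <= n) if n >= 1 else ns == 0
    cl_ok = (n <= cl <= rep.k * n) if n >= 1 else cl == 0
    return RepresentationStats(
        kind=rep.kind,
        k=rep.k,
        model=kmer_set.model.value,
        ns=ns,
        cl=cl,
        n_kmers=n,
        eq1_residual=residual,
        ns_bounds_ok=ns_ok,
        cl_bounds_ok=cl_ok,
        bits_per_kmer_uncompressed=bits_per_kmer(cl, n) if n else None,
    )


def reduction_ratios(
    unitig_stats: RepresentationStats, simplitig_stats: RepresentationStats
) -> tuple[float, float]:
    """(NS ratio, CL ratio) of unitigs over simplitigs; >= 1 for maximal
    simplitigs in uni mode."""
    if simplitig_stats.ns == 0 or simplitig_stats.cl == 0:
        raise ValueError("reduction ratio undefined for an empty representation")
    return (
        unitig_stats.ns / simplitig_stats.ns,
        unitig_stats.cl / simplitig_stats.cl,
    )


def bits_per_kmer(payload_bytes: int, n_kmers: int) -> float:
    """8 * payload_bytes / n_kmers, the storage rate per distinct k-mer."""
    if n_kmers < 1:
        raise ValueError("bits per k-mer undefined for an empty k-mer set")
    return 8.0 * payload_bytes / n_kmers


_COMPRESSORS = ("xz", "bz2", "gzip")


def _compress(data: bytes, compressor: str) -> bytes | None:
    try:
        if compressor == "xz":
            import lzma

            return lzma.compress(data, preset=9)
        if compressor == "bz2":
            import bz2

            return bz2.compress(data, 9)
        if compressor == "gzip":
            import zlib

            return zlib.compress(data, 9)
    except ImportError:
        warnings.warn(
            f"compressor {compressor!r} unavailable in this runtime; "
            "compressed bits-per-k-mer disabled",
            RuntimeWarning,
            stacklevel=3,
        )
        return None
    raise ValueError(f"unknown compressor {compressor!r}; choose from {_COMPRESSORS}")


def compressed_bits_per_kmer(
    data: bytes, n_kmers: int, compressor: str = "xz"
) -> float | None:
    """Bits per distinct k-mer after compressing ``data`` at the best level.

    Deterministic for a fixed compressor. Returns None (with a warning)
    when the compressor is unavailable.
    """
    if n_kmers < 1:
        raise ValueError("bits per k-mer undefined for an empty k-mer set")
    blob = _compress(data, compressor)
    if blob is None:
        return None
    return bits_per_kmer(len(blob), n_kmers)


def stats_table(rows: list[RepresentationStats]) -> pd.DataFrame:
    """One row per representation, suitable for TSV/JSON export."""
    return pd.DataFrame([asdict(r) for r in rows])


def write_stats(rows: list[RepresentationStats], path: str) -> None:
    """Write stats as TSV (default) or JSON when the path ends in .json."""
    df = stats_table(rows)
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
            fh.write("\n")
    else:
        df.to_csv(path, sep="\t", index=False)
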