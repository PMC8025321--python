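"""Synthetic genomes, mutated pan-genome collections, and a brute-force
path-cover oracle.

The simulators stand in for real assembly collections in tests and
experiments: a uniform random genome plays the role of a reference, and a
pan-genome is emulated as one base genome plus per-genome i.i.d.
substitutions, which is exactly the mechanism that creates branching
nodes ("bubbles") in the de Bruijn graph — the phenomenon that separates
simplitigs from unitigs. Indels are available but off by default.

The oracle computes the exact minimum vertex-disjoint path cover of tiny
graphs by exhaustive search, deliberately sharing nothing with the greedy
code path it benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import KmerSet, StrandModel

__all__ = [
    "PanGenomeConfig",
    "random_genome",
    "simulate_pangenome",
    "min_path_cover_bruteforce",
    "tiny_kmer_set_catalogue",
    "ORACLE_MAX_KMERS",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

ORACLE_MAX_KMERS = 12


def random_genome(length: int, seed) -> str:
    """Uniform i.i.d. ACGT string of the given length; deterministic per seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


@dataclass(frozen=True)
class PanGenomeConfig:
    """Synthetic pan-genome: ``n_genomes`` copies of a ``length``-bp base
    genome, each non-base copy carrying i.i.d. substitutions at rate
    ``substitution_rate`` per base (and optional indels at ``indel_rate``,
    split evenly between single-base deletions and insertions)."""

    length: int
    n_genomes: int
    substitution_rate: float
    seed: int
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def simulate_pangenome(cfg: PanGenomeConfig) -> list[str]:
    """Genome 1 is the base; each further genome is an independently
    mutated copy (substituted base drawn uniformly from the 3 alternatives).
    Fully reproducible from ``cfg.seed``."""
    base = random_genome(cfg.length, cfg.seed)
    base_codes = np.frombuffer(base.encode("ascii"), dtype=np.uint8)
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lookup[b] = i
    base_idx = lookup[base_codes]
    genomes = [base]
    for g in range(1, cfg.n_genomes):
        rng = np.random.default_rng([cfg.seed, g])
        idx = base_idx.copy()
        mask = rng.random(cfg.length) < cfg.substitution_rate
        n_mut = int(mask.sum())
        if n_mut:
            idx[mask] = (idx[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
        if cfg.indel_rate > 0.0:
            keep = rng.random(len(idx)) >= cfg.indel_rate / 2.0
            idx = idx[keep]
            ins_mask = rng.random(len(idx)) < cfg.indel_rate / 2.0
            if ins_mask.any():
                pieces = []
                last = 0
                for pos in np.nonzero(ins_mask)[0]:
                    pieces.append(idx[last : pos + 1])
                    pieces.append(
                        rng.integers(0, 4, size=1, dtype=np.uint8)
                    )
                    last = pos + 1
                pieces.append(idx[last:])
                idx = np.concatenate(pieces)
        genomes.append(_BASE_BYTES[idx].tobytes().decode("ascii"))
    return genomes


def tiny_kmer_set_catalogue(seed: int, n_random: int = 150) -> list[KmerSet]:
    """Deterministic catalogue of uni-directed k-mer sets with <= 10
    members, for benchmarking the greedy cover against the exact oracle.

    Mix of structured instances (chains, a cycle, a branching fork,
    disjoint singletons) and random ones: short random genomes at small k
    (dense, repeat-rich graphs) plus uniformly drawn code sets (sparse,
    fragmented graphs).
    """
    from .kmers import build_kmer_set, decode_kmer  # deferred: avoid cycle

    catalogue: list[KmerSet] = []
    structured = [
        (["ACGTT"], 3),  # chain
        (["ACGTAGC"], 3),  # longer chain
        (["ACG", "CGA", "CGT"], 3),  # fork
        (["ACG", "CGA", "GAC"], 3),  # 3-cycle
        (["AAT", "CCG", "GGA", "TTC"], 3),  # disjoint singletons
        (["AAAA"], 3),  # self-loop node AAA
        (["ACGACG"], 3),  # cycle with entry
    ]
    for seqs, k in structured:
        catalogue.append(build_kmer_set(seqs, k, StrandModel.UNI))
    rng = np.random.default_rng(seed)
    while len(catalogue) < len(structured) + n_random:
        if rng.random() < 0.5:
            k = int(rng.integers(3, 6))
            genome = random_genome(int(rng.integers(k + 1, 21)), int(rng.integers(0, 2**31)))
            ks = build_kmer_set([genome], k, StrandModel.UNI)
        else:
            k = int(rng.integers(3, 6))
            m = int(rng.integers(1, 11))
            codes = rng.choice(4**k, size=m, replace=False)
            ks = build_kmer_set(
                [decode_kmer(int(c), k) for c in codes], k, StrandModel.UNI
            )
        if 1 <= len(ks) <= 10:
            catalogue.append(ks)
    return catalogue


def min_path_cover_bruteforce(kmer_set: KmerSet) -> int:
    """Exact minimum number of vertex-disjoint paths covering the
    node-centric de Bruijn graph of a (uni-directed) k-mer set.

    Exhaustive search over edge subsets that keep in/out-degree <= 1 and
    stay acyclic: the cover size is n minus the largest such subset. The
    search budget caps the set at ORACLE_MAX_KMERS members.
    """
    if kmer_set.model is StrandModel.BI:
        raise ValueError(
            "brute-force path cover oracle supports the uni-directed model only"
        )
    n = len(kmer_set)
    if n == 0:
        return 0
    if n > ORACLE_MAX_KMERS:
        raise ValueError(
            f"k-mer set has {n} members; oracle budget is {ORACLE_MAX_KMERS}"
        )
    k = kmer_set.k
    mask = (1 << (2 * k)) - 1
    members = set(kmer_set.codes)
    edges = [
        (u, v)
        for u in sorted(members)
        for b in range(4)
        if (v := ((u << 2) & mask) | b) in members and v != u
    ]
    nxt: dict[int, int | None] = {u: None for u in members}
    prv: dict[int, int | None] = {u: None for u in members}
    best = 0
    m = len(edges)

    def chain_tail(u: int) -> int:
        while nxt[u] is not None:
            u = nxt[u]
        return u

    def dfs(i: int, used: int) -> None:
        nonlocal best
        if used > best:
            best = used
        if i == m or used + (m - i) <= best or best == n - 1:
            return
        u, v = edges[i]
        if nxt[u] is None and prv[v] is None and chain_tail(v) != u:
            nxt[u], prv[v] = v, u
            dfs(i + 1, used + 1)
            nxt[u], prv[v] = None, None
        dfs(i + 1, used)

    dfs(0, 0)
    return n - best
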