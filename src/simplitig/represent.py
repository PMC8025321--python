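"""Greedy maximal simplitigs and node-centric maximal unitigs.

Both representations spell vertex-disjoint path covers of the node-centric
de Bruijn graph of a k-mer set: consecutive path nodes overlap by k-1
bases and each k-mer of the set occurs exactly once over the output.
Unitig paths stop at branching nodes and are unique up to order, reverse
complementing, and cycle break points; simplitigs may run through
branchings, and the greedy procedure here extends each seed k-mer forward
and then backward as far as the remaining (unused) k-mers allow, trying
the four nucleotides in a fixed order.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

from .kmers import (
    BASES,
    KmerSet,
    StrandModel,
    decode_kmer,
    revcomp_code,
)

__all__ = [
    "SIMPLITIGS",
    "UNITIGS",
    "ASSEMBLY",
    "Representation",
    "ExtensionPolicy",
    "MaximalityReport",
    "compute_simplitigs",
    "compute_unitigs",
    "is_maximal",
]

SIMPLITIGS = "simplitigs"
UNITIGS = "unitigs"
ASSEMBLY = "assembly"  # cleaned input sequences, used in storage comparisons

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class Representation:
    """An ordered collection of spelled paths (or raw assembly sequences)."""

    kind: str
    k: int
    model: StrandModel
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.model = StrandModel(self.model)

    @property
    def ns(self) -> int:
        return len(self.sequences)

    @property
    def cl(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass(frozen=True)
class ExtensionPolicy:
    """Tie-breaking policy for the greedy simplitig computation.

    ``nucleotide_order`` fixes the order in which extension bases are
    tried (lexicographic by default). ``seed_order`` picks how unused
    k-mers are chosen as seeds; seeding is the only source of
    run-to-run variability:

    * ``unitig-starts`` (default): maximal-unitig start nodes in ascending
      packed-code order, then the remaining (cycle-internal) nodes in
      ascending order. Fully deterministic, and it guarantees that every
      maximal unitig survives as a contiguous substring of exactly one
      simplitig — a seed landing mid-unitig on a cyclic component would
      otherwise emit the unitig rotated.
    * ``sorted-code``: plain ascending packed code, also deterministic.
    * ``insertion``: order of first appearance in the input.
    * ``random``: shuffled with an explicit integer ``seed``, emulating
      the arbitrary seed choice of hash-ordered implementations.
    """

    nucleotide_order: str = "ACGT"
    seed_order: str = "unitig-starts"
    seed: int | None = None

    _SEED_ORDERS = ("unitig-starts", "sorted-code", "insertion", "random")

    def __post_init__(self) -> None:
        if sorted(self.nucleotide_order) != list(BASES):
            raise ValueError(
                f"nucleotide_order must be a permutation of {BASES!r}, "
                f"got {self.nucleotide_order!r}"
            )
        if self.seed_order not in self._SEED_ORDERS:
            raise ValueError(f"seed_order must be one of {self._SEED_ORDERS}")
        if self.seed_order == "random" and self.seed is None:
            raise ValueError("seed_order='random' requires an integer seed")

    def seed_sequence(self, kmer_set: KmerSet) -> list[int]:
        codes = list(kmer_set.codes)
        if self.seed_order == "unitig-starts":
            starts = _unitig_start_codes(kmer_set)
            return sorted(c for c in codes if c in starts) + sorted(
                c for c in codes if c not in starts
            )
        if self.seed_order == "sorted-code":
            return sorted(codes)
        if self.seed_order == "insertion":
            return codes
        rng = _random.Random(self.seed)
        rng.shuffle(codes)
        return codes


def _unitig_start_codes(kmer_set: KmerSet) -> set[int]:
    """Codes of nodes at which a maximal unitig can start.

    Uni mode: in-degree != 1, or the unique predecessor has out-degree
    != 1. Bi mode: the analogous oriented condition holds in either
    orientation. Nodes not in this set are internal to a unitig (or sit
    on an isolated cycle).
    """
    k = kmer_set.k
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    members = set(kmer_set.codes)
    starts: set[int] = set()
    if kmer_set.model is StrandModel.BI:

        def successors(fw: int, rc: int) -> list[tuple[int, int]]:
            out = []
            for b in range(4):
                cfw = ((fw << 2) | b) & mask
                crc = (rc >> 2) | ((3 - b) << shift)
                if (cfw if cfw <= crc else crc) in members:
                    out.append((cfw, crc))
            return out

        for c in members:
            rc = revcomp_code(c, k)
            for fw, bw in ((c, rc), (rc, c)):
                back = successors(bw, fw)
                if len(back) != 1 or len(successors(back[0][1], back[0][0])) != 1:
                    starts.add(c)
                    break
    else:
        for u in members:
            base = u >> 2
            preds = [
                w
                for w in (
                    base,
                    base | (1 << shift),
                    base | (2 << shift),
                    base | (3 << shift),
                )
                if w in members
            ]
            if len(preds) != 1:
                starts.add(u)
                continue
            p = (preds[0] << 2) & mask
            if sum((p | b) in members for b in range(4)) != 1:
                starts.add(u)
    return starts


def compute_simplitigs(
    kmer_set: KmerSet, policy: ExtensionPolicy | None = None
) -> Representation:
    """Greedily compute maximal simplitigs of a k-mer set.

    Repeatedly pick the next unused k-mer as a seed, remove it from the
    working set, and extend the growing string: forward first (append one
    base whose induced k-mer — canonical in bi mode — is still unused),
    then backward symmetrically, each direction until no trial base
    succeeds. Every consumed k-mer is removed the moment it is appended,
    so the output carries each input k-mer exactly once.
    """
    policy = policy or ExtensionPolicy()
    k = kmer_set.k
    bi = kmer_set.model is StrandModel.BI
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    order = [_BASE_CODE[b] for b in policy.nucleotide_order]
    working = set(kmer_set.codes)
    sequences: list[str] = []

    for seed in policy.seed_sequence(kmer_set):
        if seed not in working:
            continue
        working.remove(seed)
        chars = list(decode_kmer(seed, k))
        head: list[str] = []  # backward-extended prefix, reversed
        # end-of-string k-mer in written orientation, plus its revcomp
        efw, erc = seed, revcomp_code(seed, k)
        sfw, src = seed, erc
        # forward: append to the (k-1)-suffix
        while True:
            for b in order:
                cfw = ((efw << 2) | b) & mask
                crc = (erc >> 2) | ((3 - b) << shift)
                key = (cfw if cfw <= crc else crc) if bi else cfw
                if key in working:
                    working.remove(key)
                    chars.append(BASES[b])
                    efw, erc = cfw, crc
                    break
            else:
                break
        # backward: prepend to the (k-1)-prefix
        while True:
            for b in order:
                cfw = (sfw >> 2) | (b << shift)
                crc = ((src << 2) | (3 - b)) & mask
                key = (cfw if cfw <= crc else crc) if bi else cfw
                if key in working:
                    working.remove(key)
                    head.append(BASES[b])
                    sfw, src = cfw, crc
                    break
            else:
                break
        head.reverse()
        sequences.append("".join(head) + "".join(chars))

    return Representation(
        kind=SIMPLITIGS, k=k, model=kmer_set.model, sequences=sequences
    )


# ---------------------------------------------------------------------------
# Unitigs


def _compute_unitigs_uni(kmer_set: KmerSet) -> list[str]:
    k = kmer_set.k
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    members = set(kmer_set.codes)

    def successors(u: int) -> list[int]:
        base = (u << 2) & mask
        return [v for v in (base, base | 1, base | 2, base | 3) if v in members]

    def predecessors(u: int) -> list[int]:
        base = u >> 2
        return [
            w
            for w in (base, base | (1 << shift), base | (2 << shift), base | (3 << shift))
            if w in members
        ]

    ordered = sorted(members)
    visited: set[int] = set()
    sequences: list[str] = []

    def walk(u: int) -> None:
        visited.add(u)
        chars = list(decode_kmer(u, k))
        cur = u
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            v = succ[0]
            if v in visited or len(predecessors(v)) != 1:
                break
            visited.add(v)
            chars.append(BASES[v & 3])
            cur = v
        sequences.append("".join(chars))

    for u in ordered:
        if u in visited:
            continue
        preds = predecessors(u)
        if len(preds) != 1 or len(successors(preds[0])) != 1:
            walk(u)
    # remaining nodes sit on isolated cycles; break each at its smallest code
    for u in ordered:
        if u not in visited:
            walk(u)
    return sequences


def _compute_unitigs_bi(kmer_set: KmerSet) -> list[str]:
    # Oriented-node compaction: each canonical k-mer has two orientations
    # (fw, rc); successors extend the written orientation to the right, and
    # the in-degree of an orientation equals the out-degree of its flip.
    k = kmer_set.k
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    members = set(kmer_set.codes)

    def successors(fw: int, rc: int) -> list[tuple[int, int]]:
        out = []
        for b in range(4):
            cfw = ((fw << 2) | b) & mask
            crc = (rc >> 2) | ((3 - b) << shift)
            if (cfw if cfw <= crc else crc) in members:
                out.append((cfw, crc))
        return out

    def indegree(fw: int, rc: int) -> int:
        return len(successors(rc, fw))

    ordered = sorted(members)
    rc_of = {c: revcomp_code(c, k) for c in ordered}
    visited: set[int] = set()
    sequences: list[str] = []

    def walk(fw: int, rc: int) -> None:
        visited.add(fw if fw <= rc else rc)
        chars = list(decode_kmer(fw, k))
        while True:
            succ = successors(fw, rc)
            if len(succ) != 1:
                break
            nfw, nrc = succ[0]
            if (nfw if nfw <= nrc else nrc) in visited:
                break
            if indegree(nfw, nrc) != 1:
                break
            visited.add(nfw if nfw <= nrc else nrc)
            chars.append(BASES[nfw & 3])
            fw, rc = nfw, nrc
        sequences.append("".join(chars))

    def is_start(fw: int, rc: int) -> bool:
        back = successors(rc, fw)
        if len(back) != 1:
            return True
        # unique predecessor is the flip of the unique left-extension
        pfw, prc = back[0][1], back[0][0]
        return len(successors(pfw, prc)) != 1

    for c in ordered:
        rc = rc_of[c]
        for fw, bw in ((c, rc), (rc, c)):
            if c in visited:
                break
            if is_start(fw, bw):
                walk(fw, bw)
    for c in ordered:  # isolated cycles, broken at the smallest canonical code
        if c not in visited:
            walk(c, rc_of[c])
    return sequences


def compute_unitigs(kmer_set: KmerSet) -> Representation:
    """Maximal unitigs of the node-centric de Bruijn graph of a k-mer set.

    A unitig path runs through nodes whose in-degree is 1 and whose
    predecessor's out-degree is 1; neighbors are found by probing all four
    one-base extensions for membership (canonical membership with
    orientation tracking in bi mode). Isolated cycles have no distinguished
    start and are broken at the node with the smallest packed code.
    """
    if kmer_set.model is StrandModel.BI:
        sequences = _compute_unitigs_bi(kmer_set)
    else:
        sequences = _compute_unitigs_uni(kmer_set)
    return Representation(
        kind=UNITIGS, k=kmer_set.k, model=kmer_set.model, sequences=sequences
    )


# ---------------------------------------------------------------------------
# Maximality


@dataclass
class MaximalityReport:
    is_maximal: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.is_maximal


def is_maximal(rep: Representation, kmer_set: KmerSet) -> MaximalityReport:
    """Check that no two sequences of an exactly-once representation can be
    merged by a (k-1)-overlap.

    A representation that already carries every k-mer exactly once is
    maximal iff no sequence end extends into the *first* k-mer of another
    sequence (and symmetrically at the left end). The representation is
    verified for the exactly-once property first and rejected if it fails.
    """
    from .verification import verify  # local import to avoid a cycle

    report = verify(rep, kmer_set)
    if not report.passed:
        raise ValueError(
            "representation fails exactly-once verification; "
            "maximality is undefined"
        )
    k = kmer_set.k
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    bi = kmer_set.model is StrandModel.BI

    def enc(s: str) -> int:
        code = 0
        for ch in s:
            code = (code << 2) | _BASE_CODE[ch]
        return code

    firsts: dict[int, int] = {}  # first k-mer code as written -> seq index
    lasts: dict[int, int] = {}
    ends = []
    for i, seq in enumerate(rep.sequences):
        f = enc(seq[:k])
        l = enc(seq[-k:])
        firsts[f] = i
        lasts[l] = i
        ends.append((f, l))

    violations: list[str] = []

    def flag(i: int, j: int | None, where: str) -> None:
        if j is not None and j != i:
            violations.append(
                f"sequence {i} {where} end merges with sequence {j}"
            )

    for i, seq in enumerate(rep.sequences):
        f, l = ends[i]
        lrc = revcomp_code(l, k)
        frc = revcomp_code(f, k)
        for b in range(4):
            # right end: appending base b induces candidate k-mer cfw;
            # mergeable iff cfw starts another sequence, or (bi) ends one
            # read in reverse orientation (rc(cfw) == that sequence's last)
            cfw = ((l << 2) | b) & mask
            flag(i, firsts.get(cfw), "right")
            if bi:
                crc = (lrc >> 2) | ((3 - b) << shift)
                flag(i, lasts.get(crc), "right")
            # left end: prepending base b
            cfw = (f >> 2) | (b << shift)
            flag(i, lasts.get(cfw), "left")
            if bi:
                crc = ((frc << 2) | (3 - b)) & mask
                flag(i, firsts.get(crc), "left")
    # dedupe, keep order
    violations = list(dict.fromkeys(violations))
    return MaximalityReport(is_maximal=not violations, violations=violations)
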