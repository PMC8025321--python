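"""Exactly-once verification of a representation against a k-mer set.

A representation is correct iff every k-mer of the reference set occurs
exactly once across its sequences and no foreign k-mer occurs. The check
here is an independent occurrence-counting pass over the emitted strings
(plain string slicing and a translation-table reverse complement), on
purpose sharing no machinery with the packed-integer code paths it
audits — the same role an external k-mer counter plays when validating a
compaction tool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .kmers import KmerSet, StrandModel
from .represent import Representation

__all__ = ["VerificationReport", "verify"]

_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class VerificationReport:
    passed: bool
    missing: set[str] = field(default_factory=set)
    extra: set[str] = field(default_factory=set)
    duplicated: dict[str, int] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.passed

    def summary(self) -> str:
        if self.passed:
            return "OK: every k-mer present exactly once"
        return (
            f"FAILED: {len(self.missing)} missing, {len(self.extra)} extra, "
            f"{len(self.duplicated)} duplicated k-mer(s)"
        )


def verify(rep: Representation, kmer_set: KmerSet) -> VerificationReport:
    """Count every (canonical) k-mer occurrence in ``rep`` and classify
    discrepancies against ``kmer_set``.

    ``missing``: reference k-mers absent from the representation.
    ``extra``: observed k-mers not in the reference.
    ``duplicated``: reference k-mers observed more than once, with counts.
    """
    if rep.k != kmer_set.k:
        raise ValueError(f"k mismatch: representation {rep.k} vs set {kmer_set.k}")
    if StrandModel(rep.model) is not kmer_set.model:
        raise ValueError(
            f"strand model mismatch: {rep.model!r} vs {kmer_set.model!r}"
        )
    k = rep.k
    bi = kmer_set.model is StrandModel.BI
    counts: Counter[str] = Counter()
    for seq in rep.sequences:
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"representation sequence contains non-ACGT character(s): "
                f"{sorted(bad)!r}"
            )
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if bi:
                rc = w.translate(_RC)[::-1]
                if rc < w:
                    w = rc
            counts[w] += 1
    reference = set(kmer_set.strings())
    observed = set(counts)
    missing = reference - observed
    extra = observed - reference
    duplicated = {w: c for w, c in counts.items() if c > 1 and w in reference}
    passed = not (missing or extra or duplicated)
    return VerificationReport(
        passed=passed, missing=missing, extra=extra, duplicated=duplicated
    )
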