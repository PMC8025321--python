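"""Desk-scale experiment harness: k-scaling, pan-genome scaling, storage.

Each experiment returns a pandas table (the contract); plotting helpers
are optional conveniences that require matplotlib.

* k-scaling: NS/CL of simplitigs and unitigs across a k range for one
  genome, with the k-mer count as the CL lower-bound column. On a random
  genome of length G the unitig NS peaks near k = log4(G), where nearly
  all 4^k k-mers exist and the graph branches at almost every node.
* pan-genome scaling: the union k-mer set over a growing prefix of a
  simulated genome collection; the NS/CL reduction ratios of simplitigs
  over unitigs grow as added genomes introduce branching.
* storage: bits per distinct k-mer (payload, whole-file, and compressed
  whole-file) for cleaned assemblies, unitigs, and simplitigs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fasta import SequenceRecord, clean_records, format_fasta, records_of
from .kmers import MAX_K, MIN_K, KmerSet, StrandModel, build_kmer_set, iter_codes
from .metrics import (
    bits_per_kmer,
    compressed_bits_per_kmer,
    reduction_ratios,
    stats_of,
)
from .represent import (
    ASSEMBLY,
    ExtensionPolicy,
    Representation,
    compute_simplitigs,
    compute_unitigs,
)
from .synthetic import PanGenomeConfig, simulate_pangenome

__all__ = [
    "k_scaling_experiment",
    "pangenome_scaling_experiment",
    "storage_experiment",
    "load_config",
    "plot_k_scaling",
]


def _both_representations(
    kmer_set: KmerSet, policy: ExtensionPolicy | None = None
) -> tuple[Representation, Representation]:
    return compute_simplitigs(kmer_set, policy), compute_unitigs(kmer_set)


def k_scaling_experiment(
    genome: str,
    k_values: Sequence[int],
    model: StrandModel | str = StrandModel.UNI,
    policy: ExtensionPolicy | None = None,
) -> pd.DataFrame:
    """NS/CL of both representations for each k; one row per k."""
    k_values = list(k_values)
    if not k_values:
        raise ValueError("empty k range")
    for k in k_values:
        if not MIN_K <= k <= MAX_K:
            raise ValueError(f"k={k} outside supported range [{MIN_K}, {MAX_K}]")
    model = StrandModel(model)
    rows = []
    for k in k_values:
        kmer_set = build_kmer_set([genome], k, model)
        simp, unit = _both_representations(kmer_set, policy)
        rows.append(
            {
                "k": k,
                "model": model.value,
                "n_kmers": len(kmer_set),
                "ns_simplitigs": simp.ns,
                "cl_simplitigs": simp.cl,
                "ns_unitigs": unit.ns,
                "cl_unitigs": unit.cl,
            }
        )
    return pd.DataFrame(rows)


def pangenome_scaling_experiment(
    cfg: PanGenomeConfig,
    k: int,
    checkpoints: Sequence[int],
    model: StrandModel | str = StrandModel.BI,
    policy: ExtensionPolicy | None = None,
) -> pd.DataFrame:
    """Union-graph NS/CL and reduction ratios at growing genome counts.

    ``checkpoints`` is a non-decreasing list of how many genomes (prefix
    of the simulated collection) to merge; the k-mer set is accumulated
    incrementally so each genome is scanned once.
    """
    checkpoints = list(checkpoints)
    if not checkpoints:
        raise ValueError("no checkpoints given")
    if any(c < 1 or c > cfg.n_genomes for c in checkpoints):
        raise ValueError(
            f"checkpoints must lie in [1, {cfg.n_genomes}], got {checkpoints}"
        )
    if any(b < a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be non-decreasing")
    model = StrandModel(model)
    genomes = simulate_pangenome(cfg)
    accumulated: dict[int, None] = {}
    loaded = 0
    rows = []
    for m in checkpoints:
        while loaded < m:
            for code in iter_codes(genomes[loaded], k, model):
                accumulated[code] = None
            loaded += 1
        kmer_set = KmerSet(k=k, model=model, codes=dict(accumulated))
        simp, unit = _both_representations(kmer_set, policy)
        s_stats = stats_of(simp, kmer_set)
        u_stats = stats_of(unit, kmer_set)
        ns_ratio, cl_ratio = reduction_ratios(u_stats, s_stats)
        rows.append(
            {
                "n_genomes": m,
                "k": k,
                "model": model.value,
                "n_kmers": len(kmer_set),
                "ns_simplitigs": simp.ns,
                "cl_simplitigs": simp.cl,
                "ns_unitigs": unit.ns,
                "cl_unitigs": unit.cl,
                "ns_reduction": ns_ratio,
                "cl_reduction": cl_ratio,
            }
        )
    return pd.DataFrame(rows)


def storage_experiment(
    inputs: Mapping[str, Iterable[SequenceRecord]],
    k_values: Sequence[int],
    model: StrandModel | str = StrandModel.BI,
    compressor: str | None = "xz",
    min_length: int = 18,
    policy: ExtensionPolicy | None = None,
) -> pd.DataFrame:
    """Bits per distinct k-mer for cleaned assemblies, unitigs, simplitigs.

    Per input x k x representation: payload rate (sequence bytes only,
    bound-comparable, >= 8 for exactly-once representations), whole-file
    rate (headers and newlines included), and the compressed whole-file
    rate when a compressor is given. Reference lines are 8 bits
    (uncompressed) and 2 bits (compressed) per k-mer.
    """
    model = StrandModel(model)
    rows = []
    for name, records in inputs.items():
        cleaned = clean_records(list(records), min_length=min_length)
        for k in k_values:
            kmer_set = build_kmer_set((r.sequence for r in cleaned), k, model)
            if not len(kmer_set):
                continue
            simp, unit = _both_representations(kmer_set, policy)
            assembly = Representation(
                kind=ASSEMBLY,
                k=k,
                model=model,
                sequences=[r.sequence for r in cleaned],
            )
            for rep in (assembly, unit, simp):
                fasta_bytes = format_fasta(records_of(rep)).encode("ascii")
                row = {
                    "input": name,
                    "k": k,
                    "model": model.value,
                    "representation": rep.kind,
                    "n_kmers": len(kmer_set),
                    "ns": rep.ns,
                    "cl": rep.cl,
                    "payload_bits_per_kmer": bits_per_kmer(rep.cl, len(kmer_set)),
                    "file_bits_per_kmer": bits_per_kmer(
                        len(fasta_bytes), len(kmer_set)
                    ),
                    "uncompressed_reference_bits": 8.0,
                    "compressed_reference_bits": 2.0,
                }
                if compressor is not None:
                    row["compressed_file_bits_per_kmer"] = compressed_bits_per_kmer(
                        fasta_bytes, len(kmer_set), compressor
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    config: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    return config


def plot_k_scaling(table: pd.DataFrame, path: str) -> None:
    """Optional NS/CL-vs-k plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_ns, ax_cl) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_ns.plot(table["k"], table["ns_simplitigs"], label="simplitigs")
    ax_ns.plot(table["k"], table["ns_unitigs"], label="unitigs")
    ax_ns.set_xlabel("k")
    ax_ns.set_ylabel("NS")
    ax_ns.legend()
    ax_cl.plot(table["k"], table["cl_simplitigs"], label="simplitigs")
    ax_cl.plot(table["k"], table["cl_unitigs"], label="unitigs")
    ax_cl.plot(table["k"], table["n_kmers"], linestyle="--", label="lower bound")
    ax_cl.set_xlabel("k")
    ax_cl.set_ylabel("CL")
    ax_cl.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
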