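# Methods

## Model

All strings are over {A, C, G, T}. For a k-mer set K, the node-centric
de Bruijn graph G(K) has V = K and an edge u→v whenever
suf_{k−1}(u) = pref_{k−1}(v); edges are implicit, so "k-mer set" and
"graph" are used interchangeably. A path v₁…v_p is spelled by gluing
consecutive nodes across their (k−1)-overlaps; the spelling of a path
of p nodes has length k + p − 1.

A *simplitig set* is the spelling of any vertex-disjoint path cover of
G(K): an acyclic spanning subgraph in which every node has in- and
out-degree ≤ 1. A simplitig set is *maximal* when no simplitig can be
extended by an unused k-mer and no two simplitigs can be merged across a
(k−1)-overlap. A *unitig* is the special case whose internal nodes have
in-degree 1 and whose non-terminal nodes have out-degree 1; maximal
unitigs are unique up to sequence order, reverse complementing, and the
break points of isolated cycles.

Two characteristics summarize a representation: NS (number of
sequences) and CL (cumulative length). For any exactly-once
representation,

    CL = #kmers + (k − 1) · NS,                                   (identity)

with 1 ≤ NS ≤ #kmers and #kmers ≤ CL ≤ k·#kmers. Minimizing NS and CL
is therefore the same problem — the minimum vertex-disjoint path cover,
NP-hard in general — which motivates the greedy heuristic below.

### Strand models

*uni*: k-mers are kept as seen. *bi* (default in the CLI, matching
double-stranded sequencing data): each k-mer is identified with its
reverse complement via the canonical form, the lexicographic minimum of
the pair. Bases are encoded A=0 < C=1 < G=2 < T=3 at 2 bits each, so
integer order on packed codes equals lexicographic order on strings and
canonicalization is a min of two 64-bit integers. k is limited to
[1, 32] so one code fits a 64-bit word; larger k is rejected, never
truncated.

## Greedy simplitig computation

A working copy of K is consumed. Repeatedly: take the next unused k-mer
in the seed order as a new simplitig; extend it to the right by trying
the four bases in lexicographic order against the (k−1)-suffix and
consuming the first k-mer still in the working set (canonical membership
in bi mode), until no trial succeeds; then extend to the left
symmetrically; emit the spelled string. Each appended k-mer — the seed
included — is removed at the moment of use, which enforces the
exactly-once property by construction. The computation is linear in
#kmers with O(1) work per trial (both the forward and reverse-complement
codes of the growing end are maintained incrementally).

### Seed order

The choice of seeds is the only source of variability. Four orders are
provided:

* **unitig-starts** (default): maximal-unitig start nodes (in-degree ≠ 1,
  or the unique predecessor has out-degree ≠ 1; either orientation in bi
  mode) in ascending packed-code order, followed by the remaining
  cycle-internal nodes in ascending order.
* **sorted-code**: plain ascending packed code.
* **insertion**: order of first appearance in the input.
* **random(seed)**: a seeded shuffle, emulating implementations that
  inherit seed order from an unordered hash container.

The default is unitig-starts rather than plain sorted order because of a
subtle interaction with cycles: a seed that lands mid-unitig on a cyclic
component spells that unitig rotated, splitting it across the seam of
the cycle. Seeding only at unitig boundaries (falling back to the
smallest remaining code, which is exactly where unitig computation
breaks an isolated cycle) makes every greedy simplitig a concatenation
of whole maximal unitigs. This guarantees, structurally rather than
empirically, that each maximal unitig occurs as a contiguous substring
of exactly one simplitig and hence NS/CL(simplitigs) ≤ NS/CL(unitigs).
The cost is one degree scan (8 membership probes per node). All orders
are deterministic except `random`, which is reproducible per seed.

### Bi-directed extension contract

The growing simplitig is held in its emitted orientation; membership
tests use canonical codes; a consumed k-mer is removed once regardless
of the orientation in which it matched. Palindromic k-mers (even k only)
are ordinary members consumed once; a trial whose candidate is an
already-consumed palindrome is simply a failed extension.

## Unitig computation

In/out-neighbors are found by probing the four single-base extensions
for membership. A node starts a unitig when its in-degree ≠ 1 or its
unique predecessor has out-degree ≠ 1; runs are compacted from each
start while the current node has out-degree 1 and the next has in-degree
1. In bi mode the same walk runs over oriented nodes (a canonical k-mer
in one of its two orientations); the in-degree of an orientation equals
the out-degree of its flip, and each canonical node is emitted exactly
once. Isolated cycles, which have no distinguished start, are broken at
the node with the smallest packed (canonical) code.

## Maximality checking

Given a representation already verified to carry every k-mer exactly
once, non-maximality reduces to mergeability: some sequence end extends
into the *first* k-mer of a different sequence (or, in bi mode, into
the reverse complement of another sequence's end). The checker indexes
first/last k-mers of all sequences and probes the four extensions of
every end in both orientations, reporting each offending pair. A merge
into the sequence's own first k-mer (a covered cycle) is not a
violation, since no two distinct sequences could be merged.

## Verification

The verifier recounts k-mer occurrences over the emitted strings with
plain string slicing and a translation-table reverse complement —
machinery disjoint from the packed-code pipeline it audits, so it can
serve as an internal stand-in for an external k-mer counter.
Discrepancies are classified as missing, extra, or duplicated (with
multiplicities); a representation passes iff all three sets are empty.

## Synthetic data

`random_genome(G, seed)` draws a uniform i.i.d. ACGT string — the
simplest null model with a known saturation point: for k below
log₄(G) almost all 4^k k-mers occur and the graph branches nearly
everywhere, so the unitig NS peak sits near k = log₄(G).

`simulate_pangenome` models a bacterial-style pan-genome as one base
genome plus per-genome i.i.d. substitutions (rate μ per base, the
substituted base uniform over the three alternatives); an indel option
exists and defaults to 0, since substitutions already create the
branching structure under study. Defaults used by the experiment CLI
and the acceptance script: G = 20 kb, 50 genomes, μ = 0.005, k = 31 —
a divergence typical of within-species isolate collections, scaled to
desk size. What the simulator does *not* reproduce: real gene-content
variation, repeats, horizontal transfer, sequencing/assembly error and
GC skew. Passing tests therefore demonstrate correctness of the
representation machinery and the *direction* of the simplitig-vs-unitig
scaling laws, not quantitative agreement with any particular species.

`min_path_cover_bruteforce` is the exact oracle for tiny uni-directed
graphs (≤ 12 k-mers): depth-first search over edge subsets keeping
degrees ≤ 1 and acyclicity, maximizing edges used; the cover size is
n − max_edges. It is deliberately independent of the greedy code path.
The bi-directed model is out of the oracle's scope (the bidirected
path-cover formalism would have to be replicated just for the oracle);
the greedy-vs-optimum comparison is run in uni mode.

## Storage accounting

Bits per distinct k-mer = 8 · bytes / #kmers. Reported two ways:
payload-only (sequence characters; for an exactly-once representation
this equals 8·CL/#kmers ≥ 8, approaching 8 as NS(k−1)/#kmers → 0) and
whole-file (FASTA headers plus newlines, matching byte-count-based
accounting of files on disk). Compression uses xz (lzma, preset 9) by
default, with bz2/gzip as alternatives; the 2-bit compressed reference
line is reported but never asserted, because highly redundant synthetic
sequences can legitimately compress below it. FASTA output is one line
per sequence with sequential integer headers so byte accounting is
reproducible; a flag restores descriptive headers.

## Cleaning protocol

`clean_records` uppercases, splits at every non-ACGT character (N and
all other IUPAC ambiguity codes alike — k-mers never span an ambiguous
position), drops segments shorter than 18 bp (configurable), and renames
survivors to sequential integers. The same segment-splitting rule is
applied inside `build_kmer_set`, so k-mer extraction is consistent with
cleaning whether or not files are cleaned first.

## Problem sizes and tolerances

The randomized acceptance suite uses 200 instances with genome lengths
log-uniform in [10², 10⁵] bp and k uniform in [3, 32], alternating
strand models — large enough to hit saturated, mixed, and sparse graph
regimes while a full run (tests or acceptance script) stays around a
minute on one CPU. The identity, conservation, bound, and refinement
checks are exact (integer) assertions with no tolerance. The
log₄(G)-peak check uses genomes of length 4⁸ and demands the peak within
±1 of k = 8 for a majority of 5 seeds, reflecting that the peak position
is a statistical, not exact, statement. The tiny-graph catalogue (157
sets, ≤ 10 k-mers each) reports the greedy-equals-optimum rate rather
than asserting it; only greedy ≥ optimum is asserted.

## Known limitations

* Pure-Python throughput is roughly a few hundred thousand k-mers per
  second; multi-megabase genomes are workable, mammalian genomes are not
  the target.
* Strict maximality in bi mode is checked and holds on all random
  instances tried, but palindrome-rich corner cases of the bidirected
  merge semantics are not formally characterized; bi-mode property tests
  assert conservation and bounds.
* k ≤ 32; weighted/colored graphs, abundance filtering, and
  NS/CL-optimal (rather than greedy) simplitigs are out of scope.
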