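"""Desk-scale de novo assembler for amplicon pools.

Short paired-end reads are decomposed into canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement, with odd k so the two never
coincide), cleaned by k-mer-spectrum thresholding plus tip clipping and
bubble popping, and traversed into maximal non-branching contigs.  Amplicon
pools are low-complexity targets, so a single k (default 31) suffices and
full-length products of 350-1,400 bp assemble into single contigs at modest
coverage.  Contigs shorter than 150 bp are removed downstream, mirroring
the pipeline's contig length filter.

All tie-breaking is deterministic (lexicographic), so assemblies are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .pcr import revcomp

DEFAULT_K = 51


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DeBruijnGraph:
    """Canonical k-mer multiset; nodes are (k-1)-mers, edges are k-mers."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def coverage(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    # -- directed double-stranded view ------------------------------------

    def _adjacency(self) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
        out: dict[str, list[str]] = {}
        inc: dict[str, list[str]] = {}
        for c in self.counts:
            for e in {c, revcomp(c)}:
                out.setdefault(e[:-1], []).append(e)
                inc.setdefault(e[1:], []).append(e)
        for d in (out, inc):
            for v in d.values():
                v.sort()
        return out, inc


def _iter_kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i: i + k]


def build_graph(reads: Iterable, k: int = DEFAULT_K) -> DeBruijnGraph:
    """Count canonical k-mers over all read sequences.

    ``reads`` may be plain strings or read-pair records with ``mate1`` /
    ``mate2`` attributes.  Each occurrence of a k-mer in a read increments
    the multiplicity of its canonical form by one, so a read and its
    reverse complement contribute identical edge sets.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[str, int] = {}
    n_reads = 0
    longest = 0
    for item in reads:
        seqs = (
            [item] if isinstance(item, str)
            else [item.mate1, item.mate2]
        )
        for seq in seqs:
            n_reads += 1
            longest = max(longest, len(seq))
            for kmer in _iter_kmers(seq, k):
                c = canonical(kmer)
                counts[c] = counts.get(c, 0) + 1
    if n_reads and longest <= k:
        raise ValueError(f"k={k} must be smaller than the read length ({longest})")
    return DeBruijnGraph(k=k, counts=counts)


# ---------------------------------------------------------------------------
# Unitigs

@dataclass(frozen=True)
class _Unitig:
    edges: tuple[str, ...]  # directed k-mers, consecutive overlap k-1

    @property
    def sequence(self) -> str:
        return self.edges[0] + "".join(e[-1] for e in self.edges[1:])

    @property
    def start_node(self) -> str:
        return self.edges[0][:-1]

    @property
    def end_node(self) -> str:
        return self.edges[-1][1:]


def _unitigs(graph: DeBruijnGraph) -> list[_Unitig]:
    """Maximal non-branching directed paths, deterministically ordered."""
    out, inc = graph._adjacency()

    def is_junction(node: str) -> bool:
        return len(out.get(node, ())) != 1 or len(inc.get(node, ())) != 1

    visited: set[str] = set()
    unitigs: list[_Unitig] = []

    def walk(start_edge: str) -> _Unitig:
        path = [start_edge]
        visited.add(start_edge)
        while True:
            node = path[-1][1:]
            if is_junction(node):
                break
            nxt = out[node][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
        return _Unitig(tuple(path))

    # paths seeded at junctions
    for node in sorted(out):
        if is_junction(node):
            for e in out[node]:
                if e not in visited:
                    unitigs.append(walk(e))
    # leftover simple cycles
    all_edges = sorted(
        e for c in graph.counts for e in {c, revcomp(c)}
    )
    for e in all_edges:
        if e not in visited:
            unitigs.append(walk(e))
    return unitigs


# ---------------------------------------------------------------------------
# Cleaning

def clean_graph(
    graph: DeBruijnGraph,
    solid_min_coverage: int = 2,
    tip_max_len: int = 4 * DEFAULT_K,
    bubble_max_len: int = 2 * DEFAULT_K,
    max_rounds: int = 4,
    weak_branch_ratio: float = 0.2,
) -> DeBruijnGraph:
    """k-mer-spectrum cleaning: weak edges, short tips, small bubbles.

    Edges below ``solid_min_coverage`` are dropped outright.  Tips
    (dead-end paths shorter than ``tip_max_len`` edges attached to a
    branching node) are clipped only when their coverage is below
    ``weak_branch_ratio`` of the continuing branch — at a genuine sequence
    terminus the terminal path carries full coverage and must survive,
    whereas recurrent-error side paths sit far below it.  Parallel simple
    paths between the same two nodes with at most ``bubble_max_len`` edges
    collapse onto the higher-coverage branch (ties keep the
    lexicographically smaller sequence), and junction-to-junction paths
    dominated on both flanks (overlapping-error bubbles that are not simple
    parallel pairs) are dropped by the same coverage ratio.  Cleaning only
    deletes k-mers, never introduces them.
    """
    if min(solid_min_coverage, tip_max_len, bubble_max_len) < 0:
        raise ValueError("cleaning parameters must be >= 0")
    counts = {
        c: v for c, v in graph.counts.items() if v >= solid_min_coverage
    }
    g = DeBruijnGraph(k=graph.k, counts=counts)
    for _ in range(max_rounds):
        removed = _clip_tips(g, tip_max_len, weak_branch_ratio)
        removed |= _pop_bubbles(g, bubble_max_len)
        removed |= _drop_weak_branches(g, weak_branch_ratio)
        if not removed:
            break
    return g


def _mean_cov(graph: DeBruijnGraph, unitig: _Unitig) -> float:
    return sum(graph.coverage(e) for e in unitig.edges) / len(unitig.edges)


def _drop_unitig(graph: DeBruijnGraph, unitig: _Unitig) -> None:
    for e in unitig.edges:
        graph.counts.pop(canonical(e), None)


def _incident_cov(
    graph: DeBruijnGraph,
    unitig_at: dict[str, list["_Unitig"]],
    node: str,
    exclude: "_Unitig",
) -> float:
    """Highest mean coverage among other unitigs touching ``node``."""
    best = 0.0
    for other in unitig_at.get(node, ()):
        if other.edges != exclude.edges:
            best = max(best, _mean_cov(graph, other))
    return best


def _endpoint_index(unitigs: list["_Unitig"]) -> dict[str, list["_Unitig"]]:
    idx: dict[str, list[_Unitig]] = {}
    for u in unitigs:
        idx.setdefault(u.start_node, []).append(u)
        idx.setdefault(u.end_node, []).append(u)
    return idx


def _clip_tips(graph: DeBruijnGraph, tip_max_len: int, ratio: float) -> bool:
    out, inc = graph._adjacency()
    unitigs = _unitigs(graph)
    at = _endpoint_index(unitigs)
    changed = False
    for u in unitigs:
        if len(u.edges) >= tip_max_len:
            continue
        dead_end = len(out.get(u.end_node, ())) == 0
        dead_start = len(inc.get(u.start_node, ())) == 0
        if dead_end == dead_start:
            continue  # isolated linear piece (keep) or internal (not a tip)
        anchor = u.start_node if dead_end else u.end_node
        anchor_cov = _incident_cov(graph, at, anchor, u)
        weak = anchor_cov > 0 and _mean_cov(graph, u) < ratio * anchor_cov
        if weak and any(canonical(e) in graph.counts for e in u.edges):
            _drop_unitig(graph, u)
            changed = True
    return changed


def _drop_weak_branches(graph: DeBruijnGraph, ratio: float) -> bool:
    """Remove junction-to-junction paths dominated on both flanks."""
    out, inc = graph._adjacency()
    unitigs = _unitigs(graph)
    at = _endpoint_index(unitigs)
    changed = False
    for u in unitigs:
        if len(inc.get(u.start_node, ())) == 0 or len(out.get(u.end_node, ())) == 0:
            continue  # a tip or an isolated piece; handled elsewhere
        cov = _mean_cov(graph, u)
        left = _incident_cov(graph, at, u.start_node, u)
        right = _incident_cov(graph, at, u.end_node, u)
        if left > 0 and right > 0 and cov < ratio * min(left, right):
            if any(canonical(e) in graph.counts for e in u.edges):
                _drop_unitig(graph, u)
                changed = True
    return changed


def _pop_bubbles(graph: DeBruijnGraph, bubble_max_len: int) -> bool:
    groups: dict[tuple[str, str], list[_Unitig]] = {}
    for u in _unitigs(graph):
        if u.start_node != u.end_node:
            groups.setdefault((u.start_node, u.end_node), []).append(u)
    changed = False
    for key in sorted(groups):
        branch = [
            u for u in groups[key]
            if len(u.edges) <= bubble_max_len
            and all(canonical(e) in graph.counts for e in u.edges)
        ]
        if len(branch) < 2:
            continue
        branch.sort(key=lambda u: (-_mean_cov(graph, u), u.sequence))
        for loser in branch[1:]:
            _drop_unitig(graph, loser)
            changed = True
    return changed


# ---------------------------------------------------------------------------
# Contigs

@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    mean_kmer_coverage: float

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def extract_contigs(graph: DeBruijnGraph) -> list[Contig]:
    """Emit maximal non-branching paths as contigs.

    Every unitig appears once per strand in the directed view; contigs are
    deduplicated to their canonical orientation (lexicographically smaller
    of sequence / reverse complement) and emitted sorted by sequence.
    """
    seen: dict[str, float] = {}
    for u in _unitigs(graph):
        seq = u.sequence
        rc = revcomp(seq)
        key = seq if seq <= rc else rc
        seen.setdefault(key, _mean_cov(graph, u))
    contigs = [
        Contig(contig_id=f"contig{i + 1:05d}", sequence=seq, mean_kmer_coverage=cov)
        for i, (seq, cov) in enumerate(sorted(seen.items()))
    ]
    return contigs


def filter_contigs(
    contigs: Sequence[Contig], min_len: int = 150
) -> tuple[list[Contig], float]:
    """Drop contigs below ``min_len`` bp; report the removed fraction."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [c for c in contigs if c.length_bp >= min_len]
    total = len(contigs)
    removed_fraction = 0.0 if total == 0 else (total - len(kept)) / total
    return kept, removed_fraction


def assemble(
    reads: Iterable,
    k: int = DEFAULT_K,
    solid_min_coverage: int = 2,
    tip_max_len: int = 4 * DEFAULT_K,
    bubble_max_len: int = 2 * DEFAULT_K,
    min_contig_len: int = 150,
) -> tuple[list[Contig], float]:
    """Build, clean, traverse and length-filter in one call."""
    graph = build_graph(reads, k=k)
    graph = clean_graph(graph, solid_min_coverage, tip_max_len, bubble_max_len)
    return filter_contigs(extract_contigs(graph), min_len=min_contig_len)
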