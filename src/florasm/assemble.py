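"""Desk-scale de novo assembly: de Bruijn contigs, paired-end scaffolds,
gap filling, unigene definition and cross-sample clustering.

The staging mirrors the classic short-read transcriptome recipe:

* reads are decomposed into k-mers and contigs are read off maximal
  *unambiguous* paths of the de Bruijn graph (paths terminate at any
  branch — a branch is never resolved arbitrarily at this stage);
* read pairs mapped back onto contigs link them into scaffolds, with the
  unknown interspace written as a run of ``N`` whose length is estimated
  from the insert size;
* gaps are then filled by a read-threading consensus anchored on exact
  flank matches, and every sequence end is extended the same way until no
  unanimous single-base extension remains — the resulting sequences (fewest
  Ns, inextensible on either end) are the unigenes;
* unigenes from the two phases are clustered by greedy single linkage on
  pairwise local alignments to yield the distinct ("All-unigene") set.

Everything operates on canonical k-mers (lexicographic minimum of a k-mer
and its reverse complement), so a read and its reverse complement induce
the same graph.
"""

from __future__ import annotations

import logging
from array import array
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align

from florasm.dna import canonical, revcomp
from florasm.io import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    k: int = 25
    min_contig_len: int = 100
    min_pair_links: int = 3
    insert_mean: float = 200.0
    min_cluster_identity: float = 0.94
    min_cluster_overlap: int = 40
    max_gap_fill: int = 2000

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
        if not 0 < self.min_cluster_identity <= 1:
            raise ValueError("min_cluster_identity must be in (0, 1]")


@dataclass
class Contig:
    id: str
    sequence: str
    support: int  # mean k-mer multiplicity, rounded

    def __post_init__(self) -> None:
        if "N" in self.sequence:
            raise ValueError(f"contig {self.id}: ambiguous bases not allowed")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Scaffold:
    id: str
    contig_ids: list[str]
    orientations: list[str]  # '+' / '-' per contig
    gap_lengths: list[int]   # between consecutive contigs
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Unigene:
    id: str
    sequence: str
    provenance: list[str]
    phase_origin: int  # 1 or 2 at definition; cluster level may be "both"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClusterSet:
    clusters: list[list[str]]               # lists of unigene ids
    representatives: list[str]              # one id per cluster
    sequences: dict[str, str]               # representative id -> sequence
    phase_origin: dict[str, str]            # representative id -> 1/2/both


# ---------------------------------------------------------------------------
# de Bruijn graph


class DeBruijnGraph:
    """Canonical-k-mer de Bruijn graph with observed-edge multiplicities.

    Nodes are the canonical k-mers seen in the reads; an edge exists only
    where the (k+1)-mer joining two k-mers was observed.  Adjacency is kept
    for both orientations of every k-mer so traversal is strand-aware.
    """

    def __init__(self, k: int):
        self.k = k
        self.coverage: Counter[str] = Counter()       # canonical k-mer counts
        self.succ: dict[str, Counter] = defaultdict(Counter)  # oriented -> base

    def add_read(self, bases: str) -> None:
        k = self.k
        if len(bases) < k:
            return
        prev = None
        for i in range(len(bases) - k + 1):
            kmer = bases[i : i + k]
            self.coverage[canonical(kmer)] += 1
            if prev is not None:
                self.succ[prev][kmer[-1]] += 1
                self.succ[revcomp(kmer)][revcomp(prev)[-1]] += 1
            prev = kmer

    @property
    def n_nodes(self) -> int:
        return len(self.coverage)

    def out_bases(self, oriented: str) -> list[str]:
        return sorted(self.succ.get(oriented, ()))

    def in_degree(self, oriented: str) -> int:
        return len(self.succ.get(revcomp(oriented), ()))

    def out_degree(self, oriented: str) -> int:
        return len(self.succ.get(oriented, ()))


def build_graph(reads: Iterable[ReadRecord | str], k: int) -> DeBruijnGraph:
    """Build the graph from cleaned (N-free) reads."""
    g = DeBruijnGraph(k)
    for read in reads:
        bases = read if isinstance(read, str) else read.bases
        if len(bases) < k:
            raise ValueError(f"k={k} not smaller than read length {len(bases)}")
        g.add_read(bases)
    return g


def extract_contigs(graph: DeBruijnGraph, cfg: AssemblyConfig) -> list[Contig]:
    """Read contigs off maximal unambiguous paths.

    A path extends from an oriented k-mer while the current node has
    exactly one outgoing edge *and* the next node has exactly one incoming
    edge; interior nodes therefore have in-degree = out-degree = 1.
    Contigs below ``min_contig_len`` are dropped.  Isolated simple cycles
    are linearized once from their lexicographically smallest k-mer.
    """
    k = graph.k
    visited: set[str] = set()
    raw: list[tuple[str, int]] = []  # (sequence, summed coverage)

    def walk(start: str) -> tuple[str, int]:
        seq = [start]
        cov = graph.coverage[canonical(start)]
        # cycle guard on ORIENTED k-mers: a canonical k-mer may legitimately
        # recur in the opposite orientation (palindromic overlap)
        on_path = {start}
        cur = start
        while True:
            outs = graph.out_bases(cur)
            if len(outs) != 1:
                break
            nxt = cur[1:] + outs[0]
            if graph.in_degree(nxt) != 1 or nxt in on_path:
                break
            seq.append(outs[0])
            cov += graph.coverage[canonical(nxt)]
            on_path.add(nxt)
            cur = nxt
        visited.update(canonical(x) for x in on_path)
        return start + "".join(seq[1:]), cov

    # pass 1: walk from every path start, in deterministic order
    for canon in sorted(graph.coverage):
        for oriented in (canon, revcomp(canon)):
            if canon in visited:
                break
            indeg = graph.in_degree(oriented)
            is_start = indeg != 1
            if not is_start:
                # unique predecessor in forward orientation: the sole
                # successor base b of rc(x) gives pred = rc(b) + x[:-1]
                b = next(iter(graph.succ[revcomp(oriented)]))
                pred_fwd = revcomp(b) + oriented[:-1]
                is_start = graph.out_degree(pred_fwd) != 1
            if is_start:
                raw.append(walk(oriented))
    # pass 2: anything left is a cycle
    for canon in sorted(graph.coverage):
        if canon not in visited:
            raw.append(walk(canon))

    contigs = []
    for seq, cov in raw:
        if len(seq) < cfg.min_contig_len:
            continue
        seq = min(seq, revcomp(seq))
        n_kmers = len(seq) - k + 1
        contigs.append((seq, int(round(cov / n_kmers))))
    contigs.sort(key=lambda c: (-len(c[0]), c[0]))
    return [Contig(f"contig{i:06d}", seq, sup)
            for i, (seq, sup) in enumerate(contigs)]


# ---------------------------------------------------------------------------
# read mapping (exact, seed-and-verify)


class ExactMapper:
    """Exact full-length read placement on a reference set, both strands."""

    def __init__(self, references: dict[str, str], k: int):
        self.refs = references
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rid, seq in references.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((rid, i))

    def map_read(self, bases: str) -> list[tuple[str, int, str]]:
        """All exact placements as (ref_id, start, strand)."""
        hits = []
        for strand, query in (("+", bases), ("-", revcomp(bases))):
            if len(query) < self.k:
                continue
            seed = query[: self.k]
            for rid, pos in self.index.get(seed, ()):
                ref = self.refs[rid]
                if ref[pos : pos + len(query)] == query:
                    hits.append((rid, pos, strand))
        return hits


# ---------------------------------------------------------------------------
# scaffolding


def _oriented_pos(pos: int, read_len: int, ref_len: int, orient: str) -> int:
    return pos if orient == "+" else ref_len - pos - read_len


def scaffold(
    contigs: Sequence[Contig],
    read_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    cfg: AssemblyConfig,
) -> list[Scaffold]:
    """Link contigs via uniquely mapped read pairs.

    A pair whose mates map uniquely to two different contigs implies a
    directed, oriented adjacency; bundles with >= ``min_pair_links``
    orientation-consistent links become edges, with the gap estimated as
    ``insert_mean`` minus the observed flank spans (floored at 1 N).
    Components containing a branch are left unscaffolded.
    """
    contig_seqs = {c.id: c.sequence for c in contigs}
    lengths = {c.id: len(c.sequence) for c in contigs}
    mapper = ExactMapper(contig_seqs, cfg.k)

    bundles: dict[tuple, list[float]] = defaultdict(list)
    conflicted: set[tuple[str, str]] = set()
    for r1, r2 in read_pairs:
        h1 = mapper.map_read(r1.bases)
        h2 = mapper.map_read(r2.bases)
        if len(h1) != 1 or len(h2) != 1:
            continue
        (ca, pa, sa), (cb, pb, sb) = h1[0], h2[0]
        if ca == cb:
            continue
        # orient the fragment so mate 1 reads forward: contig A appears with
        # orientation sa, contig B with the flip of sb, and A precedes B
        oa, ob = sa, ("-" if sb == "+" else "+")
        la, lb = lengths[ca], lengths[cb]
        span_a = la - _oriented_pos(pa, len(r1.bases), la, oa)
        span_b = _oriented_pos(pb, len(r2.bases), lb, ob) + len(r2.bases)
        gap = cfg.insert_mean - span_a - span_b
        key = (ca, oa, cb, ob)
        flipped = (cb, "-" if ob == "+" else "+", ca, "-" if oa == "+" else "+")
        bundles[min(key, flipped)].append(gap)

    # collapse to accepted edges, rejecting contig pairs linked in
    # contradictory orientations
    by_pair: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for key in bundles:
        a, _, b, _ = key
        by_pair[tuple(sorted((a, b)))].append(key)
    edges: list[tuple[str, str, str, str, int]] = []
    for pair, keys in sorted(by_pair.items()):
        keys = [k for k in keys if len(bundles[k]) >= cfg.min_pair_links]
        if len(keys) > 1:
            logger.warning("contradictory link orientations between %s; discarded",
                           pair)
            continue
        if not keys:
            continue
        a, oa, b, ob = keys[0]
        gaps = bundles[keys[0]]
        gap = max(1, round(sum(gaps) / len(gaps)))
        edges.append((a, oa, b, ob, gap))

    # build a port graph: each contig has ports L/R in its native strand.
    # edge (a, oa, b, ob): leaves a via port R if oa='+' else L, and enters
    # b via port L if ob='+' else R.
    port_edges: dict[tuple[str, str], tuple[str, str, int]] = {}
    branched: set[str] = set()
    for a, oa, b, ob, gap in edges:
        pa = (a, "R" if oa == "+" else "L")
        pb = (b, "L" if ob == "+" else "R")
        for p, q in ((pa, pb), (pb, pa)):
            if p in port_edges:
                branched.add(p[0])
                branched.add(port_edges[p][0])
            port_edges[p] = (q[0], q[1], gap)
    # propagate branching through components
    adj: dict[str, set[str]] = defaultdict(set)
    for (a, _), (b, _, _) in port_edges.items():
        adj[a].add(b)
        adj[b].add(a)
    bad = set()
    stack = list(branched)
    while stack:
        c = stack.pop()
        if c in bad:
            continue
        bad.add(c)
        stack.extend(adj[c] - bad)

    linked = {a for a in adj if a not in bad}
    scaffolds: list[Scaffold] = []
    used: set[str] = set()
    idx = 0
    for start in sorted(linked):
        if start in used:
            continue
        # find a terminal port to start the walk from
        def free_port(c: str) -> Optional[str]:
            for side in ("L", "R"):
                if (c, side) not in port_edges:
                    return side
            return None

        term = start
        side = free_port(term)
        seen = {term}
        while side is None:  # walk to a terminus (acyclic chains only)
            nxt, nside, _ = port_edges[(term, "L")]
            if nxt in seen:
                break  # circular component: linearize from 'start'
            term, seen = nxt, seen | {nxt}
            side = free_port(term)
        side = side or "L"

        chain: list[tuple[str, str, int]] = []  # (contig, orient, gap_after)
        cur, enter = term, side
        while True:
            used.add(cur)
            orient = "+" if enter == "L" else "-"
            exit_port = "R" if enter == "L" else "L"
            nxt = port_edges.get((cur, exit_port))
            if nxt is None or nxt[0] in used:
                chain.append((cur, orient, 0))
                break
            chain.append((cur, orient, nxt[2]))
            cur, enter = nxt[0], nxt[1]

        if len(chain) < 2:
            continue
        parts, cids, orients, gaps = [], [], [], []
        for j, (cid, orient, gap) in enumerate(chain):
            seq = contig_seqs[cid]
            parts.append(seq if orient == "+" else revcomp(seq))
            cids.append(cid)
            orients.append(orient)
            if j < len(chain) - 1:
                parts.append("N" * gap)
                gaps.append(gap)
        scaffolds.append(Scaffold(f"scaffold{idx:06d}", cids, orients, gaps,
                                  "".join(parts)))
        idx += 1
    return scaffolds


# ---------------------------------------------------------------------------
# read-threading consensus (gap filling and end extension)


class ReadThreader:
    """Consensus single-base extension anchored on exact read substrings.

    The anchor is the trailing ``anchor_len`` bases of the current
    sequence; reads containing the anchor (either strand) vote on the next
    base, and extension proceeds only while the vote is unanimous.  Using
    anchors up to nearly a full read length lets a spanning read thread
    through a branch that is ambiguous at the k-mer level.
    """

    def __init__(self, reads: Sequence[str], k: int, anchor_len: int = 40):
        self.k = k
        self.anchor_len = anchor_len
        self.reads = list(reads)
        self.by_kmer: dict[str, array] = defaultdict(lambda: array("i"))
        for ridx, bases in enumerate(self.reads):
            seen = set()
            for i in range(len(bases) - k + 1):
                kmer = canonical(bases[i : i + k])
                if kmer not in seen:
                    self.by_kmer[kmer].append(ridx)
                    seen.add(kmer)

    @classmethod
    def from_pairs(cls, read_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
                   k: int, anchor_len: int = 40) -> "ReadThreader":
        flat = []
        for r1, r2 in read_pairs:
            flat.append(r1.bases)
            flat.append(r2.bases)
        return cls(flat, k, anchor_len)

    def next_base_votes(self, context: str) -> Counter:
        anchor = context[-self.anchor_len:]
        tail = anchor[-self.k:]
        votes: Counter = Counter()
        for ridx in self.by_kmer.get(canonical(tail), ()):
            bases = self.reads[ridx]
            for strand_seq in (bases, revcomp(bases)):
                start = 0
                while True:
                    i = strand_seq.find(anchor, start)
                    if i < 0:
                        break
                    j = i + len(anchor)
                    if j < len(strand_seq):
                        votes[strand_seq[j]] += 1
                    start = i + 1
        return votes

    def extend(self, seq: str, max_steps: int,
               stop_probe: Optional[str] = None) -> tuple[str, Optional[int]]:
        """Extend ``seq`` rightward by unanimous votes.

        If ``stop_probe`` is given, stops when the extension's tail matches
        it and returns the extension length at the match; otherwise extends
        until votes stop being unanimous or ``max_steps`` is reached.
        """
        added = []
        for _ in range(max_steps):
            votes = self.next_base_votes(seq)
            if len(votes) != 1:
                break
            base = next(iter(votes))
            seq += base
            added.append(base)
            if stop_probe is not None and seq.endswith(stop_probe):
                return seq, len(added)
        return seq, None


def fill_gaps(
    scaffolds: Sequence[Scaffold],
    read_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    cfg: AssemblyConfig,
    threader: Optional[ReadThreader] = None,
) -> list[Scaffold]:
    """Replace N runs by a read consensus where reads tile across the gap
    unambiguously; gaps that cannot be closed (no anchoring reads, or
    conflicting tilings) keep their Ns.  The total N count never increases.
    """
    if threader is None:
        threader = ReadThreader.from_pairs(read_pairs, cfg.k)
    probe_len = cfg.k
    out = []
    for sc in scaffolds:
        segments = [s for s in _split_on_gaps(sc.sequence)]
        filled = [segments[0][1]]
        new_gaps = []
        for (is_gap, text), (_, right) in zip(segments[1::2], segments[2::2]):
            left = filled[-1]
            probe = right[:probe_len]
            budget = min(cfg.max_gap_fill, len(text) + 6 * int(cfg.insert_mean))
            extended, hit = threader.extend(left, budget, stop_probe=probe)
            if hit is not None:
                filled[-1] = extended[: len(extended) - probe_len]
                filled.append(right)
                new_gaps.append(0)
            else:
                logger.info("scaffold %s: gap of %d Ns left unfilled",
                            sc.id, len(text))
                filled.append("N" * len(text))
                filled.append(right)
                new_gaps.append(len(text))
        seq = "".join(filled)
        gaps = [g for g in new_gaps if g > 0]
        out.append(Scaffold(sc.id, sc.contig_ids, sc.orientations, gaps, seq))
    return out


def _split_on_gaps(seq: str) -> list[tuple[bool, str]]:
    """Alternating (is_gap, text) segments, starting and ending with
    non-gap text (possibly empty)."""
    parts: list[tuple[bool, str]] = []
    i = 0
    while i < len(seq):
        is_gap = seq[i] == "N"
        j = i
        while j < len(seq) and (seq[j] == "N") == is_gap:
            j += 1
        parts.append((is_gap, seq[i:j]))
        i = j
    if not parts or parts[0][0]:
        parts.insert(0, (False, ""))
    if parts[-1][0]:
        parts.append((False, ""))
    return parts


def define_unigenes(
    sequences: Sequence[tuple[str, str]],
    read_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    cfg: AssemblyConfig,
    phase: int,
    threader: Optional[ReadThreader] = None,
) -> list[Unigene]:
    """Extension closure over filled scaffolds and leftover contigs.

    Each sequence end is extended by the read-threading consensus until no
    unanimous extension remains ("could not be further extended on either
    end"); exact duplicates (up to reverse complement) are merged.
    """
    if threader is None:
        threader = ReadThreader.from_pairs(read_pairs, cfg.k)
    max_steps = cfg.max_gap_fill * 5
    results: dict[str, list[str]] = {}
    for sid, seq in sequences:
        ext, _ = threader.extend(seq, max_steps)
        left_rc, _ = threader.extend(revcomp(ext), max_steps)
        final = revcomp(left_rc)
        key = min(final, revcomp(final))
        results.setdefault(key, []).append(sid)
    unigenes = [
        Unigene(f"p{phase}_unigene{i:06d}", seq, sorted(prov), phase)
        for i, (seq, prov) in enumerate(sorted(results.items(),
                                               key=lambda kv: (-len(kv[0]), kv[0])))
    ]
    return unigenes


# ---------------------------------------------------------------------------
# cross-sample clustering


def _local_alignment_stats(a: str, b: str) -> tuple[float, int]:
    """(identity, overlap columns) of the best local alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    best = None
    for query in (b, revcomp(b)):
        aln = aligner.align(a, query)
        if len(aln) == 0:
            continue
        top = aln[0]
        if best is None or top.score > best.score:
            best = top
    if best is None:
        return 0.0, 0
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        seg_a = best.sequences[0][a0:a1]
        seg_b = best.sequences[1][b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += a1 - a0
    # count gap columns inside the aligned region
    blocks_a, blocks_b = best.aligned
    if len(blocks_a) > 1:
        for i in range(1, len(blocks_a)):
            columns += max(blocks_a[i][0] - blocks_a[i - 1][1],
                           blocks_b[i][0] - blocks_b[i - 1][1])
    if columns == 0:
        return 0.0, 0
    return matches / columns, columns


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_unigenes(
    unigenes: Sequence[Unigene], cfg: AssemblyConfig
) -> ClusterSet:
    """Greedy single-linkage clustering of unigenes from both phases.

    Candidate pairs must share at least one canonical k-mer; a candidate
    pair joins when its best local alignment reaches
    ``min_cluster_identity`` over at least ``min_cluster_overlap`` columns.
    The longest member represents each cluster.
    """
    if not unigenes:
        raise ValueError("cluster_unigenes requires at least one unigene")
    seqs = {u.id: u.sequence for u in unigenes}
    phases = {u.id: u.phase_origin for u in unigenes}
    k = cfg.k
    by_kmer: dict[str, list[str]] = defaultdict(list)
    for uid in sorted(seqs):
        seen = set()
        s = seqs[uid]
        for i in range(len(s) - k + 1):
            c = canonical(s[i : i + k])
            if c not in seen:
                by_kmer[c].append(uid)
                seen.add(c)
    candidates = set()
    for ids in by_kmer.values():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                candidates.add((ids[i], ids[j]))
    uf = _UnionFind(seqs)
    for a, b in sorted(candidates):
        if uf.find(a) == uf.find(b):
            continue
        ident, overlap = _local_alignment_stats(seqs[a], seqs[b])
        if ident >= cfg.min_cluster_identity and overlap >= cfg.min_cluster_overlap:
            uf.union(a, b)
    groups: dict[str, list[str]] = defaultdict(list)
    for uid in sorted(seqs):
        groups[uf.find(uid)].append(uid)
    clusters, reps, rep_seqs, rep_phase = [], [], {}, {}
    for root in sorted(groups):
        members = groups[root]
        rep = max(members, key=lambda u: (len(seqs[u]), u))
        clusters.append(members)
        reps.append(rep)
        rep_seqs[rep] = seqs[rep]
        ph = {phases[m] for m in members}
        rep_phase[rep] = "both" if len(ph) > 1 else str(ph.pop())
    return ClusterSet(clusters, reps, rep_seqs, rep_phase)


# ---------------------------------------------------------------------------
# phase-level driver


@dataclass
class PhaseAssembly:
    contigs: list[Contig]
    scaffolds: list[Scaffold]
    unigenes: list[Unigene]


def assemble_phase(
    read_pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    cfg: AssemblyConfig,
    phase: int,
) -> PhaseAssembly:
    """contigs -> scaffolds -> gap fill -> unigenes for one phase."""
    reads = [r.bases for pr in read_pairs for r in pr]
    graph = build_graph(reads, cfg.k)
    contigs = extract_contigs(graph, cfg)
    scaffolds = scaffold(contigs, read_pairs, cfg)
    threader = ReadThreader(reads, cfg.k)
    filled = fill_gaps(scaffolds, read_pairs, cfg, threader=threader)
    in_scaffold = {cid for sc in scaffolds for cid in sc.contig_ids}
    pieces = [(sc.id, sc.sequence) for sc in filled]
    pieces += [(c.id, c.sequence) for c in contigs if c.id not in in_scaffold]
    unigenes = define_unigenes(pieces, read_pairs, cfg, phase, threader=threader)
    return PhaseAssembly(contigs, scaffolds, unigenes)
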