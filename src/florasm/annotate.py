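"""Annotation summarization from precomputed homology hits.

Homology searches themselves are out of scope; this module consumes hit
tables in the ubiquitous 12-column tabular alignment format (query,
subject, % identity, alignment length, mismatches, gap opens, q. start,
q. end, s. start, s. end, E-value, bit score), one table per protein
database.  Hits at E-value >= 1e-5 are discarded; for each query the best
passing hit from the highest-priority database (Nr > SwissProt > KEGG >
COG) wins and donates the sequence direction via its frame/strand.
Queries with no passing hit fall back to a longest-open-reading-frame
direction heuristic (``orf_fallback``).

GO-slim mapping follows map2slim semantics: a query maps to the slim
terms reachable from its assigned terms through is_a/part_of ancestor
paths that do not pass through another slim term (nearest-slim-ancestor
with shadowing; reflexive on slim terms).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import obonet
import pandas as pd

from florasm.dna import revcomp

DATABASE_PRIORITY = ("Nr", "SwissProt", "KEGG", "COG")
DEFAULT_EVALUE_CUTOFF = 1e-5

LENGTH_BINS = ((100, 500), (500, 1000), (1000, 2000), (2000, None))

BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitRecord:
    query: str
    database: str
    subject: str
    pident: float
    length: int
    evalue: float
    strand: str  # '+' or '-', from query coordinate order
    bitscore: float

    def __post_init__(self) -> None:
        if self.database not in DATABASE_PRIORITY:
            raise ValueError(f"unknown database label {self.database!r}")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not 0 <= self.pident <= 100:
            raise ValueError("percent identity must be in [0, 100]")


@dataclass
class AnnotationAssignment:
    query: str
    database: Optional[str]
    subject: Optional[str]
    direction: str  # '+', '-', 'unknown'
    source: str     # 'hit' or 'orf_fallback'
    evalue: Optional[float] = None
    pident: Optional[float] = None


def read_hit_table(path: str | Path, database: str) -> list[HitRecord]:
    """Parse one 12-column tabular hit file for a named database."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        strand = "+" if row.qstart <= row.qend else "-"
        hits.append(HitRecord(str(row.query), database, str(row.subject),
                              float(row.pident), int(row.length),
                              float(row.evalue), strand, float(row.bitscore)))
    return hits


def _orf_direction(seq: str) -> str:
    """Strand holding the longest stop-free codon run over six frames."""
    stops = {"TAA", "TAG", "TGA"}

    def longest_orf(s: str) -> int:
        best = 0
        for frame in range(3):
            run = 0
            for i in range(frame, len(s) - 2, 3):
                if s[i : i + 3] in stops:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
        return best

    fwd, rev = longest_orf(seq), longest_orf(revcomp(seq))
    if fwd == rev:
        return "unknown"
    return "+" if fwd > rev else "-"


def select_annotations(
    hits: Iterable[HitRecord],
    sequences: Optional[dict[str, str]] = None,
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[AnnotationAssignment]:
    """Choose one annotation per query by database priority.

    Hits with ``evalue >= cutoff`` are discarded.  Within the
    highest-priority database holding a passing hit, the best hit wins
    (lowest E-value, ties by bit score then subject id), deterministically
    under input permutation.  Queries given in ``sequences`` but without a
    passing hit get an ``orf_fallback`` direction call.
    """
    by_query: dict[str, dict[str, list[HitRecord]]] = defaultdict(
        lambda: defaultdict(list))
    for h in hits:
        if h.evalue < cutoff:
            by_query[h.query][h.database].append(h)
    out = []
    queries = set(by_query)
    if sequences:
        queries |= set(sequences)
    for q in sorted(queries):
        chosen = None
        for db in DATABASE_PRIORITY:
            cands = by_query.get(q, {}).get(db)
            if cands:
                chosen = min(cands, key=lambda h: (h.evalue, -h.bitscore,
                                                   h.subject))
                break
        if chosen is not None:
            out.append(AnnotationAssignment(q, chosen.database, chosen.subject,
                                            chosen.strand, "hit",
                                            chosen.evalue, chosen.pident))
        elif sequences and q in sequences:
            out.append(AnnotationAssignment(q, None, None,
                                            _orf_direction(sequences[q]),
                                            "orf_fallback"))
    return out


def length_binned_match_rate(
    lengths: dict[str, int], assignments: Sequence[AnnotationAssignment]
) -> pd.DataFrame:
    """Per length-bin proportion of unigenes holding a homology-based
    annotation (bins half-open: [100,500), [500,1000), [1000,2000),
    [2000,inf); shorter sequences fall into an 'other' bin)."""
    annotated = {a.query for a in assignments if a.source == "hit"}
    rows = []
    bins = list(LENGTH_BINS) + [(0, 100)]
    labels = ["100-500", "500-1000", "1000-2000", ">=2000", "other"]
    for (lo, hi), label in zip(bins, labels):
        ids = [u for u, L in lengths.items()
               if L >= lo and (hi is None or L < hi)]
        n = len(ids)
        m = sum(1 for u in ids if u in annotated)
        rows.append({"bin": label, "n_unigenes": n, "n_matched": m,
                     "match_rate": m / n if n else float("nan")})
    return pd.DataFrame(rows)


def homology_class_summary(
    assignments: Sequence[AnnotationAssignment],
) -> pd.DataFrame:
    """E-value class (strong: e < 1e-50; moderate otherwise) and identity
    class (high: > 80%; mid: <= 80%) proportions over matched queries."""
    matched = [a for a in assignments if a.source == "hit"]
    n = len(matched)
    strong = sum(1 for a in matched if a.evalue < 1e-50)
    high = sum(1 for a in matched if a.pident is not None and a.pident > 80.0)
    rows = [
        {"classification": "evalue_strong", "count": strong,
         "proportion": strong / n if n else float("nan")},
        {"classification": "evalue_moderate", "count": n - strong,
         "proportion": (n - strong) / n if n else float("nan")},
        {"classification": "identity_high", "count": high,
         "proportion": high / n if n else float("nan")},
        {"classification": "identity_mid", "count": n - high,
         "proportion": (n - high) / n if n else float("nan")},
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ontology handling


class OntologyDAG:
    """Directed acyclic ontology over is_a / part_of parent links."""

    RELATIONS = ("is_a", "part_of")

    def __init__(self, graph: nx.MultiDiGraph, slim: set[str]):
        self.graph = graph  # edges child -> parent
        self.slim = set(slim)
        missing = self.slim - set(graph.nodes)
        if missing:
            raise ValueError(f"slim terms absent from ontology: {sorted(missing)}")
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")

    @classmethod
    def from_obo(cls, obo_path: str | Path, slim_path: str | Path) -> "OntologyDAG":
        raw = obonet.read_obo(str(obo_path))
        g = nx.MultiDiGraph()
        g.add_nodes_from(raw.nodes)
        for child, parent, key in raw.edges(keys=True):
            if key in cls.RELATIONS:
                g.add_edge(child, parent, key=key)
        with open(slim_path) as fh:
            slim = {line.strip() for line in fh if line.strip()}
        return cls(g, slim)

    def parents(self, term: str) -> list[str]:
        return sorted(set(self.graph.successors(term)))

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(c, p, k) for c, p, k in self.graph.edges(keys=True)}


def map_to_slim(
    assignments: dict[str, set[str]], dag: OntologyDAG
) -> dict[str, set[str]]:
    """Map each query's terms to its nearest slim ancestors.

    A slim term S is reported for a query iff some assigned term reaches S
    along an ancestor path (reflexive) with no other slim term strictly
    between — upward traversal simply stops at slim terms.
    """
    cache: dict[str, frozenset[str]] = {}

    def nearest_slim(term: str) -> frozenset[str]:
        if term in cache:
            return cache[term]
        if term in dag.slim:
            result = frozenset([term])
        else:
            found: set[str] = set()
            for parent in dag.parents(term):
                found |= nearest_slim(parent)
            result = frozenset(found)
        cache[term] = result
        return result

    out: dict[str, set[str]] = {}
    for query, terms in assignments.items():
        mapped: set[str] = set()
        for term in terms:
            if term not in dag.graph.nodes:
                raise ValueError(f"term {term!r} absent from ontology")
            mapped |= nearest_slim(term)
        out[query] = mapped
    return out


def read_assignments(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (id, comma-separated terms) TSV."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[1]:
                out[parts[0]] = set(parts[1].split(","))
            else:
                out[parts[0]] = set()
    return out


def write_assignments(assignments: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tterms\n")
        for q in sorted(assignments):
            fh.write(f"{q}\t{','.join(sorted(assignments[q]))}\n")
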