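"""Synthetic inputs for the pipeline: transcriptomes, two-phase read sets
with known differential-expression structure, and toy ontologies.

The generator emulates a two-condition bulk RNA-seq experiment on a
short-read instrument: ~75 bp paired-end reads drawn from cDNA fragments
whose size follows a gel-excision window of 200±25 bp, with configurable
substitution errors, adaptor read-through, ambiguous base calls, low-quality
tails and chastity-filter failures.  Every read pair's true origin and every
artifact injected is logged to a truth table so downstream modules can be
tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from florasm.dna import random_dna, revcomp
from florasm.io import ReadRecord

# Widely used library adaptor (P7 side); only its presence matters here.
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class SyntheticTranscriptome:
    """A toy transcript set, optionally carrying a shared repeat block."""

    transcripts: list[tuple[str, str]]
    repeat_spec: Optional[tuple[int, int]] = None  # (length bp, copy count)
    repeat_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        if any(not seq for _, seq in self.transcripts):
            raise ValueError("transcript sequences must be non-empty")

    @property
    def ids(self) -> list[str]:
        return [tid for tid, _ in self.transcripts]

    def as_dict(self) -> dict[str, str]:
        return dict(self.transcripts)


@dataclass
class AbundanceProfile:
    """Expected per-transcript read-pair abundances for the two phases.

    ``de`` maps a transcript id to ``(fold, up_phase)``: the transcript's
    expected abundance is multiplied by ``fold`` (>= 2) in the named phase.
    """

    baseline: dict[str, float]
    de: dict[str, tuple[float, int]] = field(default_factory=dict)
    phase_totals: tuple[int, int] = (10_000, 10_000)

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.baseline.values()):
            raise ValueError("baseline abundances must be positive")
        for tid, (fold, up) in self.de.items():
            if tid not in self.baseline:
                raise ValueError(f"DE member {tid!r} not in baseline")
            if fold < 2:
                raise ValueError(f"DE fold for {tid!r} must be >= 2, got {fold}")
            if up not in (1, 2):
                raise ValueError("up_phase must be 1 or 2")

    def weights(self, phase: int) -> dict[str, float]:
        w = dict(self.baseline)
        for tid, (fold, up) in self.de.items():
            if up == phase:
                w[tid] *= fold
        return w


@dataclass
class SimulationConfig:
    read_length: int = 75
    insert_mean: float = 200.0
    insert_sd: float = 12.5
    error_rate: float = 0.0
    adaptor_rate: float = 0.0
    n_rate: float = 0.0
    lowq_rate: float = 0.0
    fail_chastity_rate: float = 0.0
    adaptor: str = DEFAULT_ADAPTOR
    phred_offset: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "adaptor_rate", "n_rate", "lowq_rate",
                     "fail_chastity_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")

    @property
    def min_transcript_length(self) -> int:
        return int(math.ceil(self.insert_mean + 3 * self.insert_sd))


def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (300, 2000),
    repeat_spec: Optional[tuple[int, int]] = None,
    seed: int = 0,
    read_length: int = 75,
) -> SyntheticTranscriptome:
    """Draw ``n_transcripts`` random transcripts with uniform lengths.

    ``repeat_spec`` = (length, copies) inserts one verbatim copy of a shared
    block into each of ``copies`` transcripts, creating assembly branch
    points.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo > hi:
        raise ValueError("length_range must be (min, max) with min <= max")
    if lo < 3 * read_length:
        raise ValueError(
            f"minimum transcript length {lo} below 3 x read length "
            f"({3 * read_length}); too short for paired-end sampling"
        )
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_transcripts)
    transcripts = [
        (f"TX{i:05d}", random_dna(int(lengths[i]), rng))
        for i in range(n_transcripts)
    ]
    repeat_seq = None
    if repeat_spec is not None:
        rep_len, copies = repeat_spec
        if copies > n_transcripts:
            raise ValueError("repeat copy count exceeds transcript count")
        if rep_len >= lo:
            raise ValueError("repeat longer than shortest transcript")
        repeat_seq = random_dna(rep_len, rng)
        carriers = rng.choice(n_transcripts, size=copies, replace=False)
        for i in sorted(int(c) for c in carriers):
            tid, seq = transcripts[i]
            pos = int(rng.integers(1, len(seq) - rep_len))
            transcripts[i] = (tid, seq[:pos] + repeat_seq + seq[pos + rep_len:])
    return SyntheticTranscriptome(transcripts, repeat_spec, repeat_seq)


def random_profile(
    txome: SyntheticTranscriptome,
    pairs_per_phase: int | tuple[int, int] = 10_000,
    de_fraction: float = 0.1,
    fold: float = 4.0,
    seed: int = 0,
) -> AbundanceProfile:
    """Log-normal baseline abundances with a designated DE subset.

    DE members are split evenly (up in phase 1 vs phase 2).
    """
    rng = np.random.default_rng([seed, 9173])
    ids = txome.ids
    baseline = {
        tid: float(b) for tid, b in zip(ids, rng.lognormal(0.0, 0.6, len(ids)))
    }
    n_de = int(round(de_fraction * len(ids)))
    de_ids = [ids[int(i)] for i in rng.choice(len(ids), size=n_de, replace=False)]
    de = {
        tid: (float(fold), 1 if j % 2 == 0 else 2)
        for j, tid in enumerate(sorted(de_ids))
    }
    if isinstance(pairs_per_phase, int):
        pairs_per_phase = (pairs_per_phase, pairs_per_phase)
    return AbundanceProfile(baseline=baseline, de=de, phase_totals=pairs_per_phase)


def _truncated_insert_lengths(
    rng: np.random.Generator, n: int, cfg: SimulationConfig, tlen: int
) -> np.ndarray:
    lo = max(cfg.read_length, cfg.insert_mean - 2 * cfg.insert_sd)
    hi = min(tlen, cfg.insert_mean + 2 * cfg.insert_sd)
    if lo > hi:
        lo = hi
    out = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n))
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, bad.sum()))
    return np.clip(out, lo, hi).astype(int)


def _base_quals(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(np.rint(rng.normal(37.0, 2.5, size=n)), 20, 41).astype(int)


def _inject_substitutions(
    seq: list[str], rng: np.random.Generator, rate: float
) -> int:
    if rate <= 0:
        return 0
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        orig = seq[i]
        alt = "ACGT"[int(rng.integers(0, 3))]
        seq[i] = alt if alt != orig else "ACGT"[3]
    return len(hits)


def simulate_paired_reads(
    txome: SyntheticTranscriptome,
    profile: AbundanceProfile,
    cfg: SimulationConfig,
    phase: int,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], pd.DataFrame]:
    """Simulate one phase's paired-end library.

    Returns the list of mate pairs and a truth table (one row per pair)
    recording the source transcript, 0-based half-open fragment
    coordinates, fragment strand, DE status and injected artifacts.
    """
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    seqs = txome.as_dict()
    min_len = cfg.min_transcript_length
    for tid, seq in seqs.items():
        if len(seq) < min_len:
            raise ValueError(
                f"transcript {tid!r} ({len(seq)} bp) shorter than insert_mean"
                f" + 3*insert_sd = {min_len} bp"
            )
    rng = np.random.default_rng([cfg.seed, phase, 2718])
    ids = list(profile.baseline)
    w = profile.weights(phase)
    weights = np.array([w[t] for t in ids], dtype=float)
    total = profile.phase_totals[phase - 1]
    counts = rng.multinomial(total, weights / weights.sum())

    L = cfg.read_length
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truth_rows: list[dict] = []
    pair_idx = 0
    for t_i, tid in enumerate(ids):
        n_pairs = int(counts[t_i])
        if n_pairs == 0:
            continue
        tseq = seqs[tid]
        tlen = len(tseq)
        frags = _truncated_insert_lengths(rng, n_pairs, cfg, tlen)
        starts = rng.integers(0, tlen - frags + 1)
        strands = rng.integers(0, 2, size=n_pairs)  # 0 = +, 1 = -
        is_de = tid in profile.de
        for j in range(n_pairs):
            flen, start = int(frags[j]), int(starts[j])
            frag = tseq[start : start + flen]
            if strands[j] == 1:
                frag = revcomp(frag)
            b1 = list(frag[:L])
            b2 = list(revcomp(frag[-L:]))
            q1 = _base_quals(rng, L)
            q2 = _base_quals(rng, L)
            err1 = _inject_substitutions(b1, rng, cfg.error_rate)
            err2 = _inject_substitutions(b2, rng, cfg.error_rate)
            art = {}
            for mate, b, q in ((1, b1, q1), (2, b2, q2)):
                adap = rng.random() < cfg.adaptor_rate
                if adap:
                    alen = int(rng.integers(15, min(L, len(cfg.adaptor)) + 1))
                    b[L - alen :] = list(cfg.adaptor[:alen])
                nn = rng.random() < cfg.n_rate
                if nn:
                    k = 1 + int(rng.poisson(0.5))
                    for pos in rng.integers(0, L, size=k):
                        b[int(pos)] = "N"
                        q[int(pos)] = 2
                lowq = rng.random() < cfg.lowq_rate
                if lowq:
                    k = int(math.floor(0.10 * L)) + 1 + int(rng.integers(0, 4))
                    pos = rng.choice(L, size=min(k, L), replace=False)
                    q[pos] = rng.integers(2, 20, size=len(pos))
                chast = rng.random() < cfg.fail_chastity_rate
                art[mate] = (adap, nn, lowq, chast)
            rid = f"P{phase}R{pair_idx:08d}"
            r1 = ReadRecord(rid, 1, "".join(b1), [int(x) for x in q1],
                            passfilter=not art[1][3])
            r2 = ReadRecord(rid, 2, "".join(b2), [int(x) for x in q2],
                            passfilter=not art[2][3])
            pairs.append((r1, r2))
            truth_rows.append({
                "pair_id": rid,
                "transcript_id": tid,
                "frag_start": start,
                "frag_end": start + flen,
                "strand": "-" if strands[j] else "+",
                "is_de": is_de,
                "errors_1": err1, "errors_2": err2,
                "adaptor_1": art[1][0], "adaptor_2": art[2][0],
                "ambiguous_1": art[1][1], "ambiguous_2": art[2][1],
                "lowq_1": art[1][2], "lowq_2": art[2][2],
                "chastity_fail_1": art[1][3], "chastity_fail_2": art[2][3],
            })
            pair_idx += 1
    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def tile_paired_reads(
    txome: SyntheticTranscriptome,
    cfg: Optional[SimulationConfig] = None,
    depth: float = 20.0,
    phase: int = 1,
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Systematic error-free pairs tiling every transcript end to end.

    Fragments of length ``insert_mean`` are placed at a regular stride
    chosen so mean per-base coverage is about ``depth``; the first and last
    placements always touch the transcript ends, so every position is
    covered.  Useful for exact-recovery assembly tests.
    """
    cfg = cfg or SimulationConfig()
    L = cfg.read_length
    flen = int(cfg.insert_mean)
    stride = max(1, int(2 * L / depth))
    pairs = []
    idx = 0
    for tid, seq in txome.transcripts:
        if len(seq) < flen:
            raise ValueError(f"transcript {tid!r} shorter than the insert size")
        starts = sorted(set(range(0, len(seq) - flen + 1, stride))
                        | {len(seq) - flen})
        for start in starts:
            frag = seq[start : start + flen]
            rid = f"P{phase}T{idx:08d}"
            q = [38] * L
            pairs.append((
                ReadRecord(rid, 1, frag[:L], list(q)),
                ReadRecord(rid, 2, revcomp(frag[-L:]), list(q)),
            ))
            idx += 1
    return pairs


# ---------------------------------------------------------------------------
# Ontology fixtures


@dataclass
class OntologyFixture:
    """A random acyclic ontology with a slim subset and term assignments."""

    terms: list[str]
    edges: list[tuple[str, str, str]]  # (child, parent, type in {is_a, part_of})
    slim: set[str]
    assignments: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        term_set = set(self.terms)
        if not self.slim <= term_set:
            raise ValueError("slim terms must be a subset of terms")
        for q, ts in self.assignments.items():
            if not ts <= term_set:
                raise ValueError(f"assignment for {q!r} uses unknown terms")


def generate_ontology_fixture(
    n_terms: int,
    depth: int = 4,
    slim_fraction: float = 0.25,
    seed: int = 0,
    part_of_fraction: float = 0.2,
) -> OntologyFixture:
    """Random layered DAG: term i at layer l draws 1-2 parents from layers
    < l, so the graph is acyclic by construction.  The root is always in
    the slim so slim mapping is never empty.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng([seed, 4242])
    terms = [f"FT:{i:07d}" for i in range(n_terms)]
    layers = np.minimum(
        np.concatenate([[0], rng.integers(1, max(depth, 1) + 1, n_terms - 1)]),
        np.arange(n_terms),  # term i can only cite parents with smaller index
    )
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        candidates = [j for j in range(i) if layers[j] < layers[i]] or [0]
        n_par = int(rng.integers(1, min(2, len(candidates)) + 1))
        parents = rng.choice(candidates, size=n_par, replace=False)
        for p in sorted(int(x) for x in parents):
            etype = "part_of" if rng.random() < part_of_fraction else "is_a"
            edges.append((terms[i], terms[p], etype))
    n_slim = max(1, int(round(slim_fraction * n_terms)))
    slim_idx = set(rng.choice(n_terms, size=n_slim, replace=False).tolist())
    slim_idx.add(0)
    if slim_fraction >= 1.0:
        slim_idx = set(range(n_terms))
    slim = {terms[i] for i in slim_idx}
    return OntologyFixture(terms=terms, edges=edges, slim=slim)


def random_assignments(
    fixture: OntologyFixture, ids: list[str], mean_terms: float = 2.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign each id 1+Poisson(mean_terms-1) random ontology terms."""
    rng = np.random.default_rng([seed, 5151])
    out: dict[str, set[str]] = {}
    n = len(fixture.terms)
    for q in ids:
        k = 1 + int(rng.poisson(max(mean_terms - 1, 0)))
        picks = rng.choice(n, size=min(k, n), replace=False)
        out[q] = {fixture.terms[int(i)] for i in picks}
    return out


def write_obo(fixture: OntologyFixture, path: str | Path) -> None:
    """Serialize the fixture as a minimal OBO 1.2 document."""
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in fixture.terms}
    for child, parent, etype in fixture.edges:
        parents[child].append((parent, etype))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: florasm-fixture\n")
        for t in fixture.terms:
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            for parent, etype in parents[t]:
                if etype == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def write_slim(fixture: OntologyFixture, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(fixture.slim):
            fh.write(t + "\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic homology-hit fixtures (the pipeline consumes hits as
# precomputed tables; no search is ever run)

_HIT_DATABASES = ("Nr", "SwissProt", "KEGG", "COG")


def simulate_hit_tables(
    ids: list[str],
    annotation_rate: float = 0.7,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Random 12-column tabular hit tables, one per protein database.

    Each annotated query receives hits in one to four databases with
    log-uniform E-values (a mix of strong and moderate homology) and
    identities in the observed 23-100% range; a small fraction of hits
    fall above the 1e-5 cutoff so cutoff handling is exercised.
    """
    rng = np.random.default_rng([seed, 6060])
    rows: dict[str, list] = {db: [] for db in _HIT_DATABASES}
    for q in ids:
        if rng.random() >= annotation_rate:
            if rng.random() < 0.2:  # sub-threshold hit only
                db = _HIT_DATABASES[int(rng.integers(0, 4))]
                rows[db].append(_random_hit_row(q, rng, log10_e=-3.0))
            continue
        n_dbs = 1 + int(rng.integers(0, 4))
        dbs = rng.choice(len(_HIT_DATABASES), size=n_dbs, replace=False)
        for d in sorted(int(x) for x in dbs):
            log10_e = float(rng.uniform(-70.0, -5.01))
            rows[_HIT_DATABASES[d]].append(_random_hit_row(q, rng, log10_e))
    from florasm.annotate import BLAST6_COLUMNS

    return {db: pd.DataFrame(r, columns=BLAST6_COLUMNS)
            for db, r in rows.items()}


def _random_hit_row(q: str, rng: np.random.Generator, log10_e: float) -> list:
    pident = float(np.round(rng.uniform(23.0, 100.0), 2))
    alen = int(rng.integers(50, 400))
    minus = rng.random() < 0.5
    qstart, qend = (alen * 3, 1) if minus else (1, alen * 3)
    subject = f"sp|{int(rng.integers(0, 10**6)):06d}"
    bitscore = float(np.round(40.0 - 1.8 * log10_e + rng.normal(0, 5), 1))
    return [q, subject, pident, alen, int(rng.integers(0, 20)), 0,
            qstart, qend, 1, alen, float(10.0 ** log10_e), bitscore]


def random_ko_assignments(
    ids: list[str], seed: int = 0, n_terms: int = 30
) -> dict[str, set[str]]:
    """Flat KO-style term assignments (pathway terms without a DAG)."""
    rng = np.random.default_rng([seed, 7070])
    terms = [f"KO:K{i:05d}" for i in range(n_terms)]
    out = {}
    for q in ids:
        k = 1 + int(rng.poisson(0.7))
        picks = rng.choice(n_terms, size=min(k, n_terms), replace=False)
        out[q] = {terms[int(i)] for i in picks}
    return out
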