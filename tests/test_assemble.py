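"""Assembly staging: graph structure, contig extraction vs a brute-force
path oracle, scaffolding, gap filling, unigene closure and clustering."""

import numpy as np
import pytest

import florasm.assemble as asm
import florasm.simulate as sim
from florasm.dna import canonical, random_dna, revcomp
from florasm.io import ReadRecord

CFG = asm.AssemblyConfig()


def _pairs_from_fragments(seq, starts, flen, rid_prefix="p"):
    out = []
    for i, s in enumerate(starts):
        frag = seq[s : s + flen]
        q = [38] * 75
        out.append((ReadRecord(f"{rid_prefix}{i}", 1, frag[:75], list(q)),
                    ReadRecord(f"{rid_prefix}{i}", 2, revcomp(frag[-75:]), list(q))))
    return out


# ---------------------------------------------------------------------------
# independent contig oracle: explicit oriented graph, no canonicalization


def oracle_contigs(reads: list[str], k: int) -> set[str]:
    """Enumerate maximal unambiguous paths by brute force on the oriented
    k-mer graph built from observed (k+1)-mers of both strands."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for read in reads:
        for strand in (read, revcomp(read)):
            for i in range(len(strand) - k + 1):
                nodes.add(strand[i : i + k])
            for i in range(len(strand) - k):
                edges.add((strand[i : i + k], strand[i + 1 : i + k + 1]))
    out = {n: sorted(b for a, b in edges if a == n) for n in nodes}
    indeg = {n: sum(1 for a, b in edges if b == n) for n in nodes}

    contigs: set[str] = set()
    for start in nodes:
        preds = [a for a, b in edges if b == start]
        if not (indeg[start] != 1 or len(out[preds[0]]) != 1):
            continue
        path = [start]
        seen = {start}
        cur = start
        while len(out[cur]) == 1 and indeg[out[cur][0]] == 1 \
                and out[cur][0] not in seen:
            cur = out[cur][0]
            path.append(cur)
            seen.add(cur)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        contigs.add(min(seq, revcomp(seq)))
    return contigs


def impl_contigs(reads: list[str], k: int, min_len=0) -> set[str]:
    g = asm.build_graph(reads, k)
    cfg = asm.AssemblyConfig(k=k, min_contig_len=min_len)
    return {c.sequence for c in asm.extract_contigs(g, cfg)}


class TestGraphAndContigs:
    def test_single_read_linear_path(self):
        # 11 bp read, k=5: seven k-mers, all canonically distinct and free
        # of self-reverse-complement (k+1)-mers, so the path is linear
        read = "AAACCCTTTGG"
        g = asm.build_graph([read], 5)
        kmers = {canonical(read[i:i + 5]) for i in range(7)}
        assert len(kmers) == 7 and g.n_nodes == 7
        assert impl_contigs([read], 5) == {min(read, revcomp(read))}

    def test_reverse_complement_gives_identical_graph(self, rng):
        read = random_dna(60, rng)
        g1 = asm.build_graph([read], 25)
        g2 = asm.build_graph([revcomp(read)], 25)
        assert g1.coverage == g2.coverage
        assert {k: dict(v) for k, v in g1.succ.items()} == \
               {k: dict(v) for k, v in g2.succ.items()}

    def test_disjoint_reads_make_disconnected_components(self, rng):
        a, b = random_dna(50, rng), random_dna(50, rng)
        assert len(impl_contigs([a, b], 25)) == 2

    def test_empty_read_set(self):
        g = asm.build_graph([], 25)
        assert asm.extract_contigs(g, CFG) == []

    def test_noiseless_tiling_recovers_transcript(self, rng):
        tx = random_dna(900, rng)
        reads = [tx[i : i + 75] for i in range(0, 826, 5)]
        contigs = impl_contigs(reads, 25, min_len=100)
        assert contigs == {min(tx, revcomp(tx))}

    def test_contigs_match_brute_force_oracle_on_random_graphs(self, rng):
        for trial in range(20):
            n_reads = int(rng.integers(2, 8))
            reads = [random_dna(int(rng.integers(30, 60)), rng)
                     for _ in range(n_reads)]
            assert impl_contigs(reads, 15) == oracle_contigs(reads, 15), reads

    def test_shared_repeat_breaks_contigs_at_branches(self, rng):
        """Two transcripts with a shared 100 bp block, k=25: contigs stop
        at the branch points (verified against the path oracle)."""
        block = random_dna(100, rng)
        t1 = random_dna(300, rng) + block + random_dna(300, rng)
        t2 = random_dna(300, rng) + block + random_dna(300, rng)
        reads = [t[i : i + 75] for t in (t1, t2)
                 for i in range(0, len(t) - 74, 3)]
        got = impl_contigs(reads, 25)
        assert got == oracle_contigs(reads, 25)
        assert len(got) > 2  # broken at branches
        for t in (t1, t2):
            assert min(t, revcomp(t)) not in got

    def test_contig_kmers_all_observed_in_reads(self, rng):
        reads = [random_dna(80, rng) for _ in range(10)]
        observed = {canonical(r[i:i + 25]) for r in reads
                    for i in range(len(r) - 24)}
        for c in impl_contigs(reads, 25):
            for i in range(len(c) - 24):
                assert canonical(c[i:i + 25]) in observed

    def test_min_contig_len_monotonicity(self, rng):
        reads = [random_dna(120, rng) for _ in range(15)]
        sizes = [len(impl_contigs(reads, 25, min_len=m)) for m in (0, 50, 110)]
        assert sizes == sorted(sizes, reverse=True)

    def test_k_not_below_read_length(self):
        with pytest.raises(ValueError, match="k=25"):
            asm.build_graph(["ACGTACGT"], 25)


class TestScaffold:
    @pytest.fixture()
    def gapped(self, rng):
        """A 900 bp transcript covered on [0,400) and [450,900) only."""
        tx = random_dna(900, rng)
        reads = [tx[s:s + 75] for s in range(0, 326, 5)]
        reads += [tx[450:][s:s + 75] for s in range(0, 376, 5)]
        cfg = asm.AssemblyConfig(insert_mean=250.0)
        contigs = asm.extract_contigs(asm.build_graph(reads, 25), cfg)
        spanning = _pairs_from_fragments(tx, range(277, 326, 4), 250)
        return tx, contigs, spanning, cfg

    def test_gap_length_estimated_from_insert(self, gapped):
        tx, contigs, spanning, cfg = gapped
        scafs = asm.scaffold(contigs, spanning, cfg)
        assert len(scafs) == 1
        sc = scafs[0]
        # oracle: true uncovered interval is [400, 450)
        assert sc.gap_lengths == [50]
        body = sc.sequence.replace("N", "")
        expected = tx[:400] + tx[450:]
        assert body in (expected, revcomp(expected))

    def test_no_spanning_pairs_means_no_scaffolds(self, gapped):
        _, contigs, _, cfg = gapped
        assert asm.scaffold(contigs, [], cfg) == []

    def test_link_threshold_enforced(self, gapped):
        tx, contigs, spanning, cfg = gapped
        assert asm.scaffold(contigs, spanning[:2], cfg) == []

    def test_min_pair_links_monotonicity(self, gapped):
        _, contigs, spanning, cfg = gapped
        counts = []
        for links in (1, 3, 100):
            c = asm.AssemblyConfig(insert_mean=250.0, min_pair_links=links)
            counts.append(len(asm.scaffold(contigs, spanning, c)))
        assert counts == sorted(counts, reverse=True)


class TestGapFill:
    def _scaffolded(self, rng):
        tx = random_dna(900, rng)
        reads = [tx[s:s + 75] for s in range(0, 326, 5)]
        reads += [tx[450:][s:s + 75] for s in range(0, 376, 5)]
        cfg = asm.AssemblyConfig(insert_mean=250.0)
        contigs = asm.extract_contigs(asm.build_graph(reads, 25), cfg)
        spanning = _pairs_from_fragments(tx, range(277, 326, 4), 250)
        return tx, asm.scaffold(contigs, spanning, cfg), cfg

    def test_fully_tiled_gap_closes_exactly(self, rng):
        tx, scafs, cfg = self._scaffolded(rng)
        closers = _pairs_from_fragments(tx, range(0, 751, 5), 150, "c")
        filled = asm.fill_gaps(scafs, closers, cfg)
        assert filled[0].sequence.count("N") == 0
        assert filled[0].sequence in (tx, revcomp(tx))

    def test_unreachable_gap_left_untouched(self, rng):
        tx, scafs, cfg = self._scaffolded(rng)
        filled = asm.fill_gaps(scafs, [], cfg)
        assert filled[0].sequence.count("N") == 50

    def test_conflicting_tilings_leave_gap(self, rng):
        tx, scafs, cfg = self._scaffolded(rng)
        # two read populations disagree right after the left flank
        variant = tx[:400] + revcomp(random_dna(50, rng)) + tx[450:]
        closers = _pairs_from_fragments(tx, range(250, 551, 10), 150, "a")
        closers += _pairs_from_fragments(variant, range(250, 551, 10), 150, "b")
        filled = asm.fill_gaps(scafs, closers, cfg)
        assert filled[0].sequence.count("N") == 50  # never increases either


class TestUnigenes:
    def test_noiseless_single_transcript_library(self, rng):
        tx = random_dna(700, rng)
        pairs = _pairs_from_fragments(tx, range(0, 551, 5), 150)
        pa = asm.assemble_phase(pairs, CFG, phase=1)
        assert len(pa.unigenes) == 1
        assert pa.unigenes[0].sequence in (tx, revcomp(tx))
        assert pa.unigenes[0].phase_origin == 1

    def test_branch_limits_unigene_count(self, rng):
        """With a shared block longer than the read length, reads cannot
        thread through and the unigene count matches the unambiguous-path
        count of the small graph."""
        block = random_dna(120, rng)  # > read length: unresolvable
        t1 = random_dna(250, rng) + block + random_dna(250, rng)
        t2 = random_dna(250, rng) + block + random_dna(250, rng)
        pairs = []
        for tag, t in (("a", t1), ("b", t2)):
            pairs += _pairs_from_fragments(t, range(0, len(t) - 149, 3), 150, tag)
        reads = [r.bases for p in pairs for r in p]
        pa = asm.assemble_phase(pairs, asm.AssemblyConfig(min_contig_len=30), 1)
        n_paths = len(oracle_contigs(reads, 25))
        assert len(pa.unigenes) <= n_paths
        assert len(pa.unigenes) > 2


class TestClustering:
    def test_exact_duplicate_across_phases(self, rng):
        seq = random_dna(500, rng)
        u = [asm.Unigene("a", seq, [], 1), asm.Unigene("b", seq, [], 2)]
        cs = asm.cluster_unigenes(u, CFG)
        assert len(cs.clusters) == 1
        assert cs.phase_origin[cs.representatives[0]] == "both"

    def test_unrelated_sequences_stay_apart(self, rng):
        u = [asm.Unigene("a", random_dna(400, rng), [], 1),
             asm.Unigene("b", random_dna(400, rng), [], 2)]
        cs = asm.cluster_unigenes(u, CFG)
        assert len(cs.clusters) == 2

    def test_single_linkage_chain(self, rng):
        x, y, z, w = (random_dna(200, rng) for _ in range(4))
        ua = asm.Unigene("A", x + y, [], 1)
        ub = asm.Unigene("B", y + z, [], 1)
        uc = asm.Unigene("C", z + w, [], 2)
        cs = asm.cluster_unigenes([ua, ub, uc], CFG)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0]) == ["A", "B", "C"]

    def test_representative_is_longest_member(self, rng):
        seq = random_dna(500, rng)
        u = [asm.Unigene("short", seq[:450], [], 1),
             asm.Unigene("long", seq, [], 2)]
        cs = asm.cluster_unigenes(u, CFG)
        assert cs.representatives == ["long"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            asm.cluster_unigenes([], CFG)


def test_noiseless_two_phase_recovery(small_txome):
    """Tiling error-free pairs in both phases: the distinct unigene set
    equals the transcript set up to reverse complement."""
    truth = {min(s, revcomp(s)) for _, s in small_txome.transcripts}
    unigenes = []
    for phase in (1, 2):
        pairs = sim.tile_paired_reads(small_txome, depth=12, phase=phase)
        unigenes.extend(asm.assemble_phase(pairs, CFG, phase).unigenes)
    cs = asm.cluster_unigenes(unigenes, CFG)
    got = {min(s, revcomp(s)) for s in cs.sequences.values()}
    assert got == truth
    assert all(v == "both" for v in cs.phase_origin.values())
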