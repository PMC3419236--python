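"""End-to-end orchestration: simulate -> qc -> assemble -> quantify ->
annotate -> enrich, with a Table-1-style summary report.

Each stage reads the previous stage's in-memory outputs (and mirrors them
to files under the output directory in standard formats).  A single seed
drives every stochastic stage.  The final report's internal arithmetic
(count x mean length vs total length, DE tallies) is verified on every
run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from florasm import annotate as ann
from florasm import assemble as asm
from florasm import enrich as enr
from florasm import qc as qcm
from florasm import quantify as qt
from florasm import simulate as sim
from florasm.io import write_fasta, write_fastq

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "assemble", "quantify", "annotate", "enrich")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("florasm_out")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    n_transcripts: int = 20
    length_range: tuple[int, int] = (300, 2000)
    pairs_per_phase: int = 20_000
    de_fraction: float = 0.1
    fold: float = 4.0
    error_rate: float = 0.0
    adaptor_rate: float = 0.01
    n_rate: float = 0.01
    lowq_rate: float = 0.01
    fail_chastity_rate: float = 0.01
    # annotate / enrich fixtures
    annotation_rate: float = 0.7
    n_terms: int = 60
    slim_fraction: float = 0.25
    # nested module configs
    qc: qcm.QCConfig = field(default_factory=qcm.QCConfig)
    assembly: asm.AssemblyConfig = field(default_factory=asm.AssemblyConfig)
    fold_min: float = 2.0
    fdr_max: float = 0.001
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "qc":
                kwargs["qc"] = qcm.QCConfig(**value)
            elif key == "assembly":
                kwargs["assembly"] = asm.AssemblyConfig(**value)
            elif key == "out_dir":
                kwargs["out_dir"] = Path(value)
            elif key in ("length_range", "stages"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PhaseSummary:
    read_pairs: int = 0
    clean_pairs: int = 0
    n_contigs: int = 0
    mean_contig_len: int = 0
    n_scaffolds: int = 0
    mean_scaffold_len: int = 0
    n_unigenes: int = 0
    mean_unigene_len: int = 0
    total_unigene_len: int = 0


@dataclass
class SummaryReport:
    phases: dict[int, PhaseSummary] = field(default_factory=dict)
    n_distinct_unigenes: int = 0
    mean_distinct_len: int = 0
    total_distinct_len: int = 0
    de_total: int = 0
    de_up1: int = 0
    de_up2: int = 0
    de_unique_to_1: int = 0
    de_unique_to_2: int = 0

    def check(self) -> None:
        """Verify every arithmetic identity the report asserts."""
        for phase, ps in self.phases.items():
            if ps.n_unigenes:
                if abs(ps.total_unigene_len
                       - ps.mean_unigene_len * ps.n_unigenes) > ps.n_unigenes:
                    raise AssertionError(
                        f"phase {phase}: mean x count does not reproduce the "
                        f"total unigene length within rounding")
        if self.n_distinct_unigenes:
            if abs(self.total_distinct_len - self.mean_distinct_len
                   * self.n_distinct_unigenes) > self.n_distinct_unigenes:
                raise AssertionError(
                    "distinct set: mean x count does not reproduce the total "
                    "length within rounding")
        if self.de_total != self.de_up1 + self.de_up2:
            raise AssertionError(
                f"DE accounting violated: {self.de_total} != "
                f"{self.de_up1} + {self.de_up2}")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for phase, ps in sorted(self.phases.items()):
            for key, value in asdict(ps).items():
                rows.append((f"phase{phase}_{key}", value))
        for key in ("n_distinct_unigenes", "mean_distinct_len",
                    "total_distinct_len", "de_total", "de_up1", "de_up2",
                    "de_unique_to_1", "de_unique_to_2"):
            rows.append((key, getattr(self, key)))
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in rows:
                fh.write(f"{key}\t{value}\n")


def mean_length(total: int, count: int) -> int:
    """Mean sequence length rounded half-up, 0 for an empty set."""
    if count == 0:
        logger.warning("mean length of an empty sequence set reported as 0")
        return 0
    return int(math.floor(total / count + 0.5))


def total_bases(n_reads: int, read_length: int) -> int:
    return n_reads * read_length


@dataclass
class PipelineResult:
    report: SummaryReport
    cluster_set: Optional[asm.ClusterSet] = None
    abundance: Optional[pd.DataFrame] = None
    truth: dict[int, pd.DataFrame] = field(default_factory=dict)
    enrichment: Optional[list[enr.EnrichmentResult]] = None


def _summarize_lengths(seqs: Sequence[str]) -> tuple[int, int, int]:
    total = sum(len(s) for s in seqs)
    return len(seqs), mean_length(total, len(seqs)), total


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the configured stages in order; any failure aborts with the
    stage name and cause."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = SummaryReport()
    result = PipelineResult(report)
    stages = [s for s in ALL_STAGES if s in cfg.stages]
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if not stages:
        logger.warning("all stages disabled; writing an empty report")
        report.to_tsv(out / "summary.tsv")
        return result

    state: dict = {}
    for stage in stages:
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, state, result, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done", stage)

    report.check()
    report.to_tsv(out / "summary.tsv")
    return result


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(
            f"stage {needed_by!r} requires output of skipped stage {stage!r}")
    return state[key]


def _stage_simulate(cfg: PipelineConfig, state: dict, result: PipelineResult,
                    out: Path) -> None:
    txome = sim.generate_transcriptome(cfg.n_transcripts, cfg.length_range,
                                       seed=cfg.seed)
    profile = sim.random_profile(txome, cfg.pairs_per_phase, cfg.de_fraction,
                                 cfg.fold, seed=cfg.seed)
    sim_cfg = sim.SimulationConfig(
        error_rate=cfg.error_rate, adaptor_rate=cfg.adaptor_rate,
        n_rate=cfg.n_rate, lowq_rate=cfg.lowq_rate,
        fail_chastity_rate=cfg.fail_chastity_rate, seed=cfg.seed)
    write_fasta(txome.transcripts, out / "transcriptome.fasta")
    state["txome"], state["profile"] = txome, profile
    state["raw"] = {}
    for phase in (1, 2):
        pairs, truth = sim.simulate_paired_reads(txome, profile, sim_cfg, phase)
        state["raw"][phase] = pairs
        result.truth[phase] = truth
        sim.write_truth_table(truth, out / f"truth_phase{phase}.tsv")
        write_fastq((r for p in pairs for r in (p[0],)),
                    out / f"phase{phase}_1.fastq")
        write_fastq((r for p in pairs for r in (p[1],)),
                    out / f"phase{phase}_2.fastq")
        result.report.phases.setdefault(phase, PhaseSummary()).read_pairs = \
            len(pairs)


def _stage_qc(cfg: PipelineConfig, state: dict, result: PipelineResult,
              out: Path) -> None:
    raw = _require(state, "raw", "simulate", "qc")
    state["clean"] = {}
    for phase in (1, 2):
        kept, qreport = qcm.filter_pairs(raw[phase], cfg.qc)
        state["clean"][phase] = kept
        qreport.to_tsv(out / f"qc_phase{phase}.tsv")
        result.report.phases[phase].clean_pairs = qreport.surviving_pairs
        write_fastq((p[0] for p in kept), out / f"clean_phase{phase}_1.fastq")
        write_fastq((p[1] for p in kept), out / f"clean_phase{phase}_2.fastq")


def _stage_assemble(cfg: PipelineConfig, state: dict, result: PipelineResult,
                    out: Path) -> None:
    clean = _require(state, "clean", "qc", "assemble")
    unigenes = []
    for phase in (1, 2):
        pa = asm.assemble_phase(clean[phase], cfg.assembly, phase)
        unigenes.extend(pa.unigenes)
        ps = result.report.phases[phase]
        ps.n_contigs, ps.mean_contig_len, _ = _summarize_lengths(
            [c.sequence for c in pa.contigs])
        ps.n_scaffolds, ps.mean_scaffold_len, _ = _summarize_lengths(
            [s.sequence for s in pa.scaffolds])
        (ps.n_unigenes, ps.mean_unigene_len,
         ps.total_unigene_len) = _summarize_lengths(
            [u.sequence for u in pa.unigenes])
        write_fasta([(c.id, c.sequence) for c in pa.contigs],
                    out / f"contigs_phase{phase}.fasta")
        write_fasta([(u.id, u.sequence) for u in pa.unigenes],
                    out / f"unigenes_phase{phase}.fasta")
    cs = asm.cluster_unigenes(unigenes, cfg.assembly)
    state["clusters"] = cs
    result.cluster_set = cs
    seqs = [cs.sequences[r] for r in cs.representatives]
    (result.report.n_distinct_unigenes, result.report.mean_distinct_len,
     result.report.total_distinct_len) = _summarize_lengths(seqs)
    write_fasta(sorted(cs.sequences.items()), out / "all_unigenes.fasta")


def _stage_quantify(cfg: PipelineConfig, state: dict, result: PipelineResult,
                    out: Path) -> None:
    clean = _require(state, "clean", "qc", "quantify")
    cs = _require(state, "clusters", "assemble", "quantify")
    reads1 = [r.bases for p in clean[1] for r in p]
    reads2 = [r.bases for p in clean[2] for r in p]
    table = qt.map_reads_unique((reads1, reads2), cs.sequences,
                                k=cfg.assembly.k)
    lengths = {uid: len(seq) for uid, seq in cs.sequences.items()}
    records = qt.call_differential(table, lengths, cfg.fold_min, cfg.fdr_max)
    state["abundance"] = records
    df = qt.abundance_frame(records)
    df.to_csv(out / "abundance.tsv", sep="\t", index=False)
    result.abundance = df
    rep = result.report
    rep.de_up1 = sum(1 for r in records if r.call == "UP1")
    rep.de_up2 = sum(1 for r in records if r.call == "UP2")
    rep.de_total = rep.de_up1 + rep.de_up2
    rep.de_unique_to_1 = sum(1 for r in records
                             if r.call == "UP1" and r.unique_to == "1")
    rep.de_unique_to_2 = sum(1 for r in records
                             if r.call == "UP2" and r.unique_to == "2")


def _stage_annotate(cfg: PipelineConfig, state: dict, result: PipelineResult,
                    out: Path) -> None:
    cs = _require(state, "clusters", "assemble", "annotate")
    ids = sorted(cs.sequences)
    hits = sim.simulate_hit_tables(ids, annotation_rate=cfg.annotation_rate,
                                   seed=cfg.seed)
    hit_records = []
    for db, frame in hits.items():
        path = out / f"hits_{db.lower()}.tsv"
        frame.to_csv(path, sep="\t", index=False, header=False)
        hit_records.extend(ann.read_hit_table(path, db))
    assignments = ann.select_annotations(hit_records, cs.sequences)
    lengths = {uid: len(seq) for uid, seq in cs.sequences.items()}
    ann_df = pd.DataFrame([a.__dict__ for a in assignments])
    ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
    bins = ann.length_binned_match_rate(lengths, assignments)
    bins.to_csv(out / "match_rate_by_length.tsv", sep="\t", index=False)
    classes = ann.homology_class_summary(assignments)
    classes.to_csv(out / "homology_classes.tsv", sep="\t", index=False)
    # toy ontology, GO term assignments and slim mapping for annotated ids
    fixture = sim.generate_ontology_fixture(cfg.n_terms,
                                            slim_fraction=cfg.slim_fraction,
                                            seed=cfg.seed)
    annotated = sorted({a.query for a in assignments if a.source == "hit"})
    fixture.assignments = sim.random_assignments(fixture, annotated,
                                                 seed=cfg.seed)
    sim.write_obo(fixture, out / "ontology.obo")
    sim.write_slim(fixture, out / "slim.txt")
    dag = ann.OntologyDAG.from_obo(out / "ontology.obo", out / "slim.txt")
    slim_map = ann.map_to_slim(fixture.assignments, dag)
    ann.write_assignments(slim_map, out / "go_slim_assignments.tsv")
    state["assignments"] = assignments
    state["go_terms"] = slim_map
    state["ko_terms"] = sim.random_ko_assignments(annotated, seed=cfg.seed)
    ann.write_assignments(state["ko_terms"], out / "ko_assignments.tsv")


def _stage_enrich(cfg: PipelineConfig, state: dict, result: PipelineResult,
                  out: Path) -> None:
    records = _require(state, "abundance", "quantify", "enrich")
    go_terms = _require(state, "go_terms", "annotate", "enrich")
    ko_terms = state.get("ko_terms", {})
    de_sets = {
        "up1": {r.unigene_id for r in records if r.call == "UP1"},
        "up2": {r.unigene_id for r in records if r.call == "UP2"},
    }
    all_results = []
    for scope, terms in (("GO", go_terms), ("KO", ko_terms)):
        res = enr.run_enrichment(de_sets, terms, alpha=cfg.alpha)
        for r in res:
            all_results.append({"scope": scope, **r.__dict__})
    result.enrichment = all_results
    pd.DataFrame(all_results).to_csv(out / "enrichment.tsv", sep="\t",
                                     index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assemble": _stage_assemble,
    "quantify": _stage_quantify,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
}
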