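"""Whole-read quality filtering for paired-end libraries.

Three rules are applied to each read, in a fixed order, and the first
failing rule is the reported removal reason:

1. *Chastity* — the instrument's base-call purity criterion.  Raw
   intensities are not present in FASTQ, so the CASAVA pass-filter flag in
   the read header stands in for it; the purity threshold (0.6 over the
   first 25 cycles) is kept in the config for documentation.
2. *Adaptor / ambiguity* — reads showing adaptor contamination (ungapped
   match of an adaptor against the read with a small mismatch allowance)
   or any ambiguous base call (``N``) are removed whole.
3. *Low quality* — reads in which strictly more than ``max_lowq_fraction``
   (default 10%) of bases have Phred quality below ``q_cutoff`` (default
   20) are removed.

Reads are never trimmed: the unit of removal is the whole read, and —
because downstream scaffolding needs intact pairs — the whole pair is
dropped if either mate fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from florasm.io import ReadRecord, read_fastq_pairs, write_fastq
from florasm.simulate import DEFAULT_ADAPTOR

KEEP = "KEEP"
CHASTITY = "CHASTITY"
ADAPTOR = "ADAPTOR"
AMBIGUOUS = "AMBIGUOUS"
LOWQ = "LOWQ"

# Removal reasons in rule order; a failing pair is attributed to the
# highest-priority reason among its two mates.
_REASON_ORDER = (CHASTITY, ADAPTOR, AMBIGUOUS, LOWQ)


@dataclass
class QCConfig:
    chastity_threshold: float = 0.6   # documented; acted on via pass-filter flag
    chastity_cycles: int = 25
    adaptor_seqs: tuple[str, ...] = (DEFAULT_ADAPTOR,)
    adaptor_max_mismatch: int = 2
    adaptor_min_overlap: int = 10
    q_cutoff: int = 20
    max_lowq_fraction: float = 0.10
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_lowq_fraction <= 1.0:
            raise ValueError("max_lowq_fraction must be in [0, 1]")
        if not 0 <= self.q_cutoff <= 60:
            raise ValueError("q_cutoff must be a Phred value in [0, 60]")


@dataclass
class QCReport:
    input_pairs: int = 0
    removed_chastity: int = 0
    removed_adaptor: int = 0
    removed_ambiguous: int = 0
    removed_lowq: int = 0
    surviving_pairs: int = 0

    @property
    def removed_total(self) -> int:
        return (self.removed_chastity + self.removed_adaptor
                + self.removed_ambiguous + self.removed_lowq)

    def check(self) -> None:
        if self.input_pairs != self.surviving_pairs + self.removed_total:
            raise AssertionError(
                f"QC accounting violated: {self.input_pairs} input != "
                f"{self.surviving_pairs} kept + {self.removed_total} removed"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tpairs\n")
            for name in ("input_pairs", "removed_chastity", "removed_adaptor",
                         "removed_ambiguous", "removed_lowq", "surviving_pairs"):
                fh.write(f"{name}\t{getattr(self, name)}\n")


def _has_adaptor(bases: str, adaptor: str, max_mismatch: int,
                 min_overlap: int) -> bool:
    """Ungapped scan: full adaptor inside the read, or an adaptor prefix of
    length >= min_overlap hanging off the read's 3' end."""
    L, A = len(bases), len(adaptor)
    # offset: adaptor start within read; positive offsets allow the adaptor
    # to run off the 3' end (read-through)
    for off in range(0, L - min_overlap + 1):
        n = min(A, L - off)
        mism = 0
        for i in range(n):
            if bases[off + i] != adaptor[i]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return True
    return False


def filter_read(read: ReadRecord, cfg: QCConfig) -> str:
    """Classify one read as KEEP or the first failing rule's reason."""
    if len(read.bases) != len(read.quals):
        raise ValueError(f"read {read.id!r}: bases/qualities length mismatch")
    if not read.passfilter:
        return CHASTITY
    for adaptor in cfg.adaptor_seqs:
        if _has_adaptor(read.bases, adaptor, cfg.adaptor_max_mismatch,
                        cfg.adaptor_min_overlap):
            return ADAPTOR
    if "N" in read.bases:
        return AMBIGUOUS
    n_low = sum(1 for q in read.quals if q < cfg.q_cutoff)
    # "more than 10%" is a strict inequality: exactly 10% is kept
    if n_low > cfg.max_lowq_fraction * len(read.quals):
        return LOWQ
    return KEEP


def filter_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], cfg: Optional[QCConfig] = None
) -> tuple[list[tuple[ReadRecord, ReadRecord]], QCReport]:
    """Filter an in-memory pair stream; pair-level removal with exact
    accounting."""
    cfg = cfg or QCConfig()
    report = QCReport()
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    for r1, r2 in pairs:
        report.input_pairs += 1
        v1, v2 = filter_read(r1, cfg), filter_read(r2, cfg)
        if v1 == KEEP and v2 == KEEP:
            kept.append((r1, r2))
            report.surviving_pairs += 1
            continue
        reasons = {v for v in (v1, v2) if v != KEEP}
        reason = next(r for r in _REASON_ORDER if r in reasons)
        attr = {CHASTITY: "removed_chastity", ADAPTOR: "removed_adaptor",
                AMBIGUOUS: "removed_ambiguous", LOWQ: "removed_lowq"}[reason]
        setattr(report, attr, getattr(report, attr) + 1)
    report.check()
    return kept, report


def run_qc(
    fastq_in1: str | Path,
    fastq_in2: str | Path,
    fastq_out1: str | Path,
    fastq_out2: str | Path,
    cfg: Optional[QCConfig] = None,
) -> QCReport:
    """File-to-file QC over synchronized mate FASTQs."""
    cfg = cfg or QCConfig()
    pairs = read_fastq_pairs(fastq_in1, fastq_in2, cfg.phred_offset)
    kept, report = filter_pairs(pairs, cfg)
    write_fastq((r1 for r1, _ in kept), fastq_out1, cfg.phred_offset)
    write_fastq((r2 for _, r2 in kept), fastq_out2, cfg.phred_offset)
    return report
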