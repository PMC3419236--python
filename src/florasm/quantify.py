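"""Digital transcript-abundance analysis.

Reads from each phase are mapped back to the distinct unigene set
(exact full-length matches, both strands); only reads matching exactly one
unigene are counted.  Per-unigene expression is summarized as RPKM
(reads per kilobase of transcript per million mapped reads,
``10^9 * C / (N * L)``), fold changes are phase-2 over phase-1 RPKM with a
0.001 substitution for zeros, and significance comes from an exact
conditional test on the count pair.

The test: given ``x`` reads for a unigene in library 1 (total mapped
``N1``) and ``y`` in library 2 (total ``N2``), under equal underlying
abundance the conditional law of ``y`` given ``x`` is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

— a negative binomial in ``y``.  The reported p-value is the two-sided
tail ``min(1, 2*min(P(Y<=y|x), P(Y>=y|x)))``.  To make the statistic
invariant under exchanging the two libraries (the discrete conditional
tails are not symmetric on their own), the test always conditions on the
smaller of the two counts.  Tails are evaluated in log space via
log-gamma, so counts up to 10^6 are handled stably.

Unigenes with |fold change| >= 2 and FDR <= 0.001 (Benjamini-Hochberg)
are called differentially abundant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from florasm.assemble import ExactMapper
from florasm.io import ReadRecord

RPKM_ZERO_SUBSTITUTE = 0.001


@dataclass
class CountTable:
    counts: dict[str, tuple[int, int]]  # unigene -> (x, y)
    n1: int
    n2: int
    multimapped: tuple[int, int] = (0, 0)
    unmapped: tuple[int, int] = (0, 0)


@dataclass
class AbundanceRecord:
    unigene_id: str
    x: int
    y: int
    length: int
    rpkm1: float
    rpkm2: float
    fold: float
    log2fold: float
    p: float
    fdr: float
    call: str        # UP1 / UP2 / NS
    unique_to: str   # "1" / "2" / "none"


def map_reads_unique(
    reads_by_phase: tuple[Iterable[ReadRecord | str], Iterable[ReadRecord | str]],
    unigene_seqs: dict[str, str],
    k: int = 25,
) -> CountTable:
    """Count uniquely mapped reads per unigene for both phases.

    A read counts for a unigene iff it matches exactly that one unigene
    (any position, either strand); reads matching several unigenes go to
    the multimap tally.  Library totals N1/N2 are the sums of unique
    counts.
    """
    if not unigene_seqs:
        raise ValueError("empty unigene index")
    mapper = ExactMapper(unigene_seqs, k)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    multi = [0, 0]
    unmapped = [0, 0]
    for phase_idx, reads in enumerate(reads_by_phase):
        for read in reads:
            bases = read if isinstance(read, str) else read.bases
            hits = mapper.map_read(bases)
            uids = {h[0] for h in hits}
            if len(uids) == 1:
                counts[next(iter(uids))][phase_idx] += 1
            elif len(uids) > 1:
                multi[phase_idx] += 1
            else:
                unmapped[phase_idx] += 1
    table = {uid: (c[0], c[1]) for uid, c in counts.items()}
    for uid in unigene_seqs:
        table.setdefault(uid, (0, 0))
    n1 = sum(x for x, _ in table.values())
    n2 = sum(y for _, y in table.values())
    return CountTable(table, n1, n2, tuple(multi), tuple(unmapped))


def rpkm(c: int, n: int, length: int) -> float:
    """Reads per kilobase per million mapped reads: 10^9 * c / (n * l)."""
    if n <= 0 or length <= 0:
        raise ValueError("library total and length must be positive")
    return 1e9 * c / (n * length)


def fold_change(rpkm1: float, rpkm2: float) -> tuple[float, float]:
    """Phase-2 over phase-1 RPKM ratio with the 0.001 zero substitution."""
    a = rpkm1 if rpkm1 > 0 else RPKM_ZERO_SUBSTITUTE
    b = rpkm2 if rpkm2 > 0 else RPKM_ZERO_SUBSTITUTE
    fold = b / a
    return fold, float(np.log2(fold))


def _log_pmf(y: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(y | x) for the conditional distribution with r = n2/n1."""
    return (y * log_r + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * np.logaddexp(0.0, log_r))


def _tails(x: int, y: int, r: float) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) evaluated by log-space summation."""
    log_r = float(np.log(r))
    lo = np.arange(0, y + 1)
    log_lower = logsumexp(_log_pmf(lo, x, log_r))
    p_lower = float(np.exp(min(log_lower, 0.0)))
    # upper tail: sum from y out past the mode until terms are negligible
    mean = (x + 1) * r
    sd = np.sqrt((x + 1) * r * (1 + r))
    hi_end = int(max(y, mean) + 12 * sd + 100)
    hi = np.arange(y, hi_end + 1)
    log_upper = logsumexp(_log_pmf(hi, x, log_r))
    p_upper = float(np.exp(min(log_upper, 0.0)))
    return min(p_lower, 1.0), min(p_upper, 1.0)


def digital_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p-value for the exact conditional count test.

    Symmetrized by conditioning on the smaller count, so
    ``digital_p(x, y, n1, n2) == digital_p(y, x, n2, n1)``.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    p_lower, p_upper = _tails(x, y, n2 / n1)
    return min(1.0, 2.0 * min(p_lower, p_upper))


def digital_p_one_sided(x: int, y: int, n1: int, n2: int,
                        alternative: str = "greater") -> float:
    """One-sided tail P(Y >= y | x) (``greater``) or P(Y <= y | x)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    p_lower, p_upper = _tails(x, y, n2 / n1)
    return p_upper if alternative == "greater" else p_lower


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_call(fold: float, fdr: float, fold_min: float = 2.0,
            fdr_max: float = 0.001) -> str:
    """DE decision with inclusive thresholds: fold >= fold_min (or
    <= 1/fold_min) AND fdr <= fdr_max."""
    if fdr <= fdr_max and fold >= fold_min:
        return "UP2"
    if fdr <= fdr_max and fold <= 1.0 / fold_min:
        return "UP1"
    return "NS"


def call_differential(
    table: CountTable,
    lengths: dict[str, int],
    fold_min: float = 2.0,
    fdr_max: float = 0.001,
) -> list[AbundanceRecord]:
    """Full abundance record per unigene with inclusive-threshold DE calls.

    UP2: fold >= fold_min and FDR <= fdr_max; UP1: fold <= 1/fold_min and
    FDR <= fdr_max; otherwise NS.  ``unique_to`` marks unigenes with all
    their unique reads in a single phase.
    """
    uids = sorted(table.counts)
    n1 = max(table.n1, 1)
    n2 = max(table.n2, 1)
    pvals = [digital_p(*table.counts[u], n1, n2) for u in uids]
    fdrs = bh_fdr(pvals)
    records = []
    for uid, p, q in zip(uids, pvals, fdrs):
        x, y = table.counts[uid]
        r1 = rpkm(x, n1, lengths[uid])
        r2 = rpkm(y, n2, lengths[uid])
        fold, l2 = fold_change(r1, r2)
        call = de_call(fold, float(q), fold_min, fdr_max)
        unique_to = "1" if (y == 0 and x > 0) else "2" if (x == 0 and y > 0) else "none"
        records.append(AbundanceRecord(uid, x, y, lengths[uid], r1, r2, fold,
                                       l2, p, float(q), call, unique_to))
    return records


def abundance_frame(records: Sequence[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
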