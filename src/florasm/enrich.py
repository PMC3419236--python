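"""Hypergeometric term enrichment over differentially abundant unigenes.

For each term the contingency is: ``N`` annotated unigenes in total, of
which ``n`` are differentially abundant; ``M`` unigenes carry the term, of
which ``m`` are differentially abundant.  The raw p-value is the
over-representation (right) tail

    p = 1 - sum_{i=0}^{m-1} C(M, i) * C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n),

adjusted by a Bonferroni correction; a corrected p strictly below 0.05 is
called significant.  By default the Bonferroni divisor is the number of
tests performed within one ontology scope and one DE direction; a global
divisor can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentInput:
    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        ok = (0 <= self.m <= min(self.n, self.M)
              and self.n <= self.N and self.M <= self.N and self.N >= 0)
        if not ok:
            raise ValueError(
                f"invalid contingency N={self.N}, n={self.n}, M={self.M}, "
                f"m={self.m}")


@dataclass
class EnrichmentResult:
    term: str
    direction: str  # 'up1' or 'up2'
    N: int
    n: int
    M: int
    m: int
    p_raw: float
    p_bonf: float
    significant: bool


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Right-tail P(X >= m) for X ~ Hypergeometric(N, M, n)."""
    if inp.m == 0:
        return 1.0
    return float(hypergeom.sf(inp.m - 1, inp.N, inp.M, inp.n))


def run_enrichment(
    de_sets: Mapping[str, set[str]],
    assignments: Mapping[str, set[str]],
    alpha: float = 0.05,
    global_divisor: bool = False,
) -> list[EnrichmentResult]:
    """Test every (term, direction) with at least one DE member.

    ``de_sets`` maps direction labels (e.g. 'up1', 'up2') to sets of
    unigene ids; ``assignments`` maps annotated unigene ids to their term
    sets (already restricted to one ontology scope, GO or KO).
    """
    annotated = {u for u, ts in assignments.items() if ts}
    N = len(annotated)
    members: dict[str, set[str]] = {}
    for uid in annotated:
        for t in assignments[uid]:
            members.setdefault(t, set()).add(uid)

    results: list[EnrichmentResult] = []
    per_direction: dict[str, list[EnrichmentResult]] = {}
    for direction in sorted(de_sets):
        de = de_sets[direction] & annotated
        if not de:
            logger.warning("no annotated DE unigenes for direction %s", direction)
            per_direction[direction] = []
            continue
        n = len(de)
        rows = []
        for term in sorted(members):
            M = len(members[term])
            m = len(members[term] & de)
            if m == 0:
                continue
            p = hypergeom_p(EnrichmentInput(N, n, M, m))
            rows.append(EnrichmentResult(term, direction, N, n, M, m, p, 1.0,
                                         False))
        per_direction[direction] = rows

    total_tests = sum(len(rows) for rows in per_direction.values())
    for direction, rows in per_direction.items():
        divisor = total_tests if global_divisor else len(rows)
        for r in rows:
            r.p_bonf = min(1.0, r.p_raw * divisor)
            r.significant = r.p_bonf < alpha
        results.extend(sorted(rows, key=lambda r: (r.p_bonf, r.term)))
    return results
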