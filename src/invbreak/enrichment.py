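"""Duplicate-gene adjacency detection and breakpoint-association tests.

The question: do inversion breakpoints fall between tandemly duplicated
genes (or next to transposed genes) more often than random breakage would
predict?  Adjacent gene pairs are called duplicates when their proteins
align with identity above 33%, hit length above 57% of the shorter query
and an e-value-equivalent score cutoff (1e-30 scale).  Proportions are then
compared with 2x2 contingency statistics implemented from their formulas:
Pearson's chi-square with and without the Yates continuity correction,
the two-sided Fisher exact test (minimum-likelihood convention: the sum of
hypergeometric point probabilities no larger than the observed table's),
and a pooled-variance two-sample t-test for intergenic distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, exp, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .alignment import protein_align, protein_score_threshold
from .config import ConfigDefaults

__all__ = [
    "ProteinRecord",
    "DuplicatePair",
    "ContingencyTable",
    "TestResult",
    "align_protein_pair",
    "find_duplicate_adjacencies",
    "chi2_2x2",
    "fisher_exact_2x2",
    "two_sample_t",
    "enrichment_report",
]


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    rank: int  # position order along the chromosome, 1-based dense
    sequence: str


@dataclass(frozen=True)
class DuplicatePair:
    gene_id_a: str
    gene_id_b: str
    pct_identity: float
    hit_length: int
    shorter_query_length: int
    score: float


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = focal vs comparison group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def align_protein_pair(seq_a: str, seq_b: str) -> tuple[float, int, float]:
    """Best local protein alignment: (identity %, hit length, raw score)."""
    return protein_align(seq_a, seq_b)


def find_duplicate_adjacencies(
    proteins: Sequence[ProteinRecord],
    cfg: Optional[ConfigDefaults] = None,
) -> tuple[set[int], list[DuplicatePair]]:
    """Intergenic regions flanked by duplicated genes.

    Proteins must be ordered by chromosome rank; the k-th intergenic region
    (1-based) separates ranks k and k+1, so ``len(proteins) - 1`` regions
    exist.  Returns the set of duplicate-flanked region indices and the
    accepted pairs.
    """
    cfg = cfg or ConfigDefaults()
    ordered = sorted(proteins, key=lambda p: p.rank)
    ranks = [p.rank for p in ordered]
    if len(set(ranks)) != len(ranks):
        raise ValueError("duplicate chromosome ranks")
    flagged: set[int] = set()
    pairs: list[DuplicatePair] = []
    for k, (p1, p2) in enumerate(zip(ordered, ordered[1:]), start=1):
        identity, hit_len, score = protein_align(p1.sequence, p2.sequence)
        shorter = min(len(p1.sequence), len(p2.sequence))
        threshold = protein_score_threshold(
            cfg.dup_evalue, len(p1.sequence), len(p2.sequence)
        )
        if (
            identity > cfg.dup_identity
            and hit_len > cfg.dup_coverage * shorter
            and score >= threshold
        ):
            flagged.add(k)
            pairs.append(
                DuplicatePair(
                    gene_id_a=p1.gene_id,
                    gene_id_b=p2.gene_id,
                    pct_identity=identity,
                    hit_length=hit_len,
                    shorter_query_length=shorter,
                    score=score,
                )
            )
    return flagged, pairs


def chi2_2x2(t: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 table, optional Yates correction.

    statistic = N (|ad - bc| - correction)^2 / ((a+b)(c+d)(a+c)(b+d)),
    correction = N/2 with Yates (clamped at zero), p from chi2(1 df).
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin; chi-square undefined")
    n = t.n
    det = abs(t.a * t.d - t.b * t.c)
    corr = n / 2.0 if yates else 0.0
    num = max(det - corr, 0.0)
    statistic = n * num * num / (r1 * r2 * c1 * c2)
    p = float(_stats.chi2.sf(statistic, 1))
    return TestResult(
        statistic=float(statistic),
        p_value=p,
        method="chi2_yates" if yates else "chi2",
    )


def _log_hyp_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(table with top-left a | margins r1, r2, c1)."""
    n = r1 + r2

    def lc(n_, k_):
        return lgamma(n_ + 1) - lgamma(k_ + 1) - lgamma(n_ - k_ + 1)

    return lc(r1, a) + lc(r2, c1 - a) - lc(n, c1)


def fisher_exact_2x2(t: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    With margins fixed, enumerates every admissible table and sums the
    point probabilities no larger than the observed one (the
    minimum-likelihood two-sided convention).  The statistic reported is
    the sample odds ratio (with the usual convention for zero cells).
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin; Fisher test undefined")
    if t.n > 2_000_000:
        raise ValueError("counts too large for exact enumeration; use chi-square")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = _log_hyp_pmf(t.a, r1, r2, c1)
    p = 0.0
    eps = 1e-7  # tolerate roundoff when comparing point probabilities
    for a in range(lo, hi + 1):
        lp = _log_hyp_pmf(a, r1, r2, c1)
        if lp <= log_obs + eps:
            p += exp(lp)
    if t.b * t.c == 0:
        odds = float("inf") if t.a * t.d > 0 else float("nan")
    else:
        odds = (t.a * t.d) / (t.b * t.c)
    return TestResult(statistic=float(odds), p_value=min(p, 1.0), method="fisher")


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample t-test, Student pooled-variance by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="t")
        raise ValueError("zero variance in both groups with unequal means")
    if welch:
        se = sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2
    tstat = (x.mean() - y.mean()) / se
    p = 2.0 * float(_stats.t.sf(abs(tstat), df))
    return TestResult(statistic=float(tstat), p_value=p, method="t")


def _build_table(
    hits_focal: int, n_focal: int, hits_all: int, n_all: int, exclusive: bool
) -> ContingencyTable:
    if exclusive:
        return ContingencyTable(
            hits_focal,
            n_focal - hits_focal,
            hits_all - hits_focal,
            (n_all - n_focal) - (hits_all - hits_focal),
        )
    return ContingencyTable(
        hits_focal, n_focal - hits_focal, hits_all, n_all - hits_all
    )


def enrichment_report(
    breakpoint_dup_hits: int,
    n_breakpoint_regions: int,
    chromosome_dup_regions: int,
    n_chromosome_regions: int,
    transposed_breakpoint_genes: int = 0,
    n_breakpoint_genes: int = 0,
    chromosome_transposed_genes: int = 0,
    n_chromosome_genes: int = 0,
    exclusive: bool = False,
) -> dict:
    """Contingency tables and tests for both breakpoint associations.

    Builds the duplication table (breakpoint intervals between duplicated
    genes vs chromosome-wide intervals) and, when gene counts are given,
    the transposition table (breakpoint-adjacent transposed genes vs
    chromosome-wide), then runs chi-square with and without Yates
    correction and the Fisher exact test on each.  By default the
    chromosome-wide comparison group includes the breakpoint intervals;
    ``exclusive=True`` removes them.
    """
    if breakpoint_dup_hits > n_breakpoint_regions:
        raise ValueError("more duplicate-flanked breakpoint intervals than intervals")
    if chromosome_dup_regions > n_chromosome_regions:
        raise ValueError("inconsistent chromosome totals")
    out: dict = {}
    dup_table = _build_table(
        breakpoint_dup_hits,
        n_breakpoint_regions,
        chromosome_dup_regions,
        n_chromosome_regions,
        exclusive,
    )
    entry = {
        "table": dup_table,
        "chi2": chi2_2x2(dup_table, yates=False),
        "chi2_yates": chi2_2x2(dup_table, yates=True),
        "fisher": fisher_exact_2x2(dup_table),
    }
    if breakpoint_dup_hits == 0:
        entry["note"] = "no breakpoint intervals between duplicates; no enrichment"
    out["duplication"] = entry
    if n_breakpoint_genes and n_chromosome_genes:
        tr_table = _build_table(
            transposed_breakpoint_genes,
            n_breakpoint_genes,
            chromosome_transposed_genes,
            n_chromosome_genes,
            exclusive,
        )
        out["transposition"] = {
            "table": tr_table,
            "chi2": chi2_2x2(tr_table, yates=False),
            "chi2_yates": chi2_2x2(tr_table, yates=True),
            "fisher": fisher_exact_2x2(tr_table),
        }
    return out
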