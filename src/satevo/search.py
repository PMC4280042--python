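"""Iterative homology capture with E-value and length filters.

Implements a BLAST-like search as repeated optimal Smith–Waterman local
alignment: per query/subject pair the best hit is reported, the subject is
split at the hit, and the flanks are searched again, yielding all
non-overlapping local alignments above the significance threshold (the
natural behaviour on tandem arrays, where one query matches many monomers).

Significance uses the Karlin–Altschul ungapped theory applied to the gapped
scores, as classic BLAST did for its default levels: E = K·m·n·exp(−λS)
with λ solved numerically from the scoring scheme and the background base
composition, and K fixed at 0.1.  Hits failing the hard filters
(E > evalue_max or span < min_length) are excluded; weaker hits that pass
them but have E > inspect_evalue and span < inspect_length are kept with a
machine-readable review flag rather than silently dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .align import (
    PairwiseAlignment,
    ScoringScheme,
    local_align,
    reverse_complement,
)

KARLIN_K = 0.1  # fixed prefactor; λ carries the scheme dependence


@dataclass
class Hit:
    """A local-alignment match of a query against a subject.

    Coordinates are 0-based half-open on the + strand of the subject.
    ``matched_sequence`` is the subject segment in the query's orientation
    (reverse-complemented for '−'-strand hits) so it can be fed back as a
    query.  ``review`` marks weak hits a human would have inspected.
    """

    query_id: str
    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    score: int
    evalue: float
    length: int
    matched_sequence: str
    query_start: int = 0
    query_end: int = 0
    identity: float = 0.0
    review: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.subject_start < self.subject_end):
            raise ValueError("invalid subject coordinates")
        if self.length != self.subject_end - self.subject_start:
            raise ValueError("length must equal subject_end - subject_start")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


@dataclass
class SearchConfig:
    """Filters and scoring for homology search.

    Defaults reproduce the capture thresholds used throughout the package:
    hard exclusion at E > 0.1 or span < 30 bp, review flag at E > 0.001
    and span < 50 bp.
    """

    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    evalue_max: float = 0.1
    min_length: int = 30
    inspect_evalue: float = 1e-3
    inspect_length: int = 50
    max_iterations: int = 20
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def karlin_lambda(scheme: ScoringScheme, background=(0.25, 0.25, 0.25, 0.25)) -> float:
    """Solve sum_ij p_i p_j exp(λ s_ij) = 1 for λ > 0.

    Requires a negative expected score with a positive match score; raises
    a configuration error otherwise.
    """
    p = np.asarray(background, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("background must be a probability vector over ACGT")
    sub = scheme.matrix()[:4, :4].astype(float)
    expected = float(p @ sub @ p)
    if expected >= 0:
        raise ValueError("expected score must be negative for λ to exist")

    def f(lam: float) -> float:
        return float(np.sum(np.outer(p, p) * np.exp(lam * sub))) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover
            raise ValueError("λ not bracketed; degenerate scoring scheme")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


def evalue(score: int, m: int, n: int, lam: float, k: float = KARLIN_K) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    return k * m * n * math.exp(-lam * score)


def min_significant_score(m: int, n: int, lam: float, evalue_max: float) -> int:
    """Smallest integer score whose E-value is <= evalue_max."""
    return math.ceil(math.log(KARLIN_K * m * n / evalue_max) / lam)


def _search_one_strand(query, qid, subject, sid, strand, cfg, lam, tally):
    """All non-overlapping significant local hits of query on one strand.

    ``subject`` is given in the orientation searched; coordinates are
    mapped back to the + strand for '−' hits.
    """
    m, n = len(query), len(subject)
    hits: list[Hit] = []
    stack = [(0, len(subject))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        aln = local_align(query, subject[lo:hi], cfg.scoring)
        if aln.score <= 0:
            continue
        ev = evalue(aln.score, m, n, lam)
        if ev > cfg.evalue_max:
            if tally is not None:
                tally["excluded_evalue"] = tally.get("excluded_evalue", 0) + 1
            continue
        s_start, s_end = lo + aln.b_start, lo + aln.b_end
        length = s_end - s_start
        # recurse into the flanks regardless of the length filter
        stack.append((lo, s_start))
        stack.append((s_end, hi))
        if length < cfg.min_length:
            if tally is not None:
                tally["excluded_length"] = tally.get("excluded_length", 0) + 1
            continue
        if strand == "+":
            p_start, p_end = s_start, s_end
            matched = subject[s_start:s_end]
        else:
            p_start, p_end = n - s_end, n - s_start
            matched = subject[s_start:s_end]  # already query-oriented
        review = ev > cfg.inspect_evalue and length < cfg.inspect_length
        if review and tally is not None:
            tally["review_flagged"] = tally.get("review_flagged", 0) + 1
        ident = _aln_identity(aln)
        hits.append(
            Hit(qid, sid, p_start, p_end, strand, aln.score, ev, length, matched,
                aln.a_start, aln.a_end, ident, review)
        )
    return hits


def _aln_identity(aln: PairwiseAlignment) -> float:
    ident = sum(1 for ca, cb in aln.columns if ca == cb and ca != "-" and ca != "N")
    return 100.0 * ident / len(aln) if len(aln) else 0.0


def search_db(
    queries: dict[str, str],
    subjects: dict[str, str],
    cfg: SearchConfig | None = None,
    tally: dict | None = None,
) -> list[Hit]:
    """Search every query against both strands of every subject.

    Returns hits passing the E-value and length filters, sorted by
    descending score (ties broken by query, subject, coordinates).  When a
    ``tally`` dict is supplied, exclusion and review-flag counts are
    accumulated into it.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    cfg = cfg or SearchConfig()
    lam = karlin_lambda(cfg.scoring, cfg.background)
    hits: list[Hit] = []
    for qid, q in queries.items():
        for sid, s in subjects.items():
            hits.extend(_search_one_strand(q, qid, s, sid, "+", cfg, lam, tally))
            hits.extend(
                _search_one_strand(q, qid, reverse_complement(s), sid, "-", cfg, lam, tally)
            )
    hits.sort(key=lambda h: (-h.score, h.query_id, h.subject_id, h.subject_start, h.strand))
    return hits


def deduplicate(seqs: list[str] | set[str]) -> list[str]:
    """Remove exact duplicates and exact substrings, strand-aware.

    A sequence equal to (or contained in) another retained sequence or its
    reverse complement is redundant.  Retention is deterministic: longest
    first, then lexicographic.  Returns the retained sequences in that
    order.
    """
    ordered = sorted(set(seqs), key=lambda s: (-len(s), s))
    kept: list[str] = []
    for s in ordered:
        rc = reverse_complement(s)
        if any(s in k or rc in k for k in kept):
            continue
        kept.append(s)
    return kept


@dataclass
class IterationTrace:
    """Per-round capture counts plus a convergence flag."""

    rounds: list[dict]
    converged: bool

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def iterative_capture(
    seed_queries: dict[str, str],
    subjects: dict[str, str],
    cfg: SearchConfig | None = None,
    tally: dict | None = None,
) -> tuple[list[str], IterationTrace]:
    """Fixed-point homology capture.

    Round ``r`` queries the subjects with the seeds plus all deduplicated
    sequences captured in earlier rounds; iteration stops when a round adds
    no new non-redundant sequence, or when ``max_iterations`` is reached
    (recorded as non-convergence; the partial result is returned).
    """
    cfg = cfg or SearchConfig()
    captured: list[str] = []
    queries = dict(seed_queries)
    rounds = []
    converged = False
    for r in range(cfg.max_iterations):
        hits = search_db(queries, subjects, cfg, tally)
        pool = set(captured) | {h.matched_sequence for h in hits}
        new_captured = deduplicate(pool)
        n_new = len(set(new_captured) - set(captured))
        rounds.append({"round": r + 1, "hits": len(hits), "captured": len(new_captured),
                       "new": n_new})
        if set(new_captured) == set(captured):
            converged = True
            break
        captured = new_captured
        queries = dict(seed_queries)
        for i, s in enumerate(captured):
            queries[f"captured_{i}"] = s
    return captured, IterationTrace(rounds, converged)
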