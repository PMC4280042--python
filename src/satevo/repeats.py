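"""Repeat-unit extraction, merging, consensus building and classification.

A *unit* (monomer) is one copy of the repeated sequence (~120 bp for the
canonical satellite).  Contigs are tiled into units by maximal
non-overlapping local alignment against a consensus; fragmented length
variants of the same underlying repeat are merged; per-species unique
repeats are counted; and units are classified against the Left/Right
canonical consensuses into canonical / variant / family-divergent bands.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ScoringScheme, global_align, pairwise_identity, reverse_complement
from .search import Hit, SearchConfig, _search_one_strand, karlin_lambda

# classification bands (percent identity to the nearer canonical consensus)
CANONICAL_MIN = 90.0
VARIANT_MIN = 79.5
FAMILY_MIN = 55.0

# a unit shorter than this fraction of the consensus is flagged partial
PARTIAL_FRACTION = 0.9


@dataclass
class RepeatUnit:
    """One repeat monomer with provenance and classification.

    ``start``/``end`` are 0-based half-open on the + strand of the source;
    minus-strand units store the consensus-oriented sequence with original
    + strand coordinates retained.
    """

    unit_id: str
    sequence: str
    source_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    species: str = ""
    locus_label: str = ""
    type_label: str = "unknown"
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")


@dataclass
class RepeatArray:
    """Ordered, non-overlapping units on one source molecule."""

    source_id: str
    units: list[RepeatUnit]
    locus_label: str = ""

    def __post_init__(self) -> None:
        self.units = sorted(self.units, key=lambda u: u.start)
        for u, v in zip(self.units, self.units[1:]):
            if v.start < u.end:
                raise ValueError("units overlap on the source molecule")

    def __len__(self) -> int:
        return len(self.units)

    def sequences(self) -> list[str]:
        return [u.sequence for u in self.units]

    @property
    def sequence(self) -> str:
        """Concatenated array sequence (units assumed contiguous)."""
        return "".join(u.sequence for u in self.units)


def extract_units(
    contig: str,
    consensus: str,
    cfg: SearchConfig | None = None,
    source_id: str = "contig",
    species: str = "",
    locus_label: str = "",
) -> list[RepeatUnit]:
    """Tile a contig with maximal non-overlapping consensus matches.

    Both strands are searched; units are reported in contig order, strand-
    normalized to the consensus orientation, and flagged ``partial`` when
    shorter than 90 % of the consensus (truncated copies at contig ends or
    genuine fragments).  A contig without similarity yields an empty list.
    """
    if len(consensus) < 30:
        raise ValueError("consensus must be at least 30 bp")
    cfg = cfg or SearchConfig()
    lam = karlin_lambda(cfg.scoring, cfg.background)
    fwd = _search_one_strand(consensus, "consensus", contig, source_id, "+", cfg, lam, None)
    rev = _search_one_strand(
        consensus, "consensus", reverse_complement(contig), source_id, "-", cfg, lam, None
    )
    # resolve strand conflicts greedily by score, keeping non-overlapping spans
    chosen: list[Hit] = []
    for h in sorted(fwd + rev, key=lambda h: (-h.score, h.subject_start, h.strand)):
        if all(h.subject_end <= c.subject_start or h.subject_start >= c.subject_end
               for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.subject_start)
    units = []
    for i, h in enumerate(chosen):
        seq = contig[h.subject_start:h.subject_end]
        if h.strand == "-":
            seq = reverse_complement(seq)
        units.append(
            RepeatUnit(
                unit_id=f"{source_id}.{i}",
                sequence=seq,
                source_id=source_id,
                start=h.subject_start,
                end=h.subject_end,
                strand=h.strand,
                species=species,
                locus_label=locus_label,
                partial=h.length < PARTIAL_FRACTION * len(consensus),
            )
        )
    return units


def _exact_overlap(x: str, y: str) -> tuple[int, str] | None:
    """Longest exact overlap between x and y.

    Returns (union_length_saving, merged) for the best arrangement, or
    ``None`` when no exact overlap exists.  Containment counts as full
    overlap of the shorter member.
    """
    if y in x:
        return len(y), x
    if x in y:
        return len(x), y
    best = None
    max_l = min(len(x), len(y)) - 1
    for l in range(max_l, 0, -1):
        if x[-l:] == y[:l]:
            best = (l, x + y[l:])
            break
    for l in range(max_l, 0, -1):
        if y[-l:] == x[:l]:
            if best is None or l > best[0]:
                best = (l, y + x[l:])
            break
    return best


def merge_pair(x: str, y: str, overhang_denominator: str = "union") -> str | None:
    """Merge two fragments sharing an exact overlap, if the rule allows.

    Fragments with identical overlapping sequence are merged when each
    member's overhang (non-overlapping tail) is < 50 % of the total
    fragment length.  ``overhang_denominator`` selects the referent of
    "total fragment length": the merged ``union`` (default) or each
    ``member``'s own length.  The overlap must additionally cover at least
    half of the shorter fragment — the two pieces must genuinely be length
    variants of the same repeat, not unrelated sequences sharing a few
    coincidental terminal bases.
    """
    ov = _exact_overlap(x, y)
    if ov is None:
        return None
    l, merged = ov
    if l < 0.5 * min(len(x), len(y)):
        return None
    oh_x, oh_y = len(x) - l, len(y) - l
    if overhang_denominator == "union":
        denom_x = denom_y = len(merged)
    elif overhang_denominator == "member":
        denom_x, denom_y = len(x), len(y)
    else:
        raise ValueError("overhang_denominator must be 'union' or 'member'")
    if oh_x < 0.5 * denom_x and oh_y < 0.5 * denom_y:
        return merged
    return None


def merge_length_variants(
    units: list[RepeatUnit] | list[str], overhang_denominator: str = "union"
) -> list[str]:
    """Collapse identical-sequence length variants into unique repeats.

    Exact duplicates are removed; then any pair with an exact overlap whose
    overhangs satisfy the <50 % rule is merged into the union sequence,
    repeated to closure.  Processing order is deterministic (longest
    first, then lexicographic); the result is idempotent under re-merging.
    Returns unique sequences.
    """
    seqs = [u.sequence if isinstance(u, RepeatUnit) else u for u in units]
    pool = sorted(set(seqs), key=lambda s: (-len(s), s))
    changed = True
    while changed:
        changed = False
        out: list[str] = []
        for s in pool:
            merged_into = False
            for i, k in enumerate(out):
                m = merge_pair(k, s, overhang_denominator)
                if m is not None:
                    out[i] = m
                    merged_into = True
                    changed = changed or (m != k)
                    break
            if not merged_into:
                out.append(s)
        new_pool = sorted(set(out), key=lambda s: (-len(s), s))
        if new_pool == pool:
            break
        pool = new_pool
    return pool


def count_unique(units: list[RepeatUnit], **merge_kwargs) -> dict[str, int]:
    """Unique-repeat count per species after length-variant merging."""
    by_species: dict[str, list[RepeatUnit]] = {}
    for u in units:
        by_species.setdefault(u.species, []).append(u)
    return {
        sp: len(merge_length_variants(us, **merge_kwargs))
        for sp, us in sorted(by_species.items())
    }


@dataclass
class ConsensusProfile:
    """Per-column base counts of a center-star alignment and its consensus."""

    counts: np.ndarray  # (n_columns, 5) over A,C,G,T,- ; N folded into counts[:,4]? no: N ignored
    consensus: str
    support: np.ndarray  # majority fraction per consensus column
    n_sequences: int
    alignment: list[str] = field(default_factory=list)


def center_star_msa(seqs: list[str], scheme: ScoringScheme | None = None) -> list[str]:
    """Progressive multiple alignment on the identity medoid (center star).

    Every sequence is globally aligned to the medoid (the sequence with
    the highest mean pairwise identity; ties broken by input order) and
    the pairwise alignments are merged under "once a gap, always a gap".
    Adequate for unit sets above ~70 % identity; not a general MSA.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if len(seqs) == 1:
        return [seqs[0].upper()]
    scheme = scheme or ScoringScheme()
    n = len(seqs)
    mean_id = np.zeros(n)
    pid = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = pairwise_identity(seqs[i], seqs[j], scheme)
            pid[i, j] = pid[j, i] = p
    mean_id = pid.sum(axis=1) / (n - 1)
    center = int(np.argmax(mean_id))
    c = seqs[center].upper()
    # master gap map: insertions[k] = gap columns before center position k
    insertions = [0] * (len(c) + 1)
    pairs = []
    for i, s in enumerate(seqs):
        if i == center:
            continue
        aln = global_align(c, s, scheme)
        pairs.append((i, aln))
        k = 0
        run = 0
        for ca in aln.gapped_a:
            if ca == "-":
                run += 1
            else:
                insertions[k] = max(insertions[k], run)
                run = 0
                k += 1
        insertions[len(c)] = max(insertions[len(c)], run)
    total_len = len(c) + sum(insertions)
    rows = [None] * n

    def lay_out(gapped_c: str, gapped_s: str) -> str:
        out = []
        k = 0  # center position index
        run = 0
        buf = []
        for ca, cs in zip(gapped_c, gapped_s):
            if ca == "-":
                buf.append(cs)
                run += 1
            else:
                out.append(buf + ["-"] * (insertions[k] - run))
                buf = []
                run = 0
                out.append([cs])
                k += 1
        out.append(buf + ["-"] * (insertions[len(c)] - run))
        return "".join("".join(x) for x in out)

    rows[center] = lay_out(c, c)
    for i, aln in pairs:
        rows[i] = lay_out(aln.gapped_a, aln.gapped_b)
    assert all(len(r) == total_len for r in rows)
    return rows


def build_consensus(seqs: list[str], scheme: ScoringScheme | None = None) -> ConsensusProfile:
    """Majority-rule consensus over a center-star alignment.

    Per column the majority base wins (alphabetical on ties); columns with
    more than 50 % gaps are dropped from the consensus string.  Support is
    the majority count over the non-gap depth of the column.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    msa = center_star_msa(seqs, scheme)
    n = len(msa)
    length = len(msa[0])
    counts = np.zeros((length, 5), dtype=int)  # A C G T gap
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    for row in msa:
        for col, ch in enumerate(row):
            counts[col, idx.get(ch, 4)] += 1  # N counted as gap-like (no base vote)
    cons = []
    support = []
    for col in range(length):
        gaps = counts[col, 4]
        if gaps * 2 > n:
            continue
        base_counts = counts[col, :4]
        best = int(np.argmax(base_counts))  # argmax takes first (alphabetical) on ties
        depth = int(base_counts.sum())
        if depth == 0:
            continue
        cons.append("ACGT"[best])
        support.append(base_counts[best] / depth)
    return ConsensusProfile(
        counts=counts,
        consensus="".join(cons),
        support=np.asarray(support),
        n_sequences=n,
        alignment=msa,
    )


def classify_unit(
    unit: RepeatUnit | str,
    left_consensus: str,
    right_consensus: str,
    scheme: ScoringScheme | None = None,
    canonical_min: float = CANONICAL_MIN,
    variant_min: float = VARIANT_MIN,
    family_min: float = FAMILY_MIN,
) -> str:
    """Classify a unit against the Left/Right canonical consensuses.

    Percent identity (global, count-gaps) to each consensus; the better of
    the two decides the band: >= 90 % -> 'Left'/'Right' (argmax, ties to
    Left); [79.5, 90) -> 'variant'; [55, 79.5) -> 'family-divergent';
    below -> 'unknown'.  Thresholds are configurable; the defaults are the
    bands used for the canonical satellite family.
    """
    seq = unit.sequence if isinstance(unit, RepeatUnit) else unit
    pid_l = pairwise_identity(seq, left_consensus, scheme)
    pid_r = pairwise_identity(seq, right_consensus, scheme)
    best = max(pid_l, pid_r)
    if best >= canonical_min:
        return "Left" if pid_l >= pid_r else "Right"
    if best >= variant_min:
        return "variant"
    if best >= family_min:
        return "family-divergent"
    return "unknown"


@dataclass
class DimerReport:
    """Lag-identity profile of an array and the inferred periodicity."""

    period: int
    lag_identity: dict[int, float]
    dimeric: bool
    within_type_identity: float | None = None
    between_type_identity: float | None = None


def detect_dimer_period(
    arr: RepeatArray | list[str],
    scheme: ScoringScheme | None = None,
    max_lag: int = 4,
    dimer_margin: float = 5.0,
) -> DimerReport:
    """Detect higher-order (dimeric) structure from lag identities.

    Computes the mean identity of unit pairs at lag k = 1..max_lag along
    the array; the period estimate is the smallest lag whose identity is
    within one point of the maximum (a true period-p structure also peaks
    at every multiple of p, so a strict arg-max would flip between p and
    2p under drift noise).  The array is called dimeric when the period is
    2 and lag-2 identity exceeds lag-1 by at least ``dimer_margin`` points
    — the signature of an alternating two-monomer (Left/Right) repeat.
    """
    seqs = arr.sequences() if isinstance(arr, RepeatArray) else list(arr)
    if len(seqs) < 4:
        raise ValueError("dimer detection needs at least 4 units")
    lag_identity: dict[int, float] = {}
    for k in range(1, max_lag + 1):
        pairs = [(seqs[i], seqs[i + k]) for i in range(len(seqs) - k)]
        if not pairs:
            continue
        lag_identity[k] = float(
            np.mean([pairwise_identity(a, b, scheme) for a, b in pairs])
        )
    peak = max(lag_identity.values())
    period = min(k for k, v in lag_identity.items() if v >= peak - 1.0)
    dimeric = period == 2 and lag_identity[2] - lag_identity.get(1, 0.0) >= dimer_margin
    within = lag_identity.get(2)
    between = lag_identity.get(1)
    return DimerReport(period, lag_identity, dimeric, within, between)


def unit_fasta_header(u: RepeatUnit) -> str:
    """Structured FASTA id: species|source|start-end|strand|type."""
    return f"{u.species}|{u.source_id}|{u.start}-{u.end}|{u.strand}|{u.type_label}"
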