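"""Forward simulation of tandem-repeat-array evolution along a species tree.

The model: an ancestral array of fixed-length monomers evolves in discrete
generations.  Per generation, on each branch, three Poisson event classes
act in a fixed order (substitutions, then gene conversions, then unequal
crossovers — fixed so event logs are replayable):

* substitutions — Poisson(mu · sites) point mutations, site uniform, new
  base uniform among the three alternatives (a Jukes–Cantor process);
* gene conversions — Poisson(gc_rate) non-reciprocal tract copies from a
  uniform donor unit onto a uniform recipient unit, tract length geometric
  with mean ``gc_tract_mean`` (support >= 1 bp), clipped at the monomer end;
* unequal crossovers — Poisson(uxo_rate) intra-lineage exchanges: the array
  recombines with a copy of itself misaligned by a geometric offset of k
  monomers (mean ``uxo_offset_mean``); the longer (n+k) or shorter (n−k)
  product is kept with equal probability; offsets whose product would
  leave [min_copies, max_copies] are resampled.

Crossovers operate on monomer boundaries only and there are no indel
mutations, so every unit keeps the ancestral monomer length and remains
traceable to an ancestral monomer.  Lineage-specific substitution-rate
multipliers implement accelerated evolution on named branches.  A single
RNG stream per :func:`evolve` call and a fixed preorder branch traversal
make runs fully determined by the seed.

Every event is logged; :func:`replay_log` reproduces a leaf array
bit-exactly from the ancestor, which is the simulator's own correctness
oracle and the ground truth for downstream benchmarks.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .align import global_align, percent_identity
from .repeats import RepeatArray, RepeatUnit

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Rates and bounds of the array-evolution model.

    Rates are per array per generation except ``mu`` (per site per
    generation).  ``rate_multipliers`` maps a branch label (leaf or
    internal node name) to a substitution-rate scale factor on that
    branch.
    """

    monomer_length: int = 120
    initial_copies: int = 16
    mu: float = 5e-5
    uxo_rate: float = 0.05
    uxo_offset_mean: float = 2.0
    gc_rate: float = 0.1
    gc_tract_mean: float = 60.0
    min_copies: int = 4
    max_copies: int = 64
    rate_multipliers: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu, self.uxo_rate, self.gc_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not (1 <= self.min_copies <= self.initial_copies <= self.max_copies):
            raise ValueError("require 1 <= min_copies <= initial_copies <= max_copies")
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if self.uxo_offset_mean < 1 or self.gc_tract_mean < 1:
            raise ValueError("offset/tract means must be >= 1")


@dataclass
class SpeciesTreeSpec:
    """A rooted species tree with branch lengths in generations."""

    newick: str

    def parse(self) -> dendropy.Tree:
        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be non-negative")
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("leaf labels must be unique")
        return tree

    def labels(self) -> set[str]:
        tree = self.parse()
        labs = {lf.taxon.label for lf in tree.leaf_node_iter()}
        for nd in tree.preorder_node_iter():
            if nd.label:
                labs.add(nd.label)
        return labs


@dataclass
class Event:
    """One logged mutation/exchange/speciation event."""

    generation: int
    kind: str  # substitution | conversion | uxo | speciation
    params: tuple

    def to_json(self) -> dict:
        return {"generation": self.generation, "kind": self.kind, "params": list(self.params)}


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def append(self, ev: Event) -> None:
        if self.events and ev.generation < self.events[-1].generation:
            raise ValueError("event generations must be non-decreasing")
        self.events.append(ev)

    def __len__(self) -> int:
        return len(self.events)

    def to_json(self) -> str:
        return json.dumps([e.to_json() for e in self.events])


@dataclass
class EvolvedLocus:
    """The evolved array of one species plus its full event history."""

    species: str
    array: RepeatArray
    event_log: EventLog
    ancestor_ids: list[int] = field(default_factory=list)
    type_labels: list[str] = field(default_factory=list)


def make_dimer_ancestor(
    left_seed: str, right_seed: str, n_dimers: int, seed: int = 0, label: str = "ancestor"
) -> RepeatArray:
    """Ancestral array of ``n_dimers`` Left/Right dimers (2·n units).

    Units alternate Left, Right, Left, Right, … each labelled with its
    type.  Seeds must be non-empty and of similar length (within 20 %).
    """
    if not left_seed or not right_seed:
        raise ValueError("seed sequences must be non-empty")
    if n_dimers < 1:
        raise ValueError("n_dimers must be >= 1")
    la, lb = len(left_seed), len(right_seed)
    if abs(la - lb) > 0.2 * max(la, lb):
        raise ValueError("seed lengths differ by more than 20%")
    units = []
    pos = 0
    for i in range(2 * n_dimers):
        seq = (left_seed if i % 2 == 0 else right_seed).upper()
        units.append(
            RepeatUnit(
                unit_id=f"{label}.{i}",
                sequence=seq,
                source_id=label,
                start=pos,
                end=pos + len(seq),
                type_label="Left" if i % 2 == 0 else "Right",
            )
        )
        pos += len(seq)
    return RepeatArray(source_id=label, units=units, locus_label=label)


def random_monomer(length: int, seed: int = 0, gc: float = 0.5) -> str:
    """A random monomer with the given GC content (composition draw)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def diverge(seq: str, n_subs: int, seed: int = 0) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    rng = np.random.default_rng(seed)
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_subs, replace=False):
        arr[pos] = rng.choice([b for b in _BASES if b != arr[pos]])
    return "".join(arr)


class _ArrayState:
    """Mutable array during simulation: per-unit sequence + ancestry."""

    __slots__ = ("seqs", "anc", "types")

    def __init__(self, seqs, anc, types):
        self.seqs = seqs  # list of bytearray
        self.anc = anc  # ancestral monomer index per unit
        self.types = types

    @classmethod
    def from_array(cls, arr: RepeatArray) -> "_ArrayState":
        return cls(
            [bytearray(u.sequence, "ascii") for u in arr.units],
            list(range(len(arr.units))),
            [u.type_label for u in arr.units],
        )

    def copy(self) -> "_ArrayState":
        return _ArrayState([bytearray(s) for s in self.seqs], list(self.anc), list(self.types))

    def __len__(self) -> int:
        return len(self.seqs)


def _apply_substitution(state: _ArrayState, unit: int, pos: int, new_base: str) -> None:
    state.seqs[unit][pos] = ord(new_base)


def _apply_conversion(state: _ArrayState, donor: int, recipient: int, start: int, length: int) -> None:
    state.seqs[recipient][start:start + length] = state.seqs[donor][start:start + length]


def _apply_uxo(state: _ArrayState, k: int, j: int, keep_longer: bool) -> None:
    if keep_longer:
        idx = list(range(0, j)) + list(range(j - k, len(state)))
    else:
        idx = list(range(0, j - k)) + list(range(j, len(state)))
    state.seqs = [bytearray(state.seqs[i]) for i in idx]
    state.anc = [state.anc[i] for i in idx]
    state.types = [state.types[i] for i in idx]


def _evolve_branch(
    state: _ArrayState,
    generations: int,
    params: SimParams,
    mult: float,
    rng: np.random.Generator,
    log: EventLog,
    gen_offset: int,
) -> int:
    L = params.monomer_length
    mu = params.mu * mult
    for g in range(generations):
        gen = gen_offset + g + 1
        n = len(state)
        sites = n * L
        # substitutions
        for _ in range(rng.poisson(mu * sites)):
            site = int(rng.integers(sites))
            unit, pos = divmod(site, L)
            old = chr(state.seqs[unit][pos])
            new = _BASES[(("ACGT".index(old) if old in _BASES else 0) + 1 + int(rng.integers(3))) % 4]
            _apply_substitution(state, unit, pos, new)
            log.append(Event(gen, "substitution", (unit, pos, new)))
        # gene conversions
        if n >= 2:
            for _ in range(rng.poisson(params.gc_rate)):
                donor = int(rng.integers(n))
                recipient = int(rng.integers(n - 1))
                if recipient >= donor:
                    recipient += 1
                start = int(rng.integers(L))
                tract = min(int(rng.geometric(1.0 / params.gc_tract_mean)), L - start)
                _apply_conversion(state, donor, recipient, start, tract)
                log.append(Event(gen, "conversion", (donor, recipient, start, tract)))
        # unequal crossovers
        for _ in range(rng.poisson(params.uxo_rate)):
            n = len(state)
            for _try in range(100):  # resample offsets that violate size bounds
                k = int(rng.geometric(1.0 / params.uxo_offset_mean))
                keep_longer = bool(rng.integers(2))
                new_n = n + k if keep_longer else n - k
                if params.min_copies <= new_n <= params.max_copies and k < n:
                    j = int(rng.integers(k, n))
                    _apply_uxo(state, k, j, keep_longer)
                    log.append(Event(gen, "uxo", (k, j, keep_longer)))
                    break
    return gen_offset + generations


def evolve(
    ancestor: RepeatArray,
    tree: SpeciesTreeSpec,
    params: SimParams,
) -> dict[str, EvolvedLocus]:
    """Evolve the ancestral array along the species tree.

    Returns one :class:`EvolvedLocus` per leaf, each carrying the full
    root-to-leaf event log (with speciation markers) so the leaf array can
    be reproduced exactly by :func:`replay_log`.
    """
    t = tree.parse()
    known = tree.labels()
    for lab in params.rate_multipliers:
        if lab not in known:
            raise ValueError(f"rate multiplier for unknown lineage label {lab!r}")
    rng = np.random.default_rng(params.seed)
    out: dict[str, EvolvedLocus] = {}

    def branch_label(node: dendropy.Node) -> str | None:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def recurse(node: dendropy.Node, state: _ArrayState, log_events: list[Event], gen: int) -> None:
        for child in node.child_nodes():
            lab = branch_label(child)
            child_state = state.copy()
            child_log = EventLog(list(log_events))
            child_log.append(Event(gen, "speciation", (lab or "",)))
            generations = int(round(child.edge.length or 0))
            mult = params.rate_multipliers.get(lab, 1.0) if lab else 1.0
            child_gen = _evolve_branch(
                child_state, generations, params, mult, rng, child_log, gen
            )
            if child.is_leaf():
                out[lab] = _to_locus(lab, child_state, child_log, params)
            else:
                recurse(child, child_state, child_log.events, child_gen)

    root_state = _ArrayState.from_array(ancestor)
    recurse(t.seed_node, root_state, [], 0)
    return out


def _to_locus(species: str, state: _ArrayState, log: EventLog, params: SimParams) -> EvolvedLocus:
    L = params.monomer_length
    units = []
    for i, s in enumerate(state.seqs):
        units.append(
            RepeatUnit(
                unit_id=f"{species}.u{i}",
                sequence=s.decode("ascii"),
                source_id=f"{species}_locus",
                start=i * L,
                end=i * L + len(s),
                species=species,
                locus_label=species,
                type_label=state.types[i],
            )
        )
    arr = RepeatArray(source_id=f"{species}_locus", units=units, locus_label=species)
    return EvolvedLocus(species, arr, log, list(state.anc), list(state.types))


def replay_log(ancestor: RepeatArray, log: EventLog) -> list[str]:
    """Re-apply an event log to the ancestor; returns the final unit sequences.

    Replaying a leaf's log reproduces its array bit-exactly — the
    round-trip correctness oracle for the simulator.
    """
    state = _ArrayState.from_array(ancestor)
    for ev in log.events:
        if ev.kind == "substitution":
            _apply_substitution(state, *ev.params)
        elif ev.kind == "conversion":
            _apply_conversion(state, *ev.params)
        elif ev.kind == "uxo":
            _apply_uxo(state, *ev.params)
        elif ev.kind != "speciation":
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return [s.decode("ascii") for s in state.seqs]


def emit_collapsed_contigs(
    locus: EvolvedLocus, collapse_identity: float, max_tandem: int = 3
) -> dict[str, str]:
    """Assembly-collapse emulation: near-identical units become one contig.

    Units are partitioned by single-linkage clustering at
    >= ``collapse_identity`` pairwise percent identity; each partition is
    represented by one tandem contig (the cluster medoid tiled up to
    ``max_tandem`` copies), mimicking how de novo assembly of a satellite
    collapses nearly identical monomers into a short tandem contig.
    """
    if not (0 < collapse_identity <= 100):
        raise ValueError("collapse_identity must be in (0, 100]")
    seqs = locus.array.sequences()
    n = len(seqs)
    pid = np.zeros((n, n))
    for i in range(n):
        pid[i, i] = 100.0
        for j in range(i + 1, n):
            pid[i, j] = pid[j, i] = percent_identity(global_align(seqs[i], seqs[j]))
    # single-linkage components over the >= threshold graph
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pid[i, j] >= collapse_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    contigs = {}
    for ci, members in enumerate(sorted(clusters.values(), key=lambda m: m[0])):
        sub = pid[np.ix_(members, members)]
        medoid = members[int(np.argmax(sub.mean(axis=1)))]
        tile = min(len(members), max_tandem)
        contigs[f"{locus.species}_contig{ci}"] = seqs[medoid] * tile
    return contigs


def emit_reads(
    locus: EvolvedLocus,
    read_length: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Uniform single-end reads with substitution errors and PHRED+33 quality.

    Read count ~= coverage * array_length / read_length; positions uniform;
    each base flips to a uniform alternative with probability
    ``error_rate``; the constant per-base quality encodes that error rate
    (Q = −10·log10(e), clamped to [2, 40]).  Deterministic under seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    template = locus.array.sequence
    if read_length > len(template):
        raise ValueError("read_length exceeds the array length")
    n_reads = int(round(coverage * len(template) / read_length))
    q = 40 if error_rate <= 0 else min(40, max(2, round(-10 * math.log10(error_rate))))
    qual = chr(q + 33) * read_length
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    reads = []
    for r in range(n_reads):
        start = int(rng.integers(0, len(template) - read_length + 1))
        seq = list(template[start:start + read_length])
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            for pos in errs:
                seq[pos] = _BASES[(base_idx.get(seq[pos], 0) + 1 + int(rng.integers(3))) % 4]
        reads.append((f"{locus.species}_read{r}_{start}", "".join(seq), qual))
    return reads


def truth_table(loci: dict[str, EvolvedLocus]) -> list[dict]:
    """Flat truth records (unit id, species, type, coordinates, ancestry)."""
    rows = []
    for sp in sorted(loci):
        locus = loci[sp]
        for u, anc in zip(locus.array.units, locus.ancestor_ids):
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "species": sp,
                    "type": u.type_label,
                    "start": u.start,
                    "end": u.end,
                    "ancestor_monomer": anc,
                }
            )
    return rows
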