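"""End-to-end orchestration: simulate → search → extract → classify → stats → trees.

A :class:`RunConfig` (single declarative mapping, YAML-loadable) drives a
fixed stage order; every stochastic stage derives its stream from the one
global seed, so a rerun with the same config is bit-identical.  The
:class:`RunReport` carries per-stage record counts and filter tallies (the
machine-readable analogue of hits "inspected by eye"), the unique-repeat
table, identity summaries, permutation p-values, Newick trees and
monophyly verdicts, and satisfies the accounting invariant
kept + excluded + flagged-partial = total at the unit level.
"""
from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import scenarios
from .align import ScoringScheme
from .io import write_fasta, write_fastq
from .phylo import bootstrap_support, is_monophyletic, to_newick
from .repeats import (
    RepeatUnit,
    center_star_msa,
    classify_unit,
    count_unique,
    extract_units,
)
from .search import SearchConfig, iterative_capture
from .simulate import emit_collapsed_contigs, emit_reads, evolve
from .stats import concerted_evolution_score, identity_summary, permutation_homology_test


@dataclass
class RunConfig:
    """Declarative configuration of a full run.

    Either a ``simulate`` block (scenario name or explicit parameters) or
    input FASTA paths.  Every capture/classification constant is a named
    key with the package default.
    """

    outdir: str = "satevo_run"
    seed: int = 0
    scenario: str = "concerted"  # concerted | null | accelerated
    collapse_identity: float = 98.0
    evalue_max: float = 0.1
    min_length: int = 30
    inspect_evalue: float = 1e-3
    inspect_length: int = 50
    variant_min: float = 79.5
    canonical_min: float = 90.0
    permutation_B: int = 999
    concerted_B: int = 999
    bootstrap_B: int = 100
    gap_policy: str = "count-gaps"
    read_coverage: float = 20.0
    read_length: int = 100
    read_error_rate: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            scoring=ScoringScheme(),
            evalue_max=self.evalue_max,
            min_length=self.min_length,
            inspect_evalue=self.inspect_evalue,
            inspect_length=self.inspect_length,
        )


@dataclass
class RunReport:
    """Machine-readable record of one end-to-end run."""

    config: dict
    stage_counts: dict = field(default_factory=dict)
    filter_tally: dict = field(default_factory=dict)
    unique_repeats: dict = field(default_factory=dict)
    identity: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    concerted: dict = field(default_factory=dict)
    newick: str = ""
    monophyly: dict = field(default_factory=dict)

    def validate_accounting(self) -> None:
        """kept + partial-excluded must equal total extracted units."""
        sc = self.stage_counts
        if sc.get("units_total", 0) != sc.get("units_kept", 0) + sc.get("units_partial", 0):
            raise AssertionError("unit accounting violated")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _scenario(cfg: RunConfig):
    builders = {
        "concerted": scenarios.concerted_scenario,
        "null": scenarios.null_scenario,
        "accelerated": scenarios.accelerated_scenario,
    }
    if cfg.scenario not in builders:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return builders[cfg.scenario](seed=cfg.seed)


def run(cfg: RunConfig, write_files: bool = True) -> RunReport:
    """Execute the full pipeline on a simulated dataset.

    Stage order: simulate → emit contigs/reads → iterative capture →
    unit extraction → length-variant merge → classification → identity
    and permutation statistics → concerted-evolution score → NJ tree with
    bootstrap → per-species monophyly.
    """
    report = RunReport(config=dataclasses.asdict(cfg))
    outdir = Path(cfg.outdir)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)

    ancestor, tree, params = _scenario(cfg)
    loci = evolve(ancestor, tree, params)
    report.stage_counts["species"] = len(loci)
    report.stage_counts["units_simulated"] = sum(len(l.array) for l in loci.values())

    # stage: emulate assembly collapse + reads
    contigs: dict[str, str] = {}
    for sp in sorted(loci):
        contigs.update(emit_collapsed_contigs(loci[sp], cfg.collapse_identity))
        if write_files:
            reads = emit_reads(
                loci[sp], cfg.read_length, cfg.read_coverage, cfg.read_error_rate,
                seed=params.seed + 7,
            )
            write_fastq(reads, outdir / f"{sp}_reads.fastq")
    report.stage_counts["contigs"] = len(contigs)
    if write_files:
        write_fasta(contigs, outdir / "contigs.fasta")
        for sp in sorted(loci):
            write_fasta(
                {u.unit_id: u.sequence for u in loci[sp].array.units},
                outdir / f"{sp}_units.fasta",
            )

    # stage: iterative homology capture seeded with the ancestral monomer
    scfg = cfg.search_config()
    seeds = {"seed_monomer": ancestor.units[0].sequence}
    tally: dict = {}
    captured, trace = iterative_capture(seeds, contigs, scfg, tally)
    report.stage_counts["captured"] = len(captured)
    report.stage_counts["capture_rounds"] = trace.n_rounds
    report.filter_tally = tally

    # stage: unit extraction from contigs against the ancestral consensus
    consensus = ancestor.units[0].sequence
    units: list[RepeatUnit] = []
    for cid in sorted(contigs):
        sp = cid.split("_contig")[0]
        units.extend(extract_units(contigs[cid], consensus, scfg, source_id=cid, species=sp))
    kept = [u for u in units if not u.partial]
    report.stage_counts["units_total"] = len(units)
    report.stage_counts["units_kept"] = len(kept)
    report.stage_counts["units_partial"] = len(units) - len(kept)
    report.validate_accounting()

    # stage: unique repeats per species (post-merge)
    report.unique_repeats = count_unique(kept)

    # stage: classification against the Left/Right seeds
    left, right = scenarios.dimer_seeds(1)
    class_counts: dict[str, int] = {}
    for u in kept:
        u.type_label = classify_unit(
            u, left, right, canonical_min=cfg.canonical_min, variant_min=cfg.variant_min
        )
        class_counts[u.type_label] = class_counts.get(u.type_label, 0) + 1
    report.stage_counts["classified"] = class_counts

    # stage: identity summaries within/between species on the true units
    by_species = {sp: loci[sp].array.sequences() for sp in sorted(loci)}
    for sp, seqs in by_species.items():
        if len(seqs) >= 2:
            s = identity_summary(seqs, gap_policy=cfg.gap_policy, grouping=f"within-{sp}")
            report.identity[f"within-{sp}"] = dataclasses.asdict(s)
    sps = sorted(by_species)
    if len(sps) >= 2:
        s = identity_summary(
            by_species[sps[0]], by_species[sps[1]], gap_policy=cfg.gap_policy,
            grouping=f"between-{sps[0]}-{sps[1]}",
        )
        report.identity[f"between-{sps[0]}-{sps[1]}"] = dataclasses.asdict(s)

    # stage: permutation homology test on one cross-species pair
    a = by_species[sps[0]][0]
    b = by_species[sps[-1]][0]
    pr = permutation_homology_test(a, b, B=cfg.permutation_B, seed=cfg.seed + 11)
    report.permutation = dataclasses.asdict(pr)

    # stage: concerted-evolution score over species groups
    all_units = [u for sp in sps for u in loci[sp].array.units]
    cs = concerted_evolution_score(
        all_units, B=cfg.concerted_B, seed=cfg.seed + 13, group_by="species"
    )
    report.concerted = dataclasses.asdict(cs)

    # stage: NJ tree with bootstrap + per-species monophyly
    named = {}
    for sp in sps:
        for u in loci[sp].array.units:
            named[u.unit_id] = u.sequence
    msa_rows = center_star_msa(list(named.values()))
    msa = dict(zip(named.keys(), msa_rows))
    t = bootstrap_support(msa, B=cfg.bootstrap_B, seed=cfg.seed + 17)
    report.newick = to_newick(t)
    for sp in sps:
        leaves = [u.unit_id for u in loci[sp].array.units]
        mono, _ = is_monophyletic(t, leaves)
        report.monophyly[sp] = bool(mono)

    if write_files:
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "tree.nwk").write_text(report.newick + "\n")
        with open(outdir / "unique_repeats.tsv", "w") as fh:
            fh.write("species\tunique_repeats\n")
            for sp, n in report.unique_repeats.items():
                fh.write(f"{sp}\t{n}\n")
    return report


_ACCESSION_RE = re.compile(r"^(?:[A-Z]{1,2}\d{5,8}(?:\.\d+)?|[A-Z]{2}_\d+(?:\.\d+)?|[DES]RR\d{6,9})$")


def fetch_and_prepare(accessions: list[str], cache_dir: str | Path) -> dict[str, Path]:
    """Resolve accessions to cached FASTA files, fetching any that are absent.

    Cached files (``<accession>.fasta`` under ``cache_dir``) are used
    without network access; missing ones are fetched from NCBI efetch.
    Malformed or unreachable accessions raise a clear error naming the id
    — never a silent skip.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for acc in accessions:
        if not _ACCESSION_RE.match(acc):
            raise ValueError(f"malformed accession: {acc!r}")
        path = cache / f"{acc}.fasta"
        if path.exists():
            out[acc] = path
            continue
        url = (
            "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
            f"?db=nuccore&id={acc}&rettype=fasta&retmode=text"
        )
        try:
            from urllib.request import urlopen

            with urlopen(url, timeout=60) as resp:
                data = resp.read().decode()
        except Exception as exc:  # noqa: BLE001 - report the id either way
            raise RuntimeError(f"could not fetch accession {acc!r}: {exc}") from exc
        if not data.startswith(">"):
            raise RuntimeError(f"accession {acc!r} returned no FASTA record")
        path.write_text(data)
        out[acc] = path
    return out
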