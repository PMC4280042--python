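"""Canned simulation scenarios: the package's documented study conditions.

Each scenario fixes an ancestral array, a species tree (branch lengths in
generations) and :class:`~satevo.simulate.SimParams`.  They emulate the
biology the package targets — a ~120-bp satellite monomer with a
Left/Right dimeric higher-order structure, exchange-driven homogenization
within lineages, and rate acceleration on a focal lineage — at desk scale.
Rationale for every number is in docs/methods.md; scenario parameters are
part of the package's definition and are not tuned per run.
"""
from __future__ import annotations

from .simulate import (
    RepeatArray,
    SimParams,
    SpeciesTreeSpec,
    diverge,
    make_dimer_ancestor,
    random_monomer,
)

MONOMER_LENGTH = 120
#: Left/Right seeds at ~84% identity (19 of 120 sites differ), mirroring the
#: canonical dimer divergence.
DIMER_DIVERGENCE_SITES = 19


def dimer_seeds(seed: int = 0) -> tuple[str, str]:
    """A Left monomer and a Right monomer at ~84 % identity."""
    left = random_monomer(MONOMER_LENGTH, seed=seed)
    right = diverge(left, DIMER_DIVERGENCE_SITES, seed=seed + 1)
    return left, right


def uniform_ancestor(n_copies: int = 16, seed: int = 0) -> RepeatArray:
    """Ancestral array of identical copies of one random monomer."""
    left, _ = dimer_seeds(seed)
    return make_dimer_ancestor(left, left, n_copies // 2, seed)


def dimer_ancestor(n_dimers: int = 8, seed: int = 0) -> RepeatArray:
    left, right = dimer_seeds(seed)
    return make_dimer_ancestor(left, right, n_dimers, seed)


def three_species_tree(t: int = 600) -> SpeciesTreeSpec:
    """((A,B),C) with terminal branches of ``t`` generations."""
    return SpeciesTreeSpec(f"((A:{t},B:{t}):{t // 2},C:{int(1.5 * t)});")


def concerted_scenario(seed: int = 0) -> tuple[RepeatArray, SpeciesTreeSpec, SimParams]:
    """Exchange-driven homogenization across a 3-species tree.

    Turnover is fast relative to drift: each unit is overwritten by
    conversion/crossover several times per branch, so within-species
    identity stays high while between-species identity decays with 2·mu·T.
    """
    params = SimParams(
        monomer_length=MONOMER_LENGTH,
        initial_copies=16,
        mu=5e-5,
        uxo_rate=0.1,
        uxo_offset_mean=2.0,
        gc_rate=0.2,
        gc_tract_mean=80.0,
        min_copies=4,
        max_copies=64,
        seed=seed,
    )
    return uniform_ancestor(16, seed=1), three_species_tree(600), params


def null_scenario(seed: int = 0) -> tuple[RepeatArray, SpeciesTreeSpec, SimParams]:
    """Mutation only (uxo = gc = 0): units drift independently.

    Within- and between-species identities then share one expectation, the
    null for the concerted-evolution score.
    """
    params = SimParams(
        monomer_length=MONOMER_LENGTH,
        initial_copies=16,
        mu=5e-5,
        uxo_rate=0.0,
        gc_rate=0.0,
        min_copies=4,
        max_copies=64,
        seed=seed,
    )
    return uniform_ancestor(16, seed=1), three_species_tree(600), params


def jc_scenario(
    divergence: float, mu: float = 5e-5, seed: int = 0
) -> tuple[RepeatArray, SpeciesTreeSpec, SimParams]:
    """Two species, mutation only, tuned so 2·mu·T equals ``divergence``."""
    t = int(round(divergence / (2 * mu)))
    params = SimParams(
        monomer_length=MONOMER_LENGTH,
        initial_copies=16,
        mu=mu,
        uxo_rate=0.0,
        gc_rate=0.0,
        min_copies=4,
        max_copies=64,
        seed=seed,
    )
    return uniform_ancestor(16, seed=1), SpeciesTreeSpec(f"(A:{t},B:{t});"), params


FOCAL_SPECIES = "A"


def accelerated_scenario(
    multiplier: float = 5.0, seed: int = 0
) -> tuple[RepeatArray, SpeciesTreeSpec, SimParams]:
    """Rate acceleration on one terminal lineage, homogenization everywhere.

    Unit turnover is fast (frequent crossovers, near-full-monomer
    conversion tracts) so each species' array homogenizes within its
    terminal branch, and the substitution input is low enough that species
    stems carry only a handful of shared substitutions; a 5× multiplier on
    the focal branch then gives that lineage a strong shared stem signal —
    the accelerated-lineage monophyly pattern of a satellite that is the
    drive target in one species.
    """
    params = SimParams(
        monomer_length=MONOMER_LENGTH,
        initial_copies=16,
        mu=1e-5,
        uxo_rate=0.3,
        uxo_offset_mean=3.0,
        gc_rate=0.3,
        gc_tract_mean=110.0,
        min_copies=4,
        max_copies=48,
        rate_multipliers={FOCAL_SPECIES: multiplier},
        seed=seed,
    )
    tree = SpeciesTreeSpec("((A:800,B:800):400,C:1200);")
    return uniform_ancestor(16, seed=1), tree, params
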