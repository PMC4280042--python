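"""Self-contained correctness and calibration benchmarks.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and returns summary numbers.  They power both the acceptance
test suite and ``scripts/acceptance.py``; problem sizes are the package's
documented study conditions (docs/methods.md).
"""
from __future__ import annotations

import math

import dendropy
import numpy as np

from . import scenarios
from .phylo import (
    DistanceMatrix,
    indel_block_distance,
    is_monophyletic,
    neighbor_joining,
    robinson_foulds,
)
from .repeats import center_star_msa, merge_length_variants
from .scenarios import FOCAL_SPECIES
from .search import SearchConfig, evalue, karlin_lambda, search_db
from .simulate import diverge, evolve, random_monomer
from .stats import concerted_evolution_score, permutation_homology_test


# ------------------------------------------------------------------ NJ oracle
def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with branch lengths in [0.1, 1] and its metric."""
    labels = [f"t{i}" for i in range(n_taxa)]

    def build(labs):
        if len(labs) == 1:
            return f"{labs[0]}:{rng.uniform(0.1, 1.0):.9f}"
        k = int(rng.integers(1, len(labs)))
        return f"({build(labs[:k])},{build(labs[k:])}):{rng.uniform(0.1, 1.0):.9f}"

    newick = f"({build(labels[:1])},{build(labels[1:])});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_taxa):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
    return tree, DistanceMatrix(labels, mat)


def nj_additivity_benchmark(n_matrices: int = 100, seed: int = 0) -> dict:
    """NJ consistency: fraction of random additive matrices recovered exactly.

    Recovery = Robinson–Foulds distance 0 to the generating tree and every
    patristic distance reproduced to 1e-9.
    """
    rng = np.random.default_rng(seed)
    recovered = 0
    max_err = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(6, 11))
        true_tree, dm = random_additive_matrix(rng, n)
        nj = neighbor_joining(dm)
        rf = robinson_foulds(true_tree, nj)
        pdm = nj.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in nj.taxon_namespace}
        err = max(
            abs(pdm.patristic_distance(taxa[a], taxa[b]) - dm.matrix[i, j])
            for i, a in enumerate(dm.labels)
            for j, b in enumerate(dm.labels)
            if i < j
        )
        max_err = max(max_err, err)
        recovered += rf == 0 and err <= 1e-9
    return {"recovered_fraction": recovered / n_matrices,
            "max_patristic_error": max_err, "n": n_matrices}


# ------------------------------------------------------- permutation calibration
def permutation_calibration(
    n_rep: int = 200, B: int = 999, length: int = 120, alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the shuffle homology test on independent null pairs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        a = "".join(rng.choice(list("ACGT"), size=length))
        b = "".join(rng.choice(list("ACGT"), size=length))
        r = permutation_homology_test(a, b, B=B, seed=int(rng.integers(2**31)))
        rejections += r.p_value <= alpha
    floor = permutation_homology_test(
        random_monomer(length, seed=seed + 1), random_monomer(length, seed=seed + 1),
        B=B, seed=seed + 2,
    )
    return {"rejection_rate": rejections / n_rep, "alpha": alpha,
            "identical_pair_p": floor.p_value, "B": B, "n": n_rep}


# ------------------------------------------------------- concerted evolution
def concerted_benchmark(
    n_rep: int = 50, B: int = 999, seed: int = 0, scenario: str = "concerted",
    alpha: float = 0.01,
) -> dict:
    """Recovery (or null calibration) of the concerted-evolution signature."""
    builder = {
        "concerted": scenarios.concerted_scenario,
        "null": scenarios.null_scenario,
    }[scenario]
    hits = 0
    deltas = []
    for i in range(n_rep):
        anc, tree, params = builder(seed=seed + i)
        loci = evolve(anc, tree, params)
        units = [u for l in loci.values() for u in l.array.units]
        cs = concerted_evolution_score(
            units, B=B, seed=seed + 10_000 + i, group_by="species"
        )
        deltas.append(cs.delta)
        hits += (cs.p_value <= alpha) and (cs.delta > 0)
    return {"recovery_fraction": hits / n_rep, "mean_delta": float(np.mean(deltas)),
            "alpha": alpha, "n": n_rep}


# ------------------------------------------------------- accelerated lineage
def monophyly_benchmark(multiplier: float, n_rep: int = 50, seed: int = 0) -> dict:
    """Fraction of replicates where the focal species' units form an NJ clade."""
    hits = 0
    for i in range(n_rep):
        anc, tree, params = scenarios.accelerated_scenario(
            multiplier=multiplier, seed=seed + i
        )
        loci = evolve(anc, tree, params)
        named = {u.unit_id: u.sequence for l in loci.values() for u in l.array.units}
        rows = center_star_msa(list(named.values()))
        t = neighbor_joining(indel_block_distance(dict(zip(named, rows))))
        focal = [u.unit_id for u in loci[FOCAL_SPECIES].array.units]
        hits += is_monophyletic(t, focal)[0]
    return {"monophyly_fraction": hits / n_rep, "multiplier": multiplier, "n": n_rep}


# ------------------------------------------------------------------ JC check
def jc_divergence_benchmark(divergence: float, n_rep: int = 20, seed: int = 0) -> dict:
    """Mutation-only between-species divergence vs the Jukes–Cantor expectation."""
    diffs = sites = 0
    for i in range(n_rep):
        anc, tree, params = scenarios.jc_scenario(divergence, seed=seed + i)
        loci = evolve(anc, tree, params)
        for sa, sb in zip(loci["A"].array.sequences(), loci["B"].array.sequences()):
            diffs += sum(x != y for x, y in zip(sa, sb))
            sites += len(sa)
    observed = diffs / sites
    expected = 0.75 * (1.0 - math.exp(-4.0 * divergence / 3.0))
    return {"observed_divergence": observed, "expected_divergence": expected,
            "relative_error": abs(observed - expected) / expected, "n": n_rep}


# ------------------------------------------------------------------ merge rule
def merge_idempotence_benchmark(n_sets: int = 1000, seed: int = 0) -> dict:
    """Idempotence of length-variant merging on random fragment sets."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_sets):
        base = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 160))))
        frags = []
        for _ in range(int(rng.integers(2, 9))):
            i = int(rng.integers(0, len(base) - 10))
            j = int(rng.integers(i + 10, len(base) + 1))
            frags.append(base[i:j])
        once = merge_length_variants(frags)
        ok += merge_length_variants(once) == once and len(once) <= len(frags)
    return {"idempotent_fraction": ok / n_sets, "n": n_sets}


# ------------------------------------------------------------------ filters
def filter_fixture_check(seed: int = 0) -> dict:
    """Reproduce the capture filters on constructed fixtures.

    A 25-bp exact hit passes the E-value cut but is excluded by the 30-bp
    length floor; a weak ~40-bp hit with E in (0.001, 0.1] is kept with the
    review flag; a diverged segment whose best E-value exceeds 0.1 yields
    no hit at all.
    """
    rng = np.random.default_rng(seed)
    cfg = SearchConfig()
    lam = karlin_lambda(cfg.scoring)
    out = {"n": 3}

    # short exact hit: excluded by length despite a tiny E-value
    subject = "".join(rng.choice(list("ACGT"), size=400))
    query = subject[100:125]
    assert evalue(25, 25, 400, lam) < cfg.evalue_max
    tally: dict = {}
    hits = search_db({"q": query}, {"s": subject}, cfg, tally=tally)
    out["short_hit_excluded"] = float(
        tally.get("excluded_length", 0) >= 1
        and not any(h.subject_start == 100 and h.length == 25 for h in hits)
    )

    # weak ~40-bp hit in the inspect window: review-flagged, not dropped
    base = "".join(rng.choice(list("ACGT"), size=40))
    f1 = "".join(rng.choice(list("ACGT"), size=80))
    f2 = "".join(rng.choice(list("ACGT"), size=80))
    flagged = 0.0
    for n_mut in range(9, 15):
        for sd in range(60):
            hits = search_db(
                {"q": base}, {"s": f1 + diverge(base, n_mut, seed=1000 * n_mut + sd) + f2},
                cfg,
            )
            window = [
                h for h in hits
                if cfg.inspect_evalue < h.evalue <= cfg.evalue_max
                and cfg.min_length <= h.length < cfg.inspect_length
            ]
            if window:
                flagged = float(all(h.review for h in window))
                break
        if flagged:
            break
    out["weak_hit_review_flagged"] = flagged

    # heavily diverged segment: best attainable E-value above the 0.1 cut
    far = diverge(base, 24, seed=77)  # ~40 % corrupted
    tally2: dict = {}
    hits = search_db({"q": base}, {"s": f1 + far + f2}, cfg, tally=tally2)
    out["insignificant_hit_excluded"] = float(len(hits) == 0)
    return out
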