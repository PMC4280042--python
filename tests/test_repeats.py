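"""Unit extraction, length-variant merging, consensus, classification, dimers."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satevo.align import pairwise_identity, reverse_complement
from satevo.repeats import (
    RepeatUnit,
    build_consensus,
    center_star_msa,
    classify_unit,
    count_unique,
    detect_dimer_period,
    extract_units,
    merge_length_variants,
    merge_pair,
)
from satevo.simulate import diverge, evolve, make_dimer_ancestor, random_monomer
from satevo.scenarios import concerted_scenario, dimer_seeds


# ---------------------------------------------------------------- extraction
class TestExtractUnits:
    def test_tandem_contig_tiled_into_units(self):
        """A 400-bp contig of a 120-bp monomer yields 3 full + 1 partial unit."""
        cons = random_monomer(120, seed=5)
        contig = (cons * 4)[:400]
        units = extract_units(contig, cons)
        assert [(u.start, u.end) for u in units] == [(0, 120), (120, 240), (240, 360), (360, 400)]
        assert [u.partial for u in units] == [False, False, False, True]

    def test_unrelated_contig_yields_nothing(self):
        cons = random_monomer(120, seed=5)
        contig = random_monomer(300, seed=99)
        assert extract_units(contig, cons) == []

    def test_reverse_complement_contig_strand_normalized(self):
        cons = random_monomer(120, seed=5)
        contig = reverse_complement(cons * 2)
        units = extract_units(contig, cons)
        assert len(units) == 2
        assert all(u.strand == "-" for u in units)
        assert all(u.sequence == cons for u in units)

    def test_diverged_copies_recovered(self):
        cons = random_monomer(120, seed=5)
        copies = [diverge(cons, 10, seed=i) for i in range(3)]  # ~92% identity
        units = extract_units("".join(copies), cons)
        assert len(units) == 3
        assert all(not u.partial for u in units)


# ---------------------------------------------------------------- merging
class TestMergeLengthVariants:
    @pytest.mark.parametrize(
        "frags,expected",
        [
            # overlap 8, overhang 2 = 20% of union(10) -> merged
            (["ACGTACGT", "ACGTACGTAA"], ["ACGTACGTAA"]),
            # overlap 4, overhangs 4 = 33% of union(12) -> merged
            (["AAAACCCC", "CCCCGGGG"], ["AAAACCCCGGGG"]),
            # overhang 12 = 60% of union(20) -> NOT merged
            (["AAAATTTT", "TTTTGGGGGGGGGGGG"], ["TTTTGGGGGGGGGGGG", "AAAATTTT"]),
        ],
    )
    def test_worked_examples(self, frags, expected):
        assert merge_length_variants(frags) == expected

    def test_mismatched_overlap_never_merged(self):
        # identical length, one internal mismatch: no exact overlap
        assert merge_pair("AACGTACG", "AACTTACG") is None

    def test_exact_duplicates_collapse(self):
        assert merge_length_variants(["ACGTACGTT", "ACGTACGTT"]) == ["ACGTACGTT"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_on_random_fragment_sets(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 120))))
        frags = []
        for _ in range(int(rng.integers(2, 8))):
            i = int(rng.integers(0, len(base) - 10))
            j = int(rng.integers(i + 10, len(base) + 1))
            frags.append(base[i:j])
        once = merge_length_variants(frags)
        assert merge_length_variants(once) == once
        assert len(once) <= len(frags)


def test_count_unique_matches_distinct_truth():
    ancestor, tree, params = concerted_scenario(seed=3)
    loci = evolve(ancestor, tree, params)
    units = [u for l in loci.values() for u in l.array.units]
    counts = count_unique(units)
    for sp, locus in loci.items():
        # same-length units: merging reduces to exact dedup
        assert counts[sp] == len(set(locus.array.sequences()))


def test_count_unique_empty_and_degenerate():
    assert count_unique([]) == {}
    us = [RepeatUnit(f"u{i}", "ACGTACGTACGT", species="melA") for i in range(10)]
    assert count_unique(us) == {"melA": 1}


# ---------------------------------------------------------------- consensus
class TestConsensus:
    def test_identical_inputs_full_support(self):
        prof = build_consensus(["ACGTACGT"] * 5)
        assert prof.consensus == "ACGTACGT"
        assert np.all(prof.support == 1.0)
        assert prof.n_sequences == 5

    def test_majority_column(self):
        prof = build_consensus(["ACGT", "ACGT", "ACTT"])
        assert prof.consensus == "ACGT"
        assert prof.support == pytest.approx([1, 1, 2 / 3, 1])

    def test_recovers_ancestor_from_diverged_copies(self):
        anc = random_monomer(120, seed=8)
        seqs = [diverge(anc, 4, seed=100 + i) for i in range(20)]  # ~3% divergence
        prof = build_consensus(seqs)
        assert len(prof.consensus) == 120
        mismatches = sum(1 for a, b in zip(prof.consensus, anc) if a != b)
        assert mismatches <= 2

    def test_center_star_rows_equal_length(self):
        seqs = [random_monomer(60, seed=i) for i in range(4)]
        rows = center_star_msa(seqs)
        assert len({len(r) for r in rows}) == 1
        for r, s in zip(rows, seqs):
            assert r.replace("-", "") == s


# ---------------------------------------------------------------- classification
class TestClassifyUnit:
    def setup_method(self):
        self.left = random_monomer(200, seed=11)
        self.right = diverge(self.left, 90, seed=12)  # far from Left

    def test_exact_left(self):
        assert classify_unit(self.left, self.left, self.right) == "Left"

    def test_variant_band(self):
        u = diverge(self.right, 30, seed=13)  # 85% to Right
        assert pairwise_identity(u, self.right) == 85.0
        assert classify_unit(u, self.left, self.right) == "variant"

    def test_family_divergent_band(self):
        u = diverge(self.left, 70, seed=14)  # 65% to Left
        label = classify_unit(u, self.left, self.right)
        assert label == "family-divergent"

    def test_boundaries_partition_exactly(self):
        at90 = diverge(self.left, 20, seed=15)  # exactly 90.0%
        assert pairwise_identity(at90, self.left) == 90.0
        assert classify_unit(at90, self.left, self.right) in ("Left", "Right")
        at795 = diverge(self.left, 41, seed=16)  # exactly 79.5%
        assert pairwise_identity(at795, self.left) == 79.5
        assert classify_unit(at795, self.left, self.right) == "variant"


# ---------------------------------------------------------------- dimer period
class TestDimerPeriod:
    def test_alternating_array_is_dimeric(self):
        left, right = dimer_seeds(0)
        arr = make_dimer_ancestor(left, right, 5)
        rep = detect_dimer_period(arr)
        assert rep.period == 2 and rep.dimeric
        assert rep.lag_identity[2] > rep.lag_identity[1] + 5

    def test_homogeneous_array_period_one(self):
        left, _ = dimer_seeds(0)
        arr = make_dimer_ancestor(left, left, 4)
        rep = detect_dimer_period(arr)
        assert rep.period == 1 and not rep.dimeric

    def test_too_few_units_is_error(self):
        left, right = dimer_seeds(0)
        arr = make_dimer_ancestor(left, right, 1)
        with pytest.raises(ValueError):
            detect_dimer_period(arr)

    def test_period_survives_substitution_drift(self):
        """Dimer structure is still called after mutation-only evolution."""
        from satevo.simulate import SimParams, SpeciesTreeSpec

        left, right = dimer_seeds(0)
        anc = make_dimer_ancestor(left, right, 8)
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            params = SimParams(mu=5e-5, uxo_rate=0.0, gc_rate=0.0, seed=seed)
            loci = evolve(anc, SpeciesTreeSpec("(A:300,B:300);"), params)
            rep = detect_dimer_period(loci["A"].array)
            hits += rep.period == 2 and rep.dimeric
        assert hits >= 0.9 * n_rep
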