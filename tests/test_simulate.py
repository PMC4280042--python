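"""Forward simulator: construction, event replay, determinism, emissions."""
import math

import numpy as np
import pytest

from satevo.align import pairwise_identity
from satevo.scenarios import concerted_scenario, dimer_seeds, jc_scenario, uniform_ancestor
from satevo.simulate import (
    SimParams,
    SpeciesTreeSpec,
    diverge,
    emit_collapsed_contigs,
    emit_reads,
    evolve,
    make_dimer_ancestor,
    random_monomer,
    replay_log,
    truth_table,
)


class TestDimerAncestor:
    def test_alternating_types(self):
        left, right = dimer_seeds(0)
        arr = make_dimer_ancestor(left, right, 3)
        assert len(arr) == 6
        assert [u.type_label for u in arr.units] == ["Left", "Right"] * 3

    def test_adjacent_identity_alternates(self):
        """Lag-1 neighbours sit at the seed divergence, lag-2 at 100 %."""
        left, right = dimer_seeds(0)
        arr = make_dimer_ancestor(left, right, 10)
        seqs = arr.sequences()
        lag1 = np.mean([pairwise_identity(a, b) for a, b in zip(seqs, seqs[1:])])
        lag2 = np.mean([pairwise_identity(a, b) for a, b in zip(seqs, seqs[2:])])
        assert lag2 == 100.0
        assert 80.0 <= lag1 <= 88.0  # seeds constructed at ~84 %

    def test_identical_seeds_degenerate(self):
        left, _ = dimer_seeds(0)
        arr = make_dimer_ancestor(left, left, 2)
        assert len({u.sequence for u in arr.units}) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_dimer_ancestor("", "ACGT" * 10, 2)
        with pytest.raises(ValueError):
            make_dimer_ancestor("A" * 100, "A" * 50, 2)


class TestEvolve:
    def test_zero_rates_arrays_unchanged(self):
        anc = uniform_ancestor(16, seed=1)
        params = SimParams(mu=0.0, uxo_rate=0.0, gc_rate=0.0, seed=4)
        loci = evolve(anc, SpeciesTreeSpec("((A:500,B:500):100,C:600);"), params)
        assert set(loci) == {"A", "B", "C"}
        for locus in loci.values():
            assert locus.array.sequences() == anc.sequences()
            assert all(e.kind == "speciation" for e in locus.event_log.events)

    def test_replay_reconstructs_leaf_exactly(self):
        for seed in (0, 1):
            anc, tree, params = concerted_scenario(seed=seed)
            loci = evolve(anc, tree, params)
            for locus in loci.values():
                assert replay_log(anc, locus.event_log) == locus.array.sequences()

    def test_seed_determinism_and_divergence(self):
        anc, tree, params = concerted_scenario(seed=7)
        a = evolve(anc, tree, params)
        b = evolve(anc, tree, params)
        assert {s: l.array.sequences() for s, l in a.items()} == {
            s: l.array.sequences() for s, l in b.items()
        }
        logs = set()
        for seed in range(10):
            anc, tree, params = concerted_scenario(seed=seed)
            loci = evolve(anc, tree, params)
            logs.add(tuple((e.kind, e.params) for e in loci["A"].event_log.events))
        assert len(logs) == 10  # different seeds, different histories

    def test_copy_number_stays_within_bounds(self):
        anc = uniform_ancestor(8, seed=1)
        params = SimParams(
            initial_copies=8, min_copies=4, max_copies=12,
            mu=1e-5, uxo_rate=0.5, uxo_offset_mean=3.0, gc_rate=0.1, seed=9,
        )
        loci = evolve(anc, SpeciesTreeSpec("(A:1500,B:1500);"), params)
        for locus in loci.values():
            assert 4 <= len(locus.array) <= 12
            # bounds hold along the whole trajectory, not just at the leaves
            state = [list(u.sequence) for u in anc.units]
            n = len(anc.units)
            for ev in locus.event_log.events:
                if ev.kind == "uxo":
                    k, j, keep_longer = ev.params
                    n = n + k if keep_longer else n - k
                    assert 4 <= n <= 12

    def test_jc_divergence_sanity(self):
        """Mutation-only divergence lands near the Jukes-Cantor expectation."""
        d = 0.2
        anc, tree, params = jc_scenario(d, seed=21)
        loci = evolve(anc, tree, params)
        a, b = loci["A"].array.sequences(), loci["B"].array.sequences()
        diffs = sum(
            sum(x != y for x, y in zip(sa, sb)) for sa, sb in zip(a, b)
        )
        sites = sum(len(s) for s in a)
        expected = 0.75 * (1 - math.exp(-4 * d / 3))
        assert diffs / sites == pytest.approx(expected, rel=0.25)  # single replicate

    def test_unknown_rate_multiplier_label(self):
        anc = uniform_ancestor(8, seed=1)
        params = SimParams(rate_multipliers={"nosuch": 5.0}, seed=0)
        with pytest.raises(ValueError):
            evolve(anc, SpeciesTreeSpec("(A:10,B:10);"), params)

    def test_truth_table_traceability(self):
        anc, tree, params = concerted_scenario(seed=2)
        loci = evolve(anc, tree, params)
        rows = truth_table(loci)
        assert len(rows) == sum(len(l.array) for l in loci.values())
        assert all(0 <= r["ancestor_monomer"] < len(anc) for r in rows)


class TestCollapsedContigs:
    def test_identical_units_single_contig(self):
        anc = uniform_ancestor(10, seed=1)
        params = SimParams(mu=0.0, uxo_rate=0.0, gc_rate=0.0, seed=0)
        loci = evolve(anc, SpeciesTreeSpec("(A:10,B:10);"), params)
        contigs = emit_collapsed_contigs(loci["A"], collapse_identity=99.0)
        assert len(contigs) == 1

    def test_two_families_two_contigs(self):
        left = random_monomer(120, seed=3)
        far = diverge(left, 24, seed=4)  # 80 % identity between families
        arr = make_dimer_ancestor(left, far, 3)
        params = SimParams(mu=0.0, uxo_rate=0.0, gc_rate=0.0, seed=0)
        loci = evolve(arr, SpeciesTreeSpec("(A:5,B:5);"), params)
        contigs = emit_collapsed_contigs(loci["A"], collapse_identity=95.0)
        assert len(contigs) == 2

    def test_no_collapse_at_full_identity_threshold(self):
        anc = uniform_ancestor(8, seed=1)
        params = SimParams(mu=5e-4, uxo_rate=0.0, gc_rate=0.0, seed=5)
        loci = evolve(anc, SpeciesTreeSpec("(A:300,B:300);"), params)
        seqs = loci["A"].array.sequences()
        assert len(set(seqs)) == len(seqs)  # all drifted apart
        contigs = emit_collapsed_contigs(loci["A"], collapse_identity=100.0)
        assert len(contigs) == len(seqs)


class TestReads:
    def _locus(self, n_units=16, seed=1):
        anc = uniform_ancestor(n_units, seed=seed)
        params = SimParams(mu=0.0, uxo_rate=0.0, gc_rate=0.0, seed=0)
        return evolve(anc, SpeciesTreeSpec("(A:5,B:5);"), params)["A"]

    def test_error_free_reads_are_substrings(self):
        locus = self._locus()
        template = locus.array.sequence
        reads = emit_reads(locus, read_length=100, coverage=30, error_rate=0.0, seed=3)
        assert all(seq in template for _, seq, _ in reads)

    def test_read_count_matches_coverage(self):
        locus = self._locus()
        L = len(locus.array.sequence)
        reads = emit_reads(locus, read_length=100, coverage=30, error_rate=0.0, seed=3)
        assert abs(len(reads) - 30 * L / 100) <= 1

    def test_error_rate_recovered(self):
        """Observed mismatch fraction ~ Binomial(error_rate) over >= 1e5 bases."""
        locus = self._locus(n_units=64, seed=2)
        template = locus.array.sequence
        reads = emit_reads(locus, read_length=100, coverage=15, error_rate=0.01, seed=4)
        mism = total = 0
        for name, seq, _ in reads:
            start = int(name.rsplit("_", 1)[1])
            ref = template[start:start + 100]
            mism += sum(a != b for a, b in zip(seq, ref))
            total += 100
        assert total >= 1e5
        assert abs(mism / total - 0.01) <= 0.002

    def test_quality_encodes_error_rate(self):
        locus = self._locus()
        reads = emit_reads(locus, read_length=50, coverage=2, error_rate=0.01, seed=5)
        assert all(q == chr(20 + 33) * 50 for _, _, q in reads)

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            emit_reads(self._locus(), read_length=50, coverage=0, error_rate=0.0, seed=1)
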