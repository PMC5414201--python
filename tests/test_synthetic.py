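"""Synthetic genome generation, planted mutations, and reference-scan tests."""

import numpy as np
import pytest

from kdisjoint import (
    DISJOINT,
    INTERSECTION,
    MutationPlan,
    SequenceRecord,
    brute_force_kdisjoint,
    disjoint_overlap_counts,
    generate_genome,
    inject_insertion,
    inject_inversion,
    inject_substitutions,
    min_hamming_per_window,
    recovered_sites,
    reverse_complement,
    sample_positions,
    write_fasta,
    write_plan_tsv,
)
from kdisjoint.synthetic import read_plan_tsv
from tests.conftest import letter_hamming, naive_min_hamming


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        assert generate_genome(100, 5).letters == generate_genome(100, 5).letters

    def test_different_seeds_differ(self):
        assert generate_genome(100, 5).letters != generate_genome(100, 6).letters

    def test_letter_frequencies_near_uniform(self):
        letters = generate_genome(100_000, 3).letters
        for base in "ACGT":
            assert abs(letters.count(base) / 100_000 - 0.25) < 0.01

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(0, 1)


class TestSamplePositions:
    def test_distinct_sorted_and_within_margin(self):
        pos = sample_positions(1000, 10, seed=4, margin=50, min_separation=20)
        assert pos == sorted(set(pos))
        assert all(51 <= p <= 950 for p in pos)
        assert all(b - a >= 20 for a, b in zip(pos, pos[1:]))

    def test_impossible_request_rejected(self):
        with pytest.raises(ValueError):
            sample_positions(10, 5, seed=0, margin=4)


class TestInjectSubstitutions:
    def test_transition_map_single_site(self):
        rec = SequenceRecord("r", "AAAA")
        mutated, plans = inject_substitutions(rec, [2])
        assert mutated.letters == "AGAA"
        assert [p.position for p in plans] == [2]

    def test_full_map_application(self):
        rec = SequenceRecord("r", "ACGT")
        mutated, _ = inject_substitutions(rec, [1, 2, 3, 4])
        assert mutated.letters == "GTAC"

    def test_hamming_equals_number_of_non_n_sites(self):
        rec = generate_genome(500, 17)
        positions = sample_positions(500, 12, seed=18)
        mutated, plans = inject_substitutions(rec, positions)
        assert letter_hamming(rec.letters, mutated.letters) == len(plans) == 12

    def test_n_site_skipped_with_warning(self, caplog):
        rec = SequenceRecord("r", "ANAA")
        with caplog.at_level("WARNING"):
            mutated, plans = inject_substitutions(rec, [2])
        assert mutated.letters == "ANAA"
        assert plans == []

    @pytest.mark.parametrize("positions", [[0], [5], [1, 1]])
    def test_invalid_positions_rejected(self, positions):
        with pytest.raises(ValueError):
            inject_substitutions(SequenceRecord("r", "ACGT"), positions)


class TestInjectInversion:
    def test_palindromic_segment_leaves_record_unchanged(self):
        rec = SequenceRecord("r", "TTACGTTT")
        mutated, plan = inject_inversion(rec, 3, 4)
        assert mutated.letters == rec.letters
        assert plan.span == (3, 6)

    def test_applying_twice_restores_original(self):
        rec = generate_genome(200, 23)
        once, _ = inject_inversion(rec, 50, 80)
        twice, _ = inject_inversion(once, 50, 80)
        assert twice.letters == rec.letters
        assert once.letters != rec.letters

    def test_poly_a_becomes_poly_t_in_place(self):
        rec = SequenceRecord("r", "CCAAAACC")
        mutated, _ = inject_inversion(rec, 3, 4)
        assert mutated.letters == "CCTTTTCC"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inject_inversion(SequenceRecord("r", "ACGT"), 3, 4)


class TestInjectInsertion:
    def test_unmutated_donor_appears_verbatim(self):
        rec = generate_genome(100, 31)
        donor = generate_genome(20, 32).letters
        mutated, plan = inject_insertion(rec, 41, donor, 0, seed=33)
        assert len(mutated) == 120
        assert mutated.letters[40:60] == donor
        assert plan.span == (41, 60)

    def test_flanks_preserved(self):
        rec = generate_genome(100, 31)
        donor = "ACGTACGTAC"
        mutated, _ = inject_insertion(rec, 51, donor, 0, seed=1)
        assert mutated.letters[:50] == rec.letters[:50]
        assert mutated.letters[60:] == rec.letters[50:]

    @pytest.mark.parametrize("n_mut", [0, 1, 2, 3])
    def test_spliced_donor_differs_in_exactly_n_positions(self, n_mut):
        rec = generate_genome(100, 41)
        donor = generate_genome(70, 42).letters
        mutated, plan = inject_insertion(rec, 31, donor, n_mut, seed=43)
        spliced = mutated.letters[30 : 30 + 70]
        assert letter_hamming(donor, spliced) == n_mut
        assert plan.detail == spliced

    def test_invalid_inputs_rejected(self):
        rec = SequenceRecord("r", "ACGT")
        with pytest.raises(ValueError):
            inject_insertion(rec, 6, "ACGT", 0, seed=0)
        with pytest.raises(ValueError):
            inject_insertion(rec, 1, "", 0, seed=0)
        with pytest.raises(ValueError):
            inject_insertion(rec, 1, "ACGT", 5, seed=0)


class TestBruteForce:
    def test_query_equals_taboo_is_all_intersection_at_k0(self):
        rec = generate_genome(100, 51, "g")
        calls = brute_force_kdisjoint([rec], [rec], 12, 0)
        assert len(calls) == 89
        assert all(c.label == INTERSECTION for c in calls)

    def test_empty_taboo_is_all_disjoint(self):
        rec = generate_genome(100, 51, "g")
        calls = brute_force_kdisjoint([rec], [], 12, 3)
        assert all(c.label == DISJOINT for c in calls)

    def test_taboo_records_shorter_than_w_ignored(self):
        rec = generate_genome(50, 52, "g")
        calls = brute_force_kdisjoint([rec], [SequenceRecord("t", "ACGT")], 12, 3)
        assert all(c.label == DISJOINT for c in calls)

    def test_vectorized_min_distance_matches_letter_loops(self):
        # dual route: the one-hot inner-product scan against literal loops
        query = generate_genome(80, 61, "q")
        taboo = [generate_genome(120, 62, "t1"), generate_genome(90, 63, "t2")]
        w = 12
        (mins,) = min_hamming_per_window([query], taboo, w)
        expected = naive_min_hamming(query.letters, [t.letters for t in taboo], w)
        assert mins.tolist() == expected

    def test_reverse_strand_is_searched(self):
        query = generate_genome(40, 71, "q")
        w = 20
        word = query.letters[5:25]
        taboo = [SequenceRecord("t", reverse_complement(word))]
        (mins,) = min_hamming_per_window([query], taboo, w)
        assert mins[5] == 0


class TestRecoveredSites:
    def test_isolated_substitution_recovered_by_w_windows(self):
        w = 30
        genome = generate_genome(5000, 81, "g")
        positions = sample_positions(5000, 1, seed=82, margin=w)
        mutated, plans = inject_substitutions(genome, positions)
        calls = brute_force_kdisjoint([mutated], [genome], w, 0)
        assert recovered_sites(calls, plans, w) == {("g", positions[0]): True}
        assert disjoint_overlap_counts(calls, plans[0], w) == w

    def test_substitution_at_position_one_recovered_by_single_window(self):
        w = 12
        genome = generate_genome(300, 83, "g")
        mutated, plans = inject_substitutions(genome, [1])
        calls = brute_force_kdisjoint([mutated], [genome], w, 0)
        assert disjoint_overlap_counts(calls, plans[0], w) == 1
        assert recovered_sites(calls, plans, w)[("g", 1)]

    def test_unmutated_control_has_no_disjoint_windows(self):
        genome = generate_genome(300, 84, "g")
        calls = brute_force_kdisjoint([genome], [genome], 12, 0)
        plan = MutationPlan("substitution", "g", 100, 1)
        assert disjoint_overlap_counts(calls, plan, 12) == 0
        assert recovered_sites(calls, plan, 12) == {("g", 100): False}


class TestFixtureFiles:
    def test_fasta_round_trip(self, tmp_path):
        from kdisjoint import read_fasta_dir

        records = [generate_genome(157, 91, "a"), generate_genome(80, 92, "b")]
        write_fasta(records, tmp_path / "x.fa")
        back = read_fasta_dir(tmp_path)
        assert [(r.record_id, r.letters) for r in back] == [
            (r.record_id, r.letters) for r in records
        ]

    def test_plan_tsv_round_trip(self, tmp_path):
        plans = [
            MutationPlan("substitution", "g", 17, 1, "A>G"),
            MutationPlan("insertion", "g", 40, 70, "ACGT" * 17 + "AC"),
        ]
        path = write_plan_tsv(plans, tmp_path / "plan.tsv")
        assert read_plan_tsv(path) == plans
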