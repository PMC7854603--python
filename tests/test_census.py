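"""Family classification, census, thinning, logo and proximity tests."""

import math

import numpy as np
import pytest

from samlink.dntpase_census import (
    AnnotatedSequence,
    ChromosomeRecord,
    ClassificationResult,
    DeflineError,
    build_profile,
    calibrate_evalue,
    census_counts,
    compute_logo,
    annotate_proximity,
    fit_gumbel,
    flag_truncated,
    map_structure_to_alignment,
    pairwise_identity,
    parse_defline,
    format_defline,
    read_fasta,
    score_and_classify,
    score_profile_local,
    thin_by_identity,
    write_fasta,
)
from samlink.synthetic_data import GeneratorConfig, gen_toy_structure

from oracles import greedy_thin_bruteforce, proximity_bruteforce


def _seq(acc, sequence, nuc="NC_000001.1", tax=("Bacteria", "Firmicutes")):
    return AnnotatedSequence(
        protein_acc=acc, nucleotide_acc=nuc, taxonomy=list(tax), sequence=sequence
    )


class TestDeflines:
    def test_three_field_parse(self):
        acc, nuc, tax = parse_defline(
            "WP_000001.1|NC_000001.1|Bacteria;Firmicutes;Bacilli"
        )
        assert acc == "WP_000001.1"
        assert nuc == "NC_000001.1"
        assert tax == ["Bacteria", "Firmicutes", "Bacilli"]

    def test_write_then_parse_round_trip(self, tmp_path):
        seqs = [_seq("WP_1.1", "ACDEFGHIKLMNPQRSTVWY" * 2)]
        path = tmp_path / "x.fasta"
        write_fasta(seqs, path)
        back = read_fasta(path)
        assert back[0].protein_acc == seqs[0].protein_acc
        assert back[0].taxonomy == seqs[0].taxonomy
        assert back[0].sequence == seqs[0].sequence

    def test_missing_nucleotide_accession_is_error(self):
        with pytest.raises(DeflineError):
            parse_defline("WP_000001.1|Bacteria;Firmicutes")

    def test_permissive_mode_tolerates_missing_fields(self):
        acc, nuc, tax = parse_defline("WP_000001.1", strict=False)
        assert acc == "WP_000001.1" and nuc == "" and tax == []


class TestProfiles:
    def test_conserved_column_log_odds_hand_value(self):
        # 10 x 'H', pseudocount 0.5, uniform background:
        # log2(((10 + 0.5) / (10 + 10)) / 0.05) = 3.392 bits
        prof = build_profile(["H"] * 10)
        h = prof.log_odds[0]["ACDEFGHIKLMNPQRSTVWY".index("H")]
        assert h == pytest.approx(math.log2((10.5 / 20.0) / 0.05), abs=1e-9)

    def test_uniform_column_has_zero_log_odds(self):
        prof = build_profile(list("ACDEFGHIKLMNPQRSTVWY"))
        assert np.allclose(prof.log_odds, 0.0, atol=1e-12)

    def test_single_sequence_profile_length(self):
        assert build_profile(["ACD"]).length == 3

    def test_gap_majority_columns_excluded(self):
        prof = build_profile(["A-C", "A-C", "AGC"])
        assert prof.length == 2
        assert prof.excluded_columns == [1]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])


class TestEvalueCalibration:
    def test_gumbel_lambda_recovered_from_known_distribution(self):
        from scipy.stats import gumbel_r

        lam_true = 0.3
        rng = np.random.default_rng(0)
        scores = gumbel_r.rvs(loc=10.0, scale=1.0 / lam_true, size=500,
                              random_state=rng)
        lam, mu = fit_gumbel(scores)
        assert lam == pytest.approx(lam_true, rel=0.10)
        assert mu == pytest.approx(10.0, abs=0.5)

    def test_evalue_monotone_decreasing_in_score(self, calibrated_profiles):
        pa, _ = calibrated_profiles
        assert pa.log10_evalue(10.0) > pa.log10_evalue(50.0)

    def test_same_seed_same_calibration(self, family_dataset):
        sequences, _, truth = family_dataset
        rows = [
            s.sequence
            for s in sequences
            if truth["labels"][s.protein_acc] == "family_a"
            and not truth["truncated"][s.protein_acc]
        ][:5]
        p1 = calibrate_evalue(build_profile(rows), n_shuffles=120, seed=3)
        p2 = calibrate_evalue(build_profile(rows), n_shuffles=120, seed=3)
        assert p1.gumbel_lambda == p2.gumbel_lambda
        assert p1.gumbel_k == p2.gumbel_k

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.full(200, 5.0))

    def test_too_few_shuffles_rejected(self, calibrated_profiles):
        pa, _ = calibrated_profiles
        with pytest.raises(ValueError):
            calibrate_evalue(pa, n_shuffles=50)


class TestClassification:
    def test_majority_of_members_confidently_labeled(
        self, family_dataset, calibrated_profiles
    ):
        sequences, _, truth = family_dataset
        pa, pb = calibrated_profiles
        correct = 0
        for s in sequences:
            r = score_and_classify(s, pa, pb)
            if r.label != "ambiguous" and r.label == truth["labels"][s.protein_acc]:
                correct += 1
        assert correct >= 0.95 * len(sequences)

    def test_identical_profiles_are_ambiguous(self, calibrated_profiles):
        pa, _ = calibrated_profiles
        seq = _seq("WP_X.1", "ACDEFGHIKLMNPQRSTVWY" * 3)
        r = score_and_classify(seq, pa, pa)
        assert r.margin == 0.0
        assert r.label == "ambiguous"

    def test_label_symmetry_under_profile_swap(
        self, family_dataset, calibrated_profiles
    ):
        sequences, _, _ = family_dataset
        pa, pb = calibrated_profiles
        for s in sequences[:6]:
            fwd = score_and_classify(s, pa, pb)
            rev = score_and_classify(s, pb, pa)
            assert fwd.margin == pytest.approx(rev.margin, rel=1e-12)
            swap = {"family_a": "family_b", "family_b": "family_a",
                    "ambiguous": "ambiguous"}
            assert rev.label == swap[fwd.label]

    def test_short_sequence_rejected(self, calibrated_profiles):
        pa, pb = calibrated_profiles
        with pytest.raises(ValueError, match="shorter"):
            score_and_classify(_seq("WP_S.1", "ACDEFGHIKL"), pa, pb)

    def test_uncalibrated_profiles_rejected(self, family_dataset):
        sequences, _, _ = family_dataset
        prof = build_profile([sequences[0].sequence])
        with pytest.raises(ValueError, match="calibrated"):
            score_and_classify(sequences[0], prof, prof)


class TestTruncationFlag:
    def test_full_length_member_not_flagged(
        self, family_dataset, calibrated_profiles
    ):
        sequences, _, truth = family_dataset
        pa, pb = calibrated_profiles
        full = next(
            s for s in sequences if not truth["truncated"][s.protein_acc]
        )
        r = score_and_classify(full, pa, pb)
        assert flag_truncated(r) is False

    def test_half_deleted_member_flagged(self, family_dataset, calibrated_profiles):
        sequences, _, truth = family_dataset
        pa, pb = calibrated_profiles
        full = next(
            s for s in sequences
            if truth["labels"][s.protein_acc] == "family_a"
            and not truth["truncated"][s.protein_acc]
        )
        frag = _seq("WP_FRAG.1", full.sequence[len(full.sequence) // 2:])
        r = score_and_classify(frag, pa, pb)
        assert flag_truncated(r) is True
        assert r.coverage == pytest.approx(0.5, abs=0.1)

    def test_boundary_is_strict_less_than(self):
        r = ClassificationResult(
            protein_acc="X", score_a=1, score_b=0, log10_e_a=-30, log10_e_b=0,
            margin=30, label="family_a", coverage=0.7,
        )
        assert flag_truncated(r, min_coverage=0.7) is False


class TestCensus:
    def _result(self, acc, label="family_a"):
        return ClassificationResult(
            protein_acc=acc, score_a=0, score_b=0, log10_e_a=0, log10_e_b=0,
            margin=30, label=label, coverage=1.0,
        )

    def test_empty_inputs_give_empty_table(self):
        census, copies = census_counts([], [], [], level=1)
        assert census.empty
        assert copies["n_chromosomes"].sum() == 0

    def test_hand_enumerated_toy_fixture(self):
        # chromosomes: two 250 kb circular (kept), one 150 kb circular
        # (dropped); proteins 2 + 1 + 1 -> counts 2 + 1, chromosome count 2
        chroms = [
            ChromosomeRecord("NC_1.1", 250_000, "circular"),
            ChromosomeRecord("NC_2.1", 250_000, "circular"),
            ChromosomeRecord("NC_3.1", 150_000, "circular"),
        ]
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [
            _seq("P1", aa, "NC_1.1"), _seq("P2", aa, "NC_1.1"),
            _seq("P3", aa, "NC_2.1", tax=("Bacteria", "Proteobacteria")),
            _seq("P4", aa, "NC_3.1"),
        ]
        results = [
            self._result("P1"), self._result("P2"),
            self._result("P3", "family_b"), self._result("P4"),
        ]
        census, copies = census_counts(results, seqs, chroms, level=2)
        assert census["n_chromosomes"].sum() == 2
        firm = census.set_index("taxon").loc["Firmicutes"]
        assert firm["n_family_a"] == 2 and firm["n_family_b"] == 0
        prot = census.set_index("taxon").loc["Proteobacteria"]
        assert prot["n_family_b"] == 1
        # P4 sits on the dropped chromosome: total classified = 3
        assert census[["n_family_a", "n_family_b"]].to_numpy().sum() == 3
        by_copies = copies.set_index("copies")["n_chromosomes"]
        assert by_copies["2"] == 1 and by_copies["1"] == 1

    def test_linear_chromosome_contributes_nothing(self):
        chroms = [ChromosomeRecord("NC_9.1", 5_000_000, "linear")]
        seqs = [_seq("P1", "ACDEFGHIKLMNPQRSTVWY", "NC_9.1")]
        census, copies = census_counts([self._result("P1")], seqs, chroms, level=1)
        assert census.empty or census[["n_family_a", "n_family_b"]].to_numpy().sum() == 0
        assert copies["n_chromosomes"].sum() == 0

    def test_count_conservation_on_default_dataset(self, family_dataset):
        sequences, chromosomes, truth = family_dataset
        kept = {c.nucleotide_acc for c in chromosomes if c.passes_census_filter}
        results = [
            self._result(s.protein_acc, truth["labels"][s.protein_acc])
            for s in sequences
        ]
        census, _ = census_counts(results, sequences, chromosomes, level=2)
        counted = census[["n_family_a", "n_family_b", "n_ambiguous"]].to_numpy().sum()
        expected = sum(1 for s in sequences if s.nucleotide_acc in kept)
        assert counted == expected

    def test_excessive_level_rejected(self, family_dataset):
        sequences, chromosomes, _ = family_dataset
        with pytest.raises(ValueError, match="level"):
            census_counts([], sequences, chromosomes, level=10)


class TestIdentityAndThinning:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0

    def test_single_mismatch_hand_value(self):
        assert pairwise_identity("ACDEFG", "ACDEFH") == pytest.approx(5 / 6)

    def test_disjoint_alphabets_zero(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetry(self):
        a, b = "ACDEFGHIKLMNP", "ACDEFGWIKLMNP"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    def test_all_identical_collapse_to_one(self):
        seqs = [_seq(f"P{i}", "ACDEFGHIKLMNPQRSTVWY") for i in range(10)]
        reps, assignment = thin_by_identity(seqs)
        assert len(reps) == 1
        assert set(assignment.values()) == {reps[0].protein_acc}

    def test_all_distant_all_representatives(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = [
            _seq(f"P{i}", "".join(rng.choice(aas, 50))) for i in range(8)
        ]
        reps, _ = thin_by_identity(seqs)
        assert len(reps) == len(seqs)

    def test_duplicate_insertion_never_adds_representative(self):
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = [_seq(f"P{i}", "".join(rng.choice(aas, 60))) for i in range(5)]
        reps, _ = thin_by_identity(seqs)
        dup = _seq("P9", seqs[0].sequence)
        reps2, assignment2 = thin_by_identity(seqs + [dup])
        assert len(reps2) == len(reps)
        assert assignment2["P9"] == "P0"

    def test_matches_bruteforce_on_random_families(self, family_dataset):
        sequences, _, _ = family_dataset
        rng = np.random.default_rng(7)
        pick = [sequences[i] for i in rng.choice(len(sequences), 15, replace=False)]
        reps, assignment = thin_by_identity(pick, threshold=0.70)
        reps_bf, assignment_bf = greedy_thin_bruteforce(
            pick, pairwise_identity, 0.70
        )
        assert [r.protein_acc for r in reps] == [r.protein_acc for r in reps_bf]
        assert assignment == assignment_bf
        rep_by_acc = {r.protein_acc: r for r in reps}
        for seq in pick:
            home = rep_by_acc[assignment[seq.protein_acc]]
            if home.protein_acc != seq.protein_acc:
                assert pairwise_identity(seq.sequence, home.sequence) >= 0.70


class TestLogo:
    def test_fully_conserved_column_reaches_max_bits(self):
        lm = compute_logo(["A", "A", "A"])
        assert lm.information[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_is_uninformative(self):
        lm = compute_logo(list("ACDEFGHIKLMNPQRSTVWY"))
        assert lm.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_column_entropy_by_hand(self):
        lm = compute_logo(["A", "A", "C", "C"])
        assert lm.information[0] == pytest.approx(math.log2(20) - 1.0, abs=1e-12)

    def test_all_gap_column(self):
        lm = compute_logo(["A-", "A-"])
        assert lm.information[1] == 0.0
        assert lm.occupancy[1] == 0.0

    def test_heights_sum_to_ic_times_occupancy(self):
        lm = compute_logo(["AC-D", "ACCD", "AC-D", "GCFD"])
        assert np.allclose(
            lm.heights.sum(axis=1), lm.information * lm.occupancy, atol=1e-12
        )
        assert (lm.heights >= 0).all()
        assert (lm.information <= math.log2(20) + 1e-12).all()

    def test_small_sample_correction_floors_at_zero(self):
        lm = compute_logo(["A", "C"], corrections="small_sample")
        assert lm.information[0] >= 0.0


class TestProximity:
    def test_matches_bruteforce_oracle(self, config):
        atoms, truth = gen_toy_structure(config)
        sel = truth["ligands"]
        assert annotate_proximity(atoms, sel) == proximity_bruteforce(atoms, sel)

    def test_generated_truth_is_recovered(self, config):
        atoms, truth = gen_toy_structure(config)
        assert annotate_proximity(atoms, truth["ligands"]) == truth["contacts"]

    def test_far_ligand_yields_empty_set(self, config):
        atoms, truth = gen_toy_structure(config, far_ligand=True)
        res = annotate_proximity(atoms, truth["ligands"])
        assert res["allosteric"] == []

    def test_exact_cutoff_boundary_is_inclusive(self):
        import biotite.structure as struc

        arr = struc.AtomArray(2)
        arr.coord = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        arr.res_id = np.array([1, 2])
        arr.res_name = np.array(["ALA", "LIG"])
        arr.atom_name = np.array(["CA", "P1"])
        arr.element = np.array(["C", "P"])
        arr.hetero = np.array([False, True])
        arr.chain_id = np.array(["A", "A"])
        res = annotate_proximity(arr, {"g": ["LIG"]}, cutoff=5.0)
        assert res["g"] == [1]

    def test_empty_selection_rejected(self, config):
        atoms, _ = gen_toy_structure(config)
        with pytest.raises(ValueError, match="matched nothing"):
            annotate_proximity(atoms, {"g": ["ZZZ"]})


class TestStructureMapping:
    def test_identity_mapping(self):
        row = "ACDEFGHIKLMNPQRSTVWY"
        mapping, best, unmapped = map_structure_to_alignment(row, [row, "W" * 20])
        assert best == 0 and not unmapped
        assert all(mapping[i + 1] == i for i in range(20))

    def test_internal_deletion_skips_columns(self):
        mapping, _, _ = map_structure_to_alignment(
            "ACDEFGHIKLPQRSTVWY", ["ACDEFGHIKL-MNPQRSTVWY"]
        )
        assert mapping[10] == 9
        assert mapping[11] == 13  # jumps over the gap and the deleted MN

    def test_scrambled_sequence_fails(self):
        with pytest.raises(ValueError, match="mapping failed"):
            map_structure_to_alignment("AAAA" * 10, ["CDEF" * 10])
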