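"""Profile HMM construction, scoring and scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsdmkit.align import MultipleAlignment
from gsdmkit.hmm import (
    HmmError,
    ProfileHmm,
    assign_match_columns,
    build_profile,
    consensus,
    forward,
    scan_proteins,
    six_frame_orfs,
    six_frame_scan,
    viterbi,
)
from gsdmkit.records import AMINO_ACIDS, ProteinRecord
from gsdmkit.synthetic import (
    CladeSpec,
    SimulationConfig,
    back_translate,
    generate_dataset,
    make_contig,
)

from oracles import brute_force_forward, brute_force_viterbi

AA = list(AMINO_ACIDS)


@pytest.fixture(scope="module")
def toy_hmm():
    """Small 4-state profile from a 3-row alignment with a gap and an insert."""
    msa = MultipleAlignment(
        ["r1", "r2", "r3"],
        ["MKVD", "MK-D", "MKVD"],
    )
    return build_profile(msa)


class TestMatchColumns:
    def test_ungapped_msa_keeps_all_columns(self):
        msa = MultipleAlignment(["a", "b"], ["MKV", "MKV"])
        assert assign_match_columns(msa, 0.5) == [0, 1, 2]

    def test_majority_gap_column_excluded(self):
        msa = MultipleAlignment(["a", "b", "c", "d"], ["M-", "M-", "M-", "MK"])
        assert assign_match_columns(msa, 0.5) == [0]

    def test_mixed_msa_matches_hand_counts(self):
        # gap fractions: col0 0/3, col1 2/3 (excluded), col2 1/3
        msa = MultipleAlignment(["a", "b", "c"], ["MKV", "M-V", "M--"])
        assert assign_match_columns(msa, 0.5) == [0, 2]

    def test_all_columns_gappy_is_an_error(self):
        msa = MultipleAlignment(["a", "b", "c"], ["M--", "-K-", "--V"])
        with pytest.raises(HmmError):
            assign_match_columns(msa, 0.5)


class TestBuildProfile:
    def test_identical_rows_small_pseudocount_approaches_indicator(self):
        msa = MultipleAlignment([f"r{i}" for i in range(5)], ["MKVD"] * 5)
        profile = build_profile(msa, pseudocount=1e-9)
        for state, residue in enumerate("MKVD"):
            assert profile.match_emissions[state, AA.index(residue)] == pytest.approx(
                1.0, abs=1e-6
            )

    def test_single_row_gives_one_state_per_residue(self):
        msa = MultipleAlignment(["only"], ["MKVLQ"])
        assert build_profile(msa).n_match == 5

    def test_three_row_emission_arithmetic(self):
        # column 1: two M, one K; pseudocount 1 with uniform background:
        # P(M) = (2 + 1/20) / (3 + 1)
        msa = MultipleAlignment(["a", "b", "c"], ["MKVD", "KKVD", "MKVD"])
        profile = build_profile(msa, pseudocount=1.0)
        assert profile.match_emissions[0, AA.index("M")] == pytest.approx(
            (2 + 1 / 20) / 4
        )
        assert profile.match_emissions[0, AA.index("K")] == pytest.approx(
            (1 + 1 / 20) / 4
        )

    def test_probability_vectors_normalized(self, toy_hmm):
        assert np.allclose(toy_hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(
            toy_hmm.t_mm + toy_hmm.t_mi + toy_hmm.t_md, 1.0, atol=1e-9
        )


class TestConsensus:
    def test_identical_rows_reproduce_sequence(self):
        msa = MultipleAlignment(["a", "b"], ["MKVD", "MKVD"])
        assert consensus(build_profile(msa)) == "MKVD"

    def test_length_equals_n_match(self, toy_hmm):
        assert len(consensus(toy_hmm)) == toy_hmm.n_match

    def test_majority_residue_wins(self):
        msa = MultipleAlignment(["a", "b", "c"], ["MKVD", "KKVD", "MKVD"])
        assert consensus(build_profile(msa)) == "MKVD"


class TestViterbiForward:
    def test_consensus_scores_positive(self, toy_hmm):
        bits, _path = viterbi(consensus(toy_hmm), toy_hmm)
        assert bits > 0

    def test_deterministic_across_calls(self, toy_hmm):
        seq = "AMKVDA"
        assert viterbi(seq, toy_hmm) == viterbi(seq, toy_hmm)

    @pytest.mark.parametrize("seq", ["MKV", "MKVD", "AMK", "DDD", "MKXD"])
    def test_viterbi_equals_path_enumeration(self, toy_hmm, seq):
        bits, _path = viterbi(seq, toy_hmm)
        assert bits == pytest.approx(brute_force_viterbi(seq, toy_hmm))

    @pytest.mark.parametrize("seq", ["MKV", "MKVD", "AMK", "DDD"])
    def test_forward_equals_path_enumeration(self, toy_hmm, seq):
        assert forward(seq, toy_hmm) == pytest.approx(brute_force_forward(seq, toy_hmm))

    @settings(max_examples=30, deadline=None)
    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=8))
    def test_forward_at_least_viterbi(self, toy_hmm, seq):
        bits, _path = viterbi(seq, toy_hmm)
        assert forward(seq, toy_hmm) >= bits - 1e-9

    def test_single_path_model_forward_equals_viterbi(self):
        # one match state, one residue: exactly one path through the model
        msa = MultipleAlignment(["only"], ["M"])
        profile = build_profile(msa, pseudocount=1e-9)
        bits, _ = viterbi("M", profile)
        assert forward("M", profile) == pytest.approx(bits, abs=1e-12)


@pytest.fixture(scope="module")
def family():
    config = SimulationConfig(
        seed=11,
        clades=[CladeSpec("bird", 8, "YVAD", 1.0)],
        nterm_length=60,
        linker_length_range=(10, 18),
        cterm_length=50,
        n_decoys=12,
        decoy_length_range=(80, 160),
        include_orthologs=False,
    )
    return generate_dataset(config)


class TestScanning:
    def test_family_separates_from_decoys(self, family):
        from gsdmkit.align import progressive_align

        records, truth = family
        members = [r for r in records if r.id in truth.family_ids]
        decoys = [r for r in records if r.id not in truth.family_ids]
        profile = build_profile(progressive_align(members))
        member_hits = scan_proteins(profile, members, bits_threshold=20.0)
        decoy_hits = scan_proteins(profile, decoys, bits_threshold=20.0)
        assert len(member_hits) == len(members)
        assert decoy_hits == []

    def test_empty_record_list(self, toy_hmm):
        assert scan_proteins(toy_hmm, []) == []

    def test_member_scores_exceed_decoy_scores_across_seeds(self):
        """Mean family bits beat mean decoy bits in every one of 20 seeds."""
        from gsdmkit.align import progressive_align

        for seed in range(20):
            config = SimulationConfig(
                seed=seed,
                clades=[CladeSpec("bird", 6, "YVAD", 1.0)],
                nterm_length=50,
                linker_length_range=(8, 14),
                cterm_length=40,
                n_decoys=6,
                decoy_length_range=(60, 120),
                include_orthologs=False,
            )
            records, truth = generate_dataset(config)
            members = [r for r in records if r.id in truth.family_ids]
            decoys = [r for r in records if r.id not in truth.family_ids]
            profile = build_profile(progressive_align(members))
            mean_member = np.mean([viterbi(r.sequence, profile)[0] for r in members])
            mean_decoy = np.mean([viterbi(r.sequence, profile)[0] for r in decoys])
            assert mean_member > mean_decoy

    def test_shuffled_member_scores_below_itself(self, family, nprng):
        from gsdmkit.align import progressive_align

        records, truth = family
        members = [r for r in records if r.id in truth.family_ids]
        profile = build_profile(progressive_align(members))
        target = members[0]
        shuffled = "".join(nprng.permutation(list(target.sequence)))
        original_bits, _ = viterbi(target.sequence, profile)
        shuffled_bits, _ = viterbi(shuffled, profile)
        assert shuffled_bits < original_bits


class TestSixFrameScan:
    def test_planted_frame_recovered(self, toy_hmm, nprng):
        member = ProteinRecord("m", "MKVD" * 10)
        contig = make_contig(member, 2, nprng, pad_range=(12, 30))
        hits = six_frame_scan("c1", contig, toy_hmm, min_orf_aa=10, bits_threshold=1.0)
        assert hits and hits[0].frame == 2

    def test_all_n_contig_has_no_hits(self, toy_hmm):
        assert six_frame_scan("c", "N" * 300, toy_hmm, min_orf_aa=5) == []

    def test_reverse_complement_negates_frames(self, toy_hmm, nprng):
        from Bio.Seq import Seq

        member = ProteinRecord("m", "MKVD" * 10)
        contig = make_contig(member, 1, nprng, pad_range=(12, 30))
        rc = str(Seq(contig).reverse_complement())
        fwd = six_frame_scan("c", contig, toy_hmm, min_orf_aa=10, bits_threshold=1.0)
        rev = six_frame_scan("c", rc, toy_hmm, min_orf_aa=10, bits_threshold=1.0)
        assert {(h.bit_score, h.start, h.end) for h in fwd} == {
            (h.bit_score, h.start, h.end) for h in rev
        }
        assert {-h.frame for h in fwd} == {h.frame for h in rev}

    def test_non_nucleotide_character_rejected(self, toy_hmm):
        with pytest.raises(HmmError):
            six_frame_scan("c", "ACGU", toy_hmm)

    def test_back_translation_round_trips(self):
        protein = "MKVDWYACDEFGHILNPQRSTV"
        from Bio.Seq import Seq

        assert str(Seq(back_translate(protein)).translate()) == protein


class TestSerialization:
    def test_json_round_trip(self, toy_hmm, tmp_path):
        path = tmp_path / "profile.json"
        toy_hmm.to_json(path)
        loaded = ProfileHmm.from_json(path)
        assert loaded.n_match == toy_hmm.n_match
        assert np.allclose(loaded.match_emissions, toy_hmm.match_emissions)
        bits_a, _ = viterbi("MKVD", toy_hmm)
        bits_b, _ = viterbi("MKVD", loaded)
        assert bits_a == pytest.approx(bits_b)


class TestPyhmmerCrossCheck:
    def test_family_decoy_ranking_agrees_with_pyhmmer(self, family=None):
        """Both implementations must rank every family member above every decoy."""
        import pyhmmer
        from gsdmkit.align import progressive_align

        config = SimulationConfig(
            seed=5,
            nterm_length=60,
            linker_length_range=(10, 18),
            cterm_length=50,
            n_decoys=8,
            decoy_length_range=(80, 160),
            include_orthologs=False,
        )
        records, truth = generate_dataset(config)
        members = [r for r in records if r.id in truth.family_ids][:10]
        decoys = [r for r in records if r.id not in truth.family_ids]
        msa = progressive_align(members)

        alphabet = pyhmmer.easel.Alphabet.amino()
        digital = pyhmmer.easel.TextMSA(
            name=b"fam",
            sequences=[
                pyhmmer.easel.TextSequence(name=rid.encode(), sequence=row)
                for rid, row in zip(msa.row_ids, msa.rows)
            ],
        ).digitize(alphabet)
        builder = pyhmmer.plan7.Builder(alphabet)
        background = pyhmmer.plan7.Background(alphabet)
        hmm_ref, _, _ = builder.build_msa(digital, background)
        pipeline = pyhmmer.plan7.Pipeline(alphabet, background=background, bias_filter=False, F1=1.0, F2=1.0, F3=1.0)
        targets = pyhmmer.easel.TextSequenceBlock(
            [
                pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.sequence)
                for r in members + decoys
            ]
        ).digitize(alphabet)
        top = pipeline.search_hmm(hmm_ref, targets)
        ref_scores = {
            (hit.name.decode() if isinstance(hit.name, bytes) else hit.name): hit.score
            for hit in top
        }

        profile = build_profile(msa)
        ours = {r.id: viterbi(r.sequence, profile)[0] for r in members + decoys}
        member_ids = {r.id for r in members}
        # pyhmmer may drop decoys entirely (no reportable hit): treat as -inf
        ref_min_member = min(ref_scores[m] for m in member_ids)
        ref_max_decoy = max(
            (s for n, s in ref_scores.items() if n not in member_ids), default=-1e9
        )
        assert ref_min_member > ref_max_decoy
        assert min(ours[m] for m in member_ids) > max(
            ours[d.id] for d in decoys
        )
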