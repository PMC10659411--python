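"""Linker projection, tetrapeptide extraction/classification, logos, hydropathy."""

import itertools
import math

import numpy as np
import pytest

from gsdmkit.align import MultipleAlignment
from gsdmkit.motifs import (
    CASPASE1_LIKE,
    CASPASE3_LIKE,
    KYTE_DOOLITTLE,
    OTHER_ASP,
    LinkerAnnotation,
    MotifError,
    ReferenceBoundaries,
    TetrapeptideSite,
    build_logo,
    clade_summary,
    classify_site,
    find_tetrapeptide_sites,
    hydropathy_profile,
    is_yvad_like,
    project_boundaries,
    read_boundaries_yaml,
    scan_caspase3_nterm,
    write_boundaries_yaml,
    yvad_similarity,
)
from gsdmkit.records import AMINO_ACIDS, ProteinRecord


def make_site(tetra, p1=10, p1p="X", p2p="X"):
    return TetrapeptideSite("s", tetra, p1, p1_prime=p1p, p2_prime=p2p)


class TestProjectBoundaries:
    def test_identity_projection(self):
        rows = ["MKVLQACDEFGH"] * 3
        msa = MultipleAlignment(["ref", "b", "c"], rows)
        ref = ReferenceBoundaries("ref", beta11_end=4, alpha5_start=9)
        linkers = project_boundaries(msa, ref)
        for annotation in linkers.values():
            assert (annotation.start, annotation.end) == (5, 8)

    def test_insertion_lengthens_linker(self):
        msa = MultipleAlignment(
            ["ref", "ins"],
            ["MKVLQAC-----DEFGH", "MKVLQACWWWWWDEFGH"],
        )
        ref = ReferenceBoundaries("ref", beta11_end=4, alpha5_start=9)
        linkers = project_boundaries(msa, ref)
        assert linkers["ref"].end - linkers["ref"].start + 1 == 4
        assert linkers["ins"].end - linkers["ins"].start + 1 == 9

    def test_empty_window_yields_null_annotation(self):
        msa = MultipleAlignment(
            ["ref", "gappy"],
            ["MKVLQACD", "MKVL---D"],
        )
        ref = ReferenceBoundaries("ref", beta11_end=4, alpha5_start=8)
        linkers = project_boundaries(msa, ref)
        assert linkers["gappy"] is None

    def test_missing_reference_is_an_error(self):
        msa = MultipleAlignment(["a"], ["MKVLQACD"])
        ref = ReferenceBoundaries("zzz", beta11_end=2, alpha5_start=5)
        with pytest.raises(MotifError, match="zzz"):
            project_boundaries(msa, ref)


class TestFindSites:
    def test_linker_without_aspartate_gives_no_sites(self):
        record = ProteinRecord("s", "MKVLAAAAWXYZ".replace("X", "C").replace("Z", "E"))
        linker = LinkerAnnotation("s", 5, 8)
        assert find_tetrapeptide_sites(record, linker) == []

    def test_fasd_site_with_gp_context(self):
        #             123456789...        linker covers FASD + GP
        record = ProteinRecord("s", "MKVLQFASDGPACDEF")
        linker = LinkerAnnotation("s", 6, 11)
        (site,) = find_tetrapeptide_sites(record, linker)
        assert site.tetrapeptide == "FASD"
        assert site.p1_position == 9
        assert (site.p1_prime, site.p2_prime) == ("G", "P")

    def test_multiple_aspartates_multiple_sites(self):
        record = ProteinRecord("s", "MKVLDAADAAQQQQ")
        linker = LinkerAnnotation("s", 5, 10)
        sites = find_tetrapeptide_sites(record, linker)
        assert [s.p1_position for s in sites] == [5, 8]

    def test_nterm_aspartate_padded_with_x(self):
        record = ProteinRecord("s", "MDKVLQAC")
        linker = LinkerAnnotation("s", 1, 4)
        (site,) = find_tetrapeptide_sites(record, linker)
        assert site.tetrapeptide == "XXMD"

    def test_cterm_site_context_is_x(self):
        record = ProteinRecord("s", "MKVLFASD")
        linker = LinkerAnnotation("s", 5, 8)
        (site,) = find_tetrapeptide_sites(record, linker)
        assert (site.p1_prime, site.p2_prime) == ("X", "X")

    def test_site_count_equals_linker_aspartates(self, nprng):
        for _ in range(20):
            seq = "".join(
                AMINO_ACIDS[i] for i in nprng.integers(0, 20, size=40)
            )
            record = ProteinRecord("s", seq)
            start, end = 10, 30
            linker = LinkerAnnotation("s", start, end)
            sites = find_tetrapeptide_sites(record, linker)
            assert len(sites) == seq[start - 1 : end].count("D")
            assert all(s.tetrapeptide[-1] == "D" for s in sites)


class TestClassifySite:
    @pytest.mark.parametrize(
        "tetra,expected",
        [
            ("YVAD", CASPASE1_LIKE),   # the canonical caspase-1 substrate
            ("FASD", CASPASE1_LIKE),   # chicken GSDMA cleavage site
            ("FVSD", CASPASE1_LIKE),
            ("FLTD", CASPASE1_LIKE),   # human GSDMD
            ("LLSD", CASPASE1_LIKE),   # mouse GSDMD
            ("AAAD", OTHER_ASP),       # the cleavage-dead mutant
            ("DAVD", CASPASE3_LIKE),   # chicken GSDME caspase-3 site
            ("DEVD", CASPASE3_LIKE),
            ("GASD", OTHER_ASP),
        ],
    )
    def test_documented_motifs(self, tetra, expected):
        assert classify_site(make_site(tetra)).site_class == expected

    def test_exhaustive_partition_over_d_terminal_tetrapeptides(self):
        counts = {CASPASE1_LIKE: 0, CASPASE3_LIKE: 0, OTHER_ASP: 0}
        for p4, p3, p2 in itertools.product(AMINO_ACIDS, repeat=3):
            site = classify_site(make_site(p4 + p3 + p2 + "D"))
            counts[site.site_class] += 1
        assert sum(counts.values()) == 20**3
        assert counts[CASPASE3_LIKE] == 1 * 20 * 20          # P4 = D
        assert counts[CASPASE1_LIKE] == 7 * 20 * 20          # P4 bulky
        assert counts[OTHER_ASP] == 12 * 20 * 20

    def test_score_components(self):
        site = classify_site(make_site("FASD", p1p="G", p2p="P"))
        assert site.score == 2 + 2 + 1 + 1
        site = classify_site(make_site("AASD", p1p="S", p2p="A"))
        assert site.score == 2

    def test_malformed_tetrapeptide_rejected(self):
        with pytest.raises(MotifError):
            make_site("WWWW")


class TestYvadLike:
    def test_yvad_is_yvad_like(self):
        assert is_yvad_like(make_site("YVAD"))

    def test_arithmetic_against_substitution_table(self):
        # YVAD self-similarity: Y7 + V4 + A4 + D6 = 21
        assert yvad_similarity("YVAD") == 21
        # FVSD: F/Y 3 + V/V 4 + S/A 1 + D/D 6 = 14 -> below the cut of 15
        assert yvad_similarity("FVSD") == 14
        assert not is_yvad_like(make_site("FVSD"))
        # YIAD: Y7 + I/V 3 + A4 + D6 = 20 -> above
        assert yvad_similarity("YIAD") == 20
        assert is_yvad_like(make_site("YIAD"))

    def test_threshold_configurable(self):
        assert is_yvad_like(make_site("FVSD"), threshold=14)


class TestCaspase3Nterm:
    def test_devd_in_range_found(self):
        record = ProteinRecord("s", "MKVLDEVDGAACDEF")
        (site,) = scan_caspase3_nterm(record, (1, 10))
        assert site.tetrapeptide == "DEVD"
        assert site.p1_position == 8
        assert site.site_class == CASPASE3_LIKE

    def test_range_without_aspartate_empty(self):
        record = ProteinRecord("s", "MKVLAAAAGG")
        assert scan_caspase3_nterm(record, (1, 10)) == []

    def test_planted_position_recovered(self, nprng):
        from gsdmkit.synthetic import _fill

        pre = _fill(20, nprng).replace("D", "A")
        post = _fill(20, nprng).replace("D", "A")
        record = ProteinRecord("s", pre + "DAVD" + post)
        (site,) = scan_caspase3_nterm(record, (1, 44))
        assert site.p1_position == 24


class TestLogo:
    def test_conserved_positions_reach_full_information(self):
        sites = [make_site("YVAD") for _ in range(10)]
        logo = build_logo(sites, small_sample_correction=False)
        assert np.allclose(logo.information_content, math.log2(20))

    def test_uniform_position_has_zero_information(self):
        sites = [make_site(aa + "VAD") for aa in AMINO_ACIDS]
        logo = build_logo(sites, small_sample_correction=False)
        assert logo.information_content[0] == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_correction_formula(self):
        n = 10
        sites = [make_site("YVAD") for _ in range(n)]
        logo = build_logo(sites, small_sample_correction=True)
        expected = math.log2(20) - 19 / (2 * math.log(2) * n)
        assert logo.information_content[3] == pytest.approx(expected, abs=1e-9)

    def test_frequencies_sum_to_one(self):
        sites = [make_site("YVAD"), make_site("FASD"), make_site("WWWD")]
        logo = build_logo(sites)
        assert np.allclose(logo.frequency_matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_merging_site_sets_never_increases_information(self, nprng):
        def random_sites(n):
            return [
                make_site(
                    "".join(AMINO_ACIDS[i] for i in nprng.integers(0, 20, size=3)) + "D"
                )
                for _ in range(n)
            ]

        for _ in range(10):
            group_a, group_b = random_sites(8), random_sites(8)
            ic_a = build_logo(group_a, small_sample_correction=False).information_content
            ic_b = build_logo(group_b, small_sample_correction=False).information_content
            ic_ab = build_logo(
                group_a + group_b, small_sample_correction=False
            ).information_content
            assert np.all(ic_ab <= np.maximum(ic_a, ic_b) + 1e-9)

    def test_empty_site_list_rejected(self):
        with pytest.raises(MotifError):
            build_logo([])


class TestHydropathy:
    def test_poly_isoleucine_hits_scale_maximum(self):
        assert hydropathy_profile("IIIII", 5) == [4.5]

    def test_poly_arginine_hits_scale_minimum(self):
        assert hydropathy_profile("RRRRR", 5) == [-4.5]

    def test_hand_computed_window(self):
        expected = (3 * KYTE_DOOLITTLE["I"] + 2 * KYTE_DOOLITTLE["R"]) / 5
        assert hydropathy_profile("IRIRI", 5) == [pytest.approx(expected)]

    def test_output_length(self):
        assert len(hydropathy_profile("IRIRIRIRIR", 3)) == 8

    def test_even_window_rejected(self):
        with pytest.raises(MotifError):
            hydropathy_profile("IRIRI", 4)


class TestCladeSummary:
    def test_clade_without_sites_reports_zeros(self):
        records = [ProteinRecord("a", "MKVL", clade="bird")]
        (summary,) = clade_summary(records, {})
        assert summary.n_with_caspase1_like == 0
        assert summary.fraction_yvad_like == 0.0

    def test_record_with_multiple_sites_counts_once(self):
        records = [ProteinRecord("a", "MKVL", clade="bird")]
        sites = [
            classify_site(make_site("YVAD")),
            classify_site(make_site("YLAD")),
        ]
        (summary,) = clade_summary(records, {"a": sites})
        assert summary.n_with_caspase1_like == 1
        assert summary.n_yvad_like == 1
        assert summary.fraction_yvad_like == 1.0

    def test_fractions_bounded(self, nprng):
        records = []
        sites_by_record = {}
        for i in range(30):
            clade = ["bird", "reptile"][int(nprng.integers(0, 2))]
            rid = f"r{i}"
            records.append(ProteinRecord(rid, "MKVL", clade=clade))
            if nprng.random() < 0.5:
                sites_by_record[rid] = [classify_site(make_site("YVAD"))]
        for summary in clade_summary(records, sites_by_record):
            assert 0.0 <= summary.fraction_yvad_like <= 1.0


class TestBoundariesYaml:
    def test_round_trip(self, tmp_path):
        ref = ReferenceBoundaries(
            "chicken_gsdma", 235, 266,
            alpha7p_alpha8_range=(314, 347), nterm_range=(1, 235),
        )
        path = tmp_path / "b.yaml"
        write_boundaries_yaml(ref, path)
        back = read_boundaries_yaml(path)
        assert back == ref
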