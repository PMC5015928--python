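import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temposel.data import (A0, A1, HET, MISSING, GenotypeMatrix, ParseError,
                           assign_cohorts_and_populations, ibs_matrix,
                           mg_to_population, population_ancestor_ibs_summary,
                           read_genotype_table, write_genotype_table,
                           year_to_cohort)

from conftest import genotype_matrix


class TestHapmapIO:
    def test_fixture_shape_and_indices(self, hapmap_path):
        g = read_genotype_table(hapmap_path)
        assert (g.n_lines, g.n_markers) == (3, 6)
        assert list(g.markers["index"]) == [1, 2, 3, 4, 5, 6]
        assert g.line_ids == ["L1", "L2", "L3"]
        expected_l3 = [HET, MISSING, A1, A0, A0, A1]
        np.testing.assert_array_equal(g.calls[2], expected_l3)

    def test_round_trip_preserves_calls(self, hapmap_path, tmp_path):
        g = read_genotype_table(hapmap_path)
        out = tmp_path / "again.tsv"
        write_genotype_table(g, out)
        g2 = read_genotype_table(out)
        np.testing.assert_array_equal(g.calls, g2.calls)
        pd.testing.assert_frame_equal(g.markers, g2.markers)
        assert g.line_ids == g2.line_ids

    def test_triallelic_site_dropped_with_warning(self, tmp_path):
        lines = ["rs\tchrom\tpos\talleles\tL1\tL2",
                 "m1\tchr1\t100\tA/C\tAA\tCC",
                 "m2\tchr1\t200\tA/C/T\tAA\tTT",
                 "m3\tchr1\t300\tA/C\tCC\tAA",
                 "m4\tchr1\t400\tA/C\tAA\tAA",
                 "m5\tchr1\t500\tA/C\tCC\tCC",
                 "m6\tchr1\t600\tA/C\tAC\tAA"]
        p = tmp_path / "tri.tsv"
        p.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="non-biallelic"):
            g = read_genotype_table(p)
        assert g.n_markers == 5
        assert "m2" not in set(g.markers["marker"])

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rs\tchrom\tpos\talleles\tL1\n"
                     "m1\tchr1\t100\tA/C\tAA\n"
                     "m2\tchr1\t200\tA/C\n")
        with pytest.raises(ParseError, match="line 3"):
            read_genotype_table(p)

    def test_unsorted_positions_sorted_with_warning(self, tmp_path):
        p = tmp_path / "unsorted.tsv"
        p.write_text("rs\tchrom\tpos\talleles\tL1\n"
                     "m1\tchr1\t300\tA/C\tAA\n"
                     "m2\tchr1\t100\tA/C\tCC\n")
        with pytest.warns(UserWarning, match="unsorted"):
            g = read_genotype_table(p)
        assert list(g.markers["pos"]) == [100, 300]
        np.testing.assert_array_equal(g.calls[0], [A1, A0])

    def test_vcf_reader(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t100\tv1\tA\tC\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            "chr1\t200\tv2\tG\tT\t.\tPASS\t.\tGT\t0/1\t./.\n"
            "chr1\t300\tv3\tA\tC,T\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "chr1\t400\tv4\tT\tG\t.\tPASS\t.\tGT\t1/1\t0/0\n")
        p = tmp_path / "tiny.vcf"
        p.write_text(vcf)
        with pytest.warns(UserWarning, match="non-biallelic"):
            g = read_genotype_table(p, format="vcf")
        assert g.n_markers == 3           # multi-allelic v3 dropped
        np.testing.assert_array_equal(g.calls[0], [A0, HET, A1])
        np.testing.assert_array_equal(g.calls[1], [A1, MISSING, A0])


class TestCohortAssignment:
    @pytest.mark.parametrize("mg,year,pop,cohort", [
        ("I", 1965, "MG0-I", "pre1970s"),
        ("II", 1985, "EXCLUDED", "1980s"),
        ("VI", 2004, "MGV+", "2000s"),
        ("00", 1972, "MG0-I", "1970s"),
        ("III", 1999, "MGIII-IV", "1990s"),
        ("0", 1938, "MG0-I", "pre1970s"),
        ("IV", 1990, "MGIII-IV", "1990s"),
    ])
    def test_rules(self, mg, year, pop, cohort):
        panel = pd.DataFrame({"line_id": ["x"], "maturity_group": [mg],
                              "year_of_release": [year]})
        out = assign_cohorts_and_populations(panel)
        assert out.loc[0, "population"] == pop
        assert out.loc[0, "cohort"] == cohort

    def test_unknown_mg_names_line(self):
        panel = pd.DataFrame({"line_id": ["good", "oops"],
                              "maturity_group": ["I", "IX"],
                              "year_of_release": [1980, 1980]})
        with pytest.raises(ValueError, match="oops"):
            assign_cohorts_and_populations(panel)

    def test_pure_function_of_inputs(self):
        assert mg_to_population("v") == "MGV+"      # case-insensitive
        assert year_to_cohort(1969) == "pre1970s"
        assert year_to_cohort(1970) == "1970s"
        assert year_to_cohort(2012) == "2000s"


class TestIBS:
    def test_identical_lines(self):
        g = genotype_matrix([[0, 1, 0, 1], [0, 1, 0, 1]])
        np.testing.assert_allclose(ibs_matrix(g).values,
                                   [[1, 1], [1, 1]])

    def test_complete_difference(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1] = 1
        assert ibs_matrix(genotype_matrix(calls)).values[0, 1] == 0.0

    def test_hand_count_quarter_diff(self):
        calls = np.zeros((2, 200), dtype=np.int8)
        calls[1, :50] = 1
        assert ibs_matrix(genotype_matrix(calls)).values[0, 1] == 0.75

    def test_het_conventions(self):
        # HET vs hom = half match, HET vs HET = full match
        g = genotype_matrix([[0, HET], [HET, HET]])
        assert ibs_matrix(g).values[0, 1] == pytest.approx(0.75)

    def test_missing_excluded_pairwise(self):
        g = genotype_matrix([[0, MISSING, 1, 1], [0, 1, MISSING, 1]])
        m = ibs_matrix(g)
        assert m.values[0, 1] == 1.0
        assert m.counts[0, 1] == 2

    def test_zero_comparable_pair_is_nan(self):
        g = genotype_matrix([[MISSING, 0], [1, MISSING]])
        assert np.isnan(ibs_matrix(g).values[0, 1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_permutation(self, seed):
        r = np.random.default_rng(seed)
        calls = r.choice([0, 1, HET, MISSING], p=[0.45, 0.45, 0.05, 0.05],
                         size=(5, 40)).astype(np.int8)
        g = genotype_matrix(calls)
        m = ibs_matrix(g).values
        np.testing.assert_allclose(m, m.T)
        valid = ~np.all(calls == MISSING, axis=1)
        np.testing.assert_allclose(np.diag(m)[valid], 1.0)
        perm = r.permutation(5)
        m2 = ibs_matrix(genotype_matrix(calls[perm])).values
        np.testing.assert_allclose(m2, m[np.ix_(perm, perm)])


class TestAncestorIBSSummary:
    def test_population_of_ancestor_copies(self):
        anc = genotype_matrix([[0, 1, 0, 1, 1], [1, 0, 1, 0, 0]],
                              line_ids=["AncA", "AncB"])
        lines = genotype_matrix(
            np.tile([0, 1, 0, 1, 1], (3, 1)),
            panel_extra={"population": ["P1"] * 3})
        res = population_ancestor_ibs_summary(lines, anc)
        a_rows = res.per_line.query("ancestor == 'AncA'")
        assert (a_rows["ibs"] == 1.0).all()
        med = res.summary.query("ancestor == 'AncA'")["median"].iloc[0]
        assert med == 1.0

    def test_empty_population_no_crash(self):
        anc = genotype_matrix([[0, 1], [1, 0]], line_ids=["A", "B"])
        lines = genotype_matrix([[0, 1]], panel_extra={"population": ["P1"]})
        res = population_ancestor_ibs_summary(lines, anc)
        assert res.summary.query("population == 'P2'").empty

    def test_marker_map_mismatch_raises(self):
        anc = genotype_matrix([[0, 1, 0], [1, 0, 1]])
        lines = genotype_matrix([[0, 1]])
        with pytest.raises(ValueError, match="marker map"):
            population_ancestor_ibs_summary(lines, anc)
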