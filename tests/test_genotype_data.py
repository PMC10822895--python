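"""Genotype domain types, file I/O, RFLP calling and tabulation."""

import numpy as np
import pytest

from dilocus import (
    GenotypeClass,
    GenotypeCounts,
    LocusDef,
    MTHFR_A1298C,
    MTHFR_C677T,
    Sample,
    TwoLocusCounts,
    call_genotype_from_fragments,
    read_samples_tsv,
    read_vcf_two_snps,
    tabulate,
    tabulate_pair,
    validate_margins,
    write_samples_tsv,
)
from dilocus.genotype_data import GenotypeError

from conftest import samples_from_grid

G = GenotypeClass


class TestLocusDef:
    def test_allele_labels_must_differ(self):
        with pytest.raises(ValueError):
            LocusDef(name="bad", rsid="rs0", ref_allele="C", alt_allele="C")

    def test_fragment_map_must_be_three_distinct_sets(self):
        with pytest.raises(ValueError, match="distinct"):
            LocusDef(
                name="bad", rsid="rs0", ref_allele="C", alt_allele="T",
                fragment_map={
                    G.HOM_REF: {198}, G.HET: {198}, G.HOM_ALT: {175, 23},
                },
            )

    @pytest.mark.parametrize("text,expected", [
        ("CT", G.HET), ("TC", G.HET), ("C/T", G.HET),
        ("CC", G.HOM_REF), ("TT", G.HOM_ALT),
    ])
    def test_parse_genotype_is_unordered(self, text, expected):
        assert MTHFR_C677T.parse_genotype(text) == expected

    def test_parse_rejects_foreign_allele(self):
        with pytest.raises(GenotypeError):
            MTHFR_C677T.parse_genotype("CG")


class TestSample:
    def test_trg_only_for_cases(self):
        with pytest.raises(ValueError, match="control"):
            Sample(sample_id="X", group="control", trg=3)

    @pytest.mark.parametrize("trg,resp", [
        (1, "responder"), (2, "responder"), (3, "non-responder"),
        (5, "non-responder"), (None, None),
    ])
    def test_response_classification(self, trg, resp):
        assert Sample(sample_id="X", group="case", trg=trg).response == resp


class TestSampleTsv:
    def _write(self, tmp_path, rows):
        path = tmp_path / "samples.tsv"
        header = "sample_id\tgroup\tsex\ttrg\tMTHFR C677T\tMTHFR A1298C"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_basic_row(self, tmp_path):
        (s,) = read_samples_tsv(self._write(tmp_path, ["P01\tcase\tmale\t3\tCT\tAA"]))
        assert s.group == "case" and s.sex == "male" and s.trg == 3
        assert s.genotypes["MTHFR C677T"] == G.HET
        assert s.genotypes["MTHFR A1298C"] == G.HOM_REF

    def test_na_trg_kept_but_unclassified(self, tmp_path):
        (s,) = read_samples_tsv(self._write(tmp_path, ["P02\tcase\tfemale\tNA\tCC\tAC"]))
        assert s.trg is None and s.response is None

    def test_reversed_genotype_string_is_same_class(self, tmp_path):
        a, b = read_samples_tsv(self._write(tmp_path, [
            "P03\tcase\tmale\t1\tTC\tNA", "P04\tcase\tmale\t1\tCT\tNA",
        ]))
        assert a.genotypes["MTHFR C677T"] == b.genotypes["MTHFR C677T"] == G.HET
        assert a.genotypes["MTHFR A1298C"] is None

    def test_unknown_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tgroup\tBOGUS\nP\tcase\tCC\n")
        with pytest.raises(GenotypeError, match="BOGUS"):
            read_samples_tsv(path)

    def test_malformed_genotype_reports_line(self, tmp_path):
        with pytest.raises(GenotypeError, match=":3:"):
            read_samples_tsv(self._write(tmp_path, [
                "P05\tcase\tmale\t1\tCC\tAA", "P06\tcase\tmale\t1\tQQ\tAA",
            ]))

    def test_round_trip(self, tmp_path):
        samples = samples_from_grid([[2, 1, 0], [1, 3, 1], [0, 0, 1]],
                                    group="case", sex="female", trg=2)
        samples += samples_from_grid([[1, 1, 1], [0, 2, 0], [1, 0, 0]],
                                     group="control", sex="male", prefix="C")
        samples[0].genotypes["MTHFR A1298C"] = None
        path = tmp_path / "rt.tsv"
        write_samples_tsv(samples, path, header_comments=["round trip"])
        back = read_samples_tsv(path)
        assert len(back) == len(samples)
        for x, y in zip(samples, back):
            assert (x.sample_id, x.group, x.sex, x.trg, x.genotypes) == (
                y.sample_id, y.group, y.sex, y.trg, y.genotypes)


class TestVcf:
    VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1801133\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t./.
1\t200\trs1801131\tA\tC\t.\t.\t.\tGT\t1|0\t1/1\t0/0
"""

    def test_gt_mapping_and_phase_collapse(self, tmp_path):
        path = tmp_path / "two.vcf"
        path.write_text(self.VCF)
        s1, s2, s3 = read_vcf_two_snps(path)
        assert s1.genotypes["MTHFR C677T"] == G.HOM_REF
        assert s2.genotypes["MTHFR C677T"] == G.HET
        assert s3.genotypes["MTHFR C677T"] is None  # ./. missing
        assert s1.genotypes["MTHFR A1298C"] == G.HET  # 1|0 phase discarded
        assert s2.genotypes["MTHFR A1298C"] == G.HOM_ALT

    def test_absent_rsid_lists_found_ids(self, tmp_path):
        path = tmp_path / "one.vcf"
        path.write_text("\n".join(self.VCF.splitlines()[:-1]) + "\n")
        with pytest.raises(GenotypeError, match="rs1801131"):
            read_vcf_two_snps(path)

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(self.VCF.replace("\tC\tT\t", "\tC\tT,G\t"))
        with pytest.raises(GenotypeError, match="biallelic"):
            read_vcf_two_snps(path)


class TestFragmentCalling:
    @pytest.mark.parametrize("locus,observed,expected", [
        (MTHFR_C677T, {198}, G.HOM_REF),
        (MTHFR_C677T, {198, 175, 23}, G.HET),
        (MTHFR_C677T, {175, 23}, G.HOM_ALT),
        (MTHFR_A1298C, {84, 31, 30, 18}, G.HOM_REF),
        (MTHFR_A1298C, {84, 56, 31, 30, 28, 18}, G.HET),
        (MTHFR_A1298C, {56, 31, 30, 28, 18}, G.HOM_ALT),
    ])
    def test_all_six_nominal_patterns(self, locus, observed, expected):
        assert call_genotype_from_fragments(observed, locus) == expected

    def test_sizing_slack_within_tolerance(self):
        assert call_genotype_from_fragments({197, 176, 24}, MTHFR_C677T) == G.HET

    @pytest.mark.parametrize("observed", [
        {198, 175},          # missing band
        {198, 175, 23, 90},  # extra band
        {150},               # matches nothing
    ])
    def test_non_matching_sets_rejected(self, observed):
        with pytest.raises(GenotypeError, match="uninterpretable"):
            call_genotype_from_fragments(observed, MTHFR_C677T)

    def test_ambiguity_is_an_error(self):
        locus = LocusDef(
            name="amb", rsid="rs0", ref_allele="G", alt_allele="A",
            fragment_map={G.HOM_REF: {100}, G.HET: {102}, G.HOM_ALT: {100, 50}},
        )
        with pytest.raises(GenotypeError, match="ambiguous"):
            call_genotype_from_fragments({101}, locus, tolerance=2)

    def test_empty_observation_rejected(self):
        with pytest.raises(GenotypeError):
            call_genotype_from_fragments(set(), MTHFR_C677T)


class TestTabulate:
    def test_counts_and_pair_cell(self, cohort):
        samples = samples_from_grid(cohort.two_locus_counts("patients").counts)
        g = tabulate(samples, MTHFR_C677T, group="case")["all"]
        assert tuple(g.as_array()) == (50, 44, 3)
        t = tabulate_pair(samples, MTHFR_C677T, MTHFR_A1298C, group="case")["all"]
        assert t.counts[1, 1] == 13  # CT/AC

    def test_response_strata(self, cohort):
        samples = samples_from_grid(
            cohort.two_locus_counts("responders").counts, trg=1
        ) + samples_from_grid(
            cohort.two_locus_counts("non-responders").counts, trg=4, prefix="N"
        )
        tabs = tabulate(samples, MTHFR_C677T, stratifier="response", group="case")
        assert tuple(tabs["responder"].as_array()) == (13, 15, 2)
        assert tuple(tabs["non-responder"].as_array()) == (35, 29, 1)

    def test_missing_trg_excluded_from_response_strata(self):
        samples = samples_from_grid([[3, 0, 0], [0, 0, 0], [0, 0, 0]], trg=None)
        tabs = tabulate(samples, MTHFR_C677T, stratifier="response", group="case")
        assert tabs["responder"].n == 0 and tabs["non-responder"].n == 0

    def test_permutation_invariance(self, cohort):
        samples = samples_from_grid(cohort.two_locus_counts("patients").counts)
        rng = np.random.default_rng(7)
        shuffled = [samples[i] for i in rng.permutation(len(samples))]
        a = tabulate(samples, MTHFR_A1298C)["all"].as_array()
        b = tabulate(shuffled, MTHFR_A1298C)["all"].as_array()
        assert (a == b).all()

    def test_sex_strata_sum_to_total_without_unknowns(self):
        samples = samples_from_grid([[2, 1, 0], [0, 3, 1], [1, 0, 0]], sex="male")
        samples += samples_from_grid([[1, 0, 2], [2, 0, 0], [0, 1, 0]],
                                     sex="female", prefix="F")
        by_sex = tabulate(samples, MTHFR_C677T, stratifier="sex")
        total = tabulate(samples, MTHFR_C677T)["all"].as_array()
        assert (by_sex["male"].as_array() + by_sex["female"].as_array() == total).all()

    def test_empty_stratum_returns_zeros(self):
        samples = samples_from_grid([[1, 0, 0], [0, 0, 0], [0, 0, 0]], sex="male")
        assert tabulate(samples, MTHFR_C677T, stratifier="sex")["female"].n == 0


class TestValidateMargins:
    def test_published_grid_consistent_with_single_locus_tables(self, cohort):
        report = validate_margins(
            cohort.two_locus_counts("patients"),
            cohort.genotype_counts("MTHFR C677T", "patients"),
            cohort.genotype_counts("MTHFR A1298C", "patients"),
        )
        assert report == []

    def test_perturbed_cell_reported(self, cohort):
        t = cohort.two_locus_counts("patients")
        bad = t.counts.copy()
        bad[1, 0] = 30  # CT/AA 29 -> 30
        report = validate_margins(
            TwoLocusCounts(t.locus1, t.locus2, bad),
            cohort.genotype_counts("MTHFR C677T", "patients"),
            cohort.genotype_counts("MTHFR A1298C", "patients"),
        )
        assert any("CT" in line and "45" in line and "44" in line for line in report)

    def test_zero_tables_consistent(self, loci):
        l1, l2 = loci
        report = validate_margins(
            TwoLocusCounts(l1, l2, np.zeros((3, 3), dtype=int)),
            GenotypeCounts(l1, 0, 0, 0),
            GenotypeCounts(l2, 0, 0, 0),
        )
        assert report == []
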