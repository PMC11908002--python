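"""Element assembly, LTR detection, Kimura dating and domain calling."""

import math

import numpy as np
import pytest

from ervrip.annotation import (
    ERVElement,
    RepeatHit,
    RepeatMaskerParseError,
    SaturationError,
    assemble_elements,
    characterize_element,
    classify_full_length,
    date_element,
    detect_ltrs,
    estimate_insertion_age,
    find_orf_domains,
    interval_length,
    kimura_k2p,
    library_from_template,
    parse_repeatmasker_out,
    scan_repeats,
)
from ervrip.simulate import build_erv_element, mutate_sequence, random_genome

RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin  end  (left)   repeat  class/family begin end (left) ID\n"
    "\n"
)
RM_BODY = (
    "  463  1.3  0.6  1.7  chr1   10001  10444  (49556) +  OvERV-LTR  LTR/ERVK  1  444  (0)  1\n"
    " 7042  2.1  0.0  0.0  chr1   10445  17486  (42514) +  OvERV-int  LTR/ERVK  1  7042 (0)  1\n"
    "  460  1.5  0.6  1.7  chr2   5000   5443   (54557) C  OvERV-LTR  LTR/ERVK  (0) 444  1   2\n"
)


class TestRepeatMaskerParser:
    def test_well_formed_hits(self, tmp_path):
        path = tmp_path / "hits.out"
        path.write_text(RM_HEADER + RM_BODY)
        hits = parse_repeatmasker_out(path)
        assert len(hits) == 3
        assert hits[0].chrom == "chr1"
        assert (hits[0].start, hits[0].end) == (10001, 10444)
        assert hits[0].family == "OvERV-LTR"
        assert hits[0].divergence == 1.3

    def test_c_orientation_is_minus_strand(self, tmp_path):
        path = tmp_path / "hits.out"
        path.write_text(RM_HEADER + RM_BODY)
        assert parse_repeatmasker_out(path)[2].strand == "-"

    def test_empty_body(self, tmp_path):
        path = tmp_path / "hits.out"
        path.write_text(RM_HEADER)
        assert parse_repeatmasker_out(path) == []

    def test_malformed_line_reported_with_number(self, tmp_path):
        path = tmp_path / "hits.out"
        path.write_text(RM_HEADER + "  463  1.3  bad line\n")
        with pytest.raises(RepeatMaskerParseError, match="line 4"):
            parse_repeatmasker_out(path)


class TestAssembleElements:
    def _hit(self, start, end, strand="+", family="F-LTR", chrom="chr1"):
        return RepeatHit(chrom, start, end, strand, family, 0.0)

    def test_ltr_internal_ltr_joined(self):
        hits = [
            self._hit(1000, 1443, family="F-LTR"),
            self._hit(1444, 8485, family="F-int"),
            self._hit(8486, 8929, family="F-LTR"),
        ]
        elements = assemble_elements(hits)
        assert len(elements) == 1
        assert (elements[0].start, elements[0].end) == (1000, 8929)

    def test_distant_clusters_stay_separate(self):
        hits = [self._hit(1000, 1500), self._hit(11500, 12000)]
        assert len(assemble_elements(hits, max_join_gap=500)) == 2

    def test_opposite_strands_not_joined(self):
        hits = [self._hit(1000, 1500, "+"), self._hit(1600, 2100, "-")]
        assert len(assemble_elements(hits, max_join_gap=500)) == 2


class TestClassifyFullLength:
    def _element(self, length, ltrs=True, domains=("Gag", "Pro", "Pol", "Env")):
        return ERVElement(
            genome_id="g",
            chrom="chr1",
            start=1001,
            end=1000 + length,
            strand="+",
            family="F",
            ltr5_span=(1001, 1444) if ltrs else None,
            ltr3_span=(557 + length, 1000 + length) if ltrs else None,
            domains=tuple((d, 100) for d in domains),
        )

    def test_reference_geometry_is_full_length(self):
        assert classify_full_length(self._element(7930)) is True

    def test_length_threshold_strict(self):
        assert classify_full_length(self._element(4999)) is False
        assert classify_full_length(self._element(5000)) is False
        assert classify_full_length(self._element(5001)) is True

    def test_missing_ltr_disqualifies(self):
        assert classify_full_length(self._element(8000, ltrs=False)) is False

    def test_missing_core_domain_disqualifies(self):
        assert classify_full_length(self._element(8000, domains=("Gag", "Pol"))) is False
        # Pro is reported when found but is not required
        assert classify_full_length(self._element(8000, domains=("Gag", "Pol", "Env"))) is True


class TestDetectLtrs:
    def test_identical_444bp_ltrs(self, template):
        element = build_erv_element(template, 0.0, seed=0)
        span5, span3, similarity = detect_ltrs(element)
        assert similarity == 100
        assert interval_length(*span5) == 444
        assert interval_length(*span3) == 444
        assert span5 == (1, 444)
        assert span3 == (len(element) - 443, len(element))

    def test_random_sequence_has_no_terminal_repeat(self):
        seq = random_genome({"c": 4000}, seed=8)["c"]
        assert detect_ltrs(seq) is None

    def test_one_mismatch_in_100bp_reads_99_percent(self):
        rng = np.random.default_rng(15)
        ltr = random_genome({"c": 100}, seed=15)["c"]
        middle = random_genome({"c": 600}, seed=16)["c"]
        ltr3 = list(ltr)
        ltr3[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ltr3[50]]
        seq = ltr + middle + "".join(ltr3)
        result = detect_ltrs(seq, min_len=80)
        assert result is not None
        _, _, similarity = result
        assert similarity == 99
        _ = rng

    def test_divergent_ltrs_match_counting_oracle(self, template):
        element = build_erv_element(template, 0.03, seed=21)
        span5, span3, similarity = detect_ltrs(element)
        ltr5 = element[span5[0] - 1 : span5[1]]
        ltr3 = element[span3[0] - 1 : span3[1]]
        matches = sum(a == b for a, b in zip(ltr5, ltr3))
        assert similarity == round(100 * matches / len(ltr5))


class TestKimura:
    def test_identical_sequences(self):
        est = kimura_k2p("ACGTACGT", "ACGTACGT")
        assert est.P == est.Q == est.K == 0.0

    def test_closed_form_value(self):
        # 100 sites: 10 transitions, 5 transversions -> P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        est = kimura_k2p(a, b)
        assert est.P == 0.10 and est.Q == 0.05
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert est.K == pytest.approx(expected, abs=1e-12)
        assert est.K == pytest.approx(0.1702, abs=5e-4)

    def test_saturation_error(self):
        # 50 transitions + 30 transversions in 100 sites: 1-2P-Q = -0.1
        a = "A" * 100
        b = "G" * 50 + "C" * 30 + "A" * 20
        with pytest.raises(SaturationError):
            kimura_k2p(a, b)

    def test_gap_columns_excluded(self):
        # the gap column is excluded; T/A in the last column is a transversion
        est = kimura_k2p("AC-GT", "ACCGA")
        assert est.n_sites == 4
        assert est.P == 0.0
        assert est.Q == 0.25

    def test_counting_oracle_on_mutated_pairs(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            a = random_genome({"c": 800}, seed=int(rng.integers(1 << 30)))["c"]
            b = mutate_sequence(a, 0.05, rng)
            transitions = sum(
                (x, y) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
                for x, y in zip(a, b)
            )
            transversions = sum(x != y for x, y in zip(a, b)) - transitions
            est = kimura_k2p(a, b)
            assert est.P == transitions / 800
            assert est.Q == transversions / 800


class TestInsertionAge:
    def test_zero_divergence_is_zero_age(self):
        assert estimate_insertion_age(0.0) == 0.0

    @pytest.mark.parametrize(
        "K, r, expected",
        [(0.1702, 2.2e-9, 3.868e7), (0.0044, 2.2e-9, 1.0e6)],
    )
    def test_age_arithmetic(self, K, r, expected):
        assert estimate_insertion_age(K, r) == pytest.approx(expected, rel=1e-3)

    def test_monotone_in_K(self):
        ages = [estimate_insertion_age(k) for k in np.linspace(0, 0.3, 20)]
        assert all(b > a for a, b in zip(ages, ages[1:]))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            estimate_insertion_age(0.1, r=0.0)

    def test_date_element_round_trip(self, template):
        element = build_erv_element(template, 0.02, seed=5)
        span5, span3, _ = detect_ltrs(element)
        est = date_element(element, span5, span3)
        assert est.T == pytest.approx(est.K / (2 * 2.2e-9))
        assert est.K > 0


class TestOrfDomains:
    def test_template_domains_recovered(self, template):
        element = build_erv_element(template, 0.0, seed=0)
        domains = find_orf_domains(
            element,
            min_aa=150,
            layout=template.domain_layout,
            layout_offset=len(template.ltr_seq),
        )
        named = {n: aa for n, aa in domains if n != "ORF"}
        assert named == {"Gag": 531, "Pro": 278, "Pol": 696, "Env": 441}

    def test_all_stop_sequence_empty(self):
        assert find_orf_domains("TAATAGTGA" * 50, min_aa=5) == []

    def test_min_aa_threshold(self):
        # ORF of exactly 10 aa (ATG + 9 codons + stop)
        orf = "ATG" + "GCT" * 9 + "TAA"
        seq = "TAGTAA" + orf + "TAGTAA"
        assert ("ORF", 10) in find_orf_domains(seq, min_aa=10)
        assert find_orf_domains(seq, min_aa=11) == []

    def test_domain_table_takes_precedence(self, tmp_path):
        path = tmp_path / "domains.tsv"
        path.write_text("domain\taa_length\nGag\t616\nPol\t777\n")
        assert find_orf_domains("ACGT", domain_table=path) == [("Gag", 616), ("Pol", 777)]

    def test_malformed_domain_table(self, tmp_path):
        path = tmp_path / "domains.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="domain"):
            find_orf_domains("ACGT", domain_table=path)


class TestScanAndCharacterize:
    def test_planted_element_fully_characterized(self, planted_scenario, template):
        genome = planted_scenario["genomes"]["g0"]
        library = library_from_template(template)
        hits = scan_repeats(genome, library)
        elements = assemble_elements(hits, genome_id="g0")
        assert len(elements) == 2
        element = characterize_element(elements[0], genome, template=template)
        assert element.full_length is True
        assert element.ltr_similarity == 100
        assert element.length == 7930
        # length arithmetic against the extracted sequence itself
        assert len(element.sequence(genome)) == element.end - element.start + 1


class TestIntervalArithmetic:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (41862971, 41870900, 7930),
            (1918, 9847, 7930),
            (42467070, 42475012, 7943),
            (45499852, 45507607, 7756),
            (41861053, 41968317, 107265),
        ],
    )
    def test_carrier_coordinates(self, start, end, expected):
        assert interval_length(start, end) == expected
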