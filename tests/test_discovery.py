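"""Flank mapping, projection, polymorphism calling, merging, gene context."""

import numpy as np
import pytest

from ervrip.annotation import ERVElement
from ervrip.discovery import (
    DiscoveryConfig,
    FlankAlignment,
    GenomeIndex,
    ProjectedInsertion,
    RIPLocus,
    Transcript,
    call_rips,
    discover_rips,
    evaluate_discovery,
    extract_flanks,
    intersect_genes,
    locate_in_transcript,
    map_flank,
    merge_rips,
    parse_gff3_transcripts,
    project_insertion,
)
from ervrip.simulate import PlantSpec, plant_insertions, random_genome, reverse_complement

CONFIG = DiscoveryConfig()


def _element(start, end, chrom="chr1", strand="+", family="F"):
    return ERVElement("g", chrom, start, end, strand, family)


class TestExtractFlanks:
    def test_coordinate_arithmetic(self):
        genome = {"chr1": random_genome({"c": 20000}, seed=1)["c"]}
        up, down, truncated = extract_flanks(_element(1001, 9000), genome, 500)
        assert up == genome["chr1"][500:1000]  # bases 501..1000
        assert down == genome["chr1"][9000:9500]  # bases 9001..9500
        assert truncated is False

    def test_contig_edge_truncates(self):
        genome = {"chr1": random_genome({"c": 20000}, seed=1)["c"]}
        up, _, truncated = extract_flanks(_element(1, 8000), genome, 500)
        assert up == ""
        assert truncated is True

    def test_element_outside_contig(self):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(ValueError, match="contig"):
            extract_flanks(_element(100, 5000), genome, 500)

    def test_planted_flank_equals_reference_context(self, planted_scenario):
        # upstream flank of a planted element reproduces the reference bases
        # before the insertion point (the TSD copy keeps it contiguous)
        truth = planted_scenario["truth"]
        row = truth[truth.genome_id == "g0"].iloc[0]
        genome = planted_scenario["genomes"]["g0"]
        pos, tsd = int(row.position), int(row.tsd_len)
        element = _element(pos + tsd, pos + tsd + row.element_length - 1)
        up, _, _ = extract_flanks(element, genome, 500)
        ref = planted_scenario["reference"]["chr1"]
        assert up == ref[pos - 1 - (500 - tsd) : pos - 1 + tsd]


@pytest.fixture(scope="module")
def ref_and_index():
    ref = random_genome({"chr1": 40000}, seed=9)
    return ref, GenomeIndex(ref, k=CONFIG.k)


class TestMapFlank:

    def test_verbatim_flank_perfect_alignment(self, ref_and_index):
        ref, index = ref_and_index
        flank = ref["chr1"][10000:10500]
        alns = map_flank(flank, index, CONFIG)
        assert len(alns) == 1
        aln = alns[0]
        assert aln.identity == 100.0
        assert aln.aligned_cols == 500
        assert aln.score == 500
        assert (aln.target_start, aln.target_end) == (10001, 10500)
        assert aln.strand == "+"

    def test_reverse_complement_maps_minus(self, ref_and_index):
        ref, index = ref_and_index
        flank = reverse_complement(ref["chr1"][10000:10500])
        alns = map_flank(flank, index, CONFIG)
        assert len(alns) == 1
        assert alns[0].strand == "-"
        assert (alns[0].target_start, alns[0].target_end) == (10001, 10500)

    def test_span_window_filter(self, ref_and_index):
        ref, index = ref_and_index
        # a 449 bp query aligns over 449 columns -> filtered; 450 retained
        assert map_flank(ref["chr1"][10000:10449], index, CONFIG) == []
        assert len(map_flank(ref["chr1"][10000:10450], index, CONFIG)) == 1

    def test_multi_mapping_flank_returns_both(self):
        core = random_genome({"c": 600}, seed=10)["c"]
        pad = random_genome({"c": 3000}, seed=11)["c"]
        ref = {"chr1": pad + core + pad[::-1] + core + pad}
        index = GenomeIndex(ref, k=CONFIG.k)
        alns = map_flank(core[:500], index, CONFIG)
        assert len(alns) == 2

    def test_filter_monotonicity(self, ref_and_index):
        ref, index = ref_and_index
        flank = list(ref["chr1"][10000:10500])
        rng = np.random.default_rng(3)
        for pos in rng.choice(500, size=30, replace=False):
            flank[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[flank[pos]]
        flank = "".join(flank)
        loose = DiscoveryConfig(min_identity=80.0, min_score=400)
        assert len(map_flank(flank, index, loose)) >= len(map_flank(flank, index, CONFIG))


def _aln(side, start, end, strand="+"):
    return FlankAlignment(
        query_id="q",
        query_len=500,
        side=side,
        target_chrom="chr1",
        target_start=start,
        target_end=end,
        strand=strand,
        matches=end - start + 1,
        aligned_cols=end - start + 1,
    )


class TestProjectInsertion:
    def test_unique_upstream_projects_after_hit(self):
        ins = project_insertion(
            {"upstream": [_aln("upstream", 41862471, 41862970)], "downstream": []},
            CONFIG,
        )
        assert ins.ref_position == 41862971
        assert ins.support == "upstream"

    def test_multi_mapping_without_rescue_omitted(self):
        alns = {
            "upstream": [_aln("upstream", 1000, 1499), _aln("upstream", 9000, 9499)],
            "downstream": [],
        }
        assert project_insertion(alns, CONFIG) is None

    def test_downstream_rescues_failed_upstream(self):
        alns = {
            "upstream": [],
            "downstream": [_aln("downstream", 2000, 2499)],
        }
        ins = project_insertion(alns, CONFIG)
        assert ins.ref_position == 2000
        assert ins.support == "downstream"

    def test_both_sides_adjacent_support_both(self):
        alns = {
            "upstream": [_aln("upstream", 1500, 1999)],
            "downstream": [_aln("downstream", 2006, 2505)],
        }
        ins = project_insertion(alns, CONFIG)
        assert ins.support == "both"
        assert ins.ref_position == 2000

    def test_disagreeing_sides_omitted(self):
        alns = {
            "upstream": [_aln("upstream", 1500, 1999)],
            "downstream": [_aln("downstream", 5000, 5499)],
        }
        assert project_insertion(alns, CONFIG) is None


class TestCallRips:
    def _proj(self, pos, family="F"):
        return ProjectedInsertion("g", "chr1", pos, "+", "upstream", family=family)

    def test_window_rule(self):
        reference_ervs = [_element(10060, 18000)]
        # nearest edge 60 bp away -> candidate at w=50
        assert call_rips([self._proj(10000)], reference_ervs, CONFIG)
        # nearest edge 40 bp away -> suppressed
        assert call_rips([self._proj(10020)], reference_ervs, CONFIG) == []

    def test_family_mismatch_ignores_reference_element(self):
        reference_ervs = [_element(10010, 18000, family="OTHER")]
        assert call_rips([self._proj(10000)], reference_ervs, CONFIG)


class TestMergeRips:
    def _proj(self, pos, strand="+"):
        return ProjectedInsertion("g", "chr1", pos, strand, "upstream")

    def test_nearby_same_strand_merge(self):
        loci = merge_rips([self._proj(1000), self._proj(1008)], CONFIG)
        assert len(loci) == 1
        assert len(loci[0].members) == 2

    def test_beyond_gap_stay_separate(self):
        assert len(merge_rips([self._proj(1000), self._proj(1012)], CONFIG)) == 2

    def test_opposite_strands_never_merge(self):
        assert len(merge_rips([self._proj(1000), self._proj(1000, "-")], CONFIG)) == 2

    def test_idempotent(self):
        candidates = [self._proj(p) for p in (1000, 1005, 1030, 1500)]
        once = merge_rips(candidates, CONFIG)
        twice = merge_rips(once, CONFIG)
        assert [(l.ref_chrom, l.ref_start, l.ref_end, l.strand, len(l.members)) for l in once] == [
            (l.ref_chrom, l.ref_start, l.ref_end, l.strand, len(l.members)) for l in twice
        ]


@pytest.fixture(scope="module")
def transcript15():
    # 15 exons of 100 bp separated by 900 bp introns, plus strand
    exons = tuple((1000 + i * 1000, 1099 + i * 1000) for i in range(15))
    return Transcript("CD36", "tx1", "chr1", "+", exons)


class TestGeneIntersection:

    def test_intron1_of_15_exon_transcript(self, transcript15):
        assert len(transcript15.exons) == 15  # hence 14 introns
        assert locate_in_transcript(transcript15, 1500) == "intron 1"

    def test_exon3(self, transcript15):
        assert locate_in_transcript(transcript15, 3050) == "exon 3"

    def test_outside_transcript(self, transcript15):
        assert locate_in_transcript(transcript15, 500) is None
        assert locate_in_transcript(transcript15, 20000) is None

    def test_minus_strand_indexing(self):
        exons = tuple((1000 + i * 1000, 1099 + i * 1000) for i in range(15))
        tx = Transcript("CD36", "tx1", "chr1", "-", exons)
        # last genomic intron is intron 1 in transcript orientation
        assert locate_in_transcript(tx, 14500) == "intron 1"
        assert locate_in_transcript(tx, 15050) == "exon 1"

    def test_intersect_annotates_loci(self, transcript15):
        inside = RIPLocus("chr1", 1500, 1500, "+", members=[object()])
        outside = RIPLocus("chr1", 50000, 50000, "+", members=[object()])
        intersect_genes([inside, outside], [transcript15])
        assert inside.gene_context == ("CD36", "tx1", "intron 1")
        assert outside.gene_context is None

    def test_gff3_round_trip(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1000\t15099\t.\t+\t.\tID=CD36\n"
            "chr1\tsrc\tmRNA\t1000\t15099\t.\t+\t.\tID=tx1;Parent=CD36\n"
            + "".join(
                f"chr1\tsrc\texon\t{1000 + i * 1000}\t{1099 + i * 1000}\t.\t+\t.\t"
                f"ID=ex{i + 1};Parent=tx1\n"
                for i in range(15)
            )
        )
        transcripts = parse_gff3_transcripts(gff)
        assert len(transcripts) == 1
        tx = transcripts[0]
        assert tx.gene_id == "CD36"
        assert len(tx.exons) == 15
        assert locate_in_transcript(tx, 1500) == "intron 1"


class TestRoundTrip:
    def test_planted_loci_recovered_exactly(self, planted_scenario, template):
        loci, _ = discover_rips(
            planted_scenario["reference"],
            planted_scenario["genomes"],
            template,
            CONFIG,
        )
        metrics = evaluate_discovery(loci, planted_scenario["truth"])
        assert metrics["recall"] == 1.0
        assert metrics["precision"] == 1.0
        assert metrics["n_loci"] == 2
        for locus in loci:
            for gid in planted_scenario["carrier_ids"]:
                assert locus.presence[gid] == "present"
            for gid in ("g3", "g4", "reference"):
                assert locus.presence[gid] == "absent"

    def test_positions_perturbed_within_gap_still_merge(self, reference, template):
        base = 30000
        specs = [
            PlantSpec(genome_id=f"g{i}", chrom="chr1", position=base + offset, seed=i)
            for i, offset in enumerate((0, 3, 7))
        ]
        genomes, truth = plant_insertions(reference, specs, template)
        loci, _ = discover_rips(reference, genomes, template, CONFIG)
        assert len(loci) == 1
        assert evaluate_discovery(loci, truth)["recall"] == 1.0

    def test_presence_symmetry_under_reference_swap(self, reference, template):
        # swapping the carrier and the reference inverts presence/absence
        spec = PlantSpec(genome_id="alt", chrom="chr1", position=30000, seed=4)
        genomes, _ = plant_insertions(reference, [spec], template, genome_ids=["alt", "other"])
        loci_fwd, _ = discover_rips(reference, genomes, template, CONFIG)
        assert len(loci_fwd) == 1
        assert loci_fwd[0].presence["alt"] == "present"
        assert loci_fwd[0].presence["other"] == "absent"

        swapped_ref = genomes["alt"]
        swapped_genomes = {"was_ref": reference, "other": genomes["other"]}
        loci_rev, _ = discover_rips(swapped_ref, swapped_genomes, template, CONFIG)
        # the insertion is now in the reference: carriers of the old screen
        # are absent in the new orientation's loci, and vice versa
        for locus in loci_rev:
            assert locus.presence.get("was_ref") != "present"
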