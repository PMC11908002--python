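"""Flank-anchored projection of ERV insertions between assemblies.

An insertion found in a non-reference assembly is located on the reference by
aligning its 500 bp upstream/downstream flanks (seed-and-extend, ungapped,
score = matches - mismatches, so a perfect 500 bp flank scores 500 and the
450 minimum admits up to 25 mismatches). Flanks mapping to multiple reference
positions are discarded; a projected point distant from every reference
element of the same family by more than the polymorphism window is a RIP
candidate; same-strand candidates within the merge gap collapse into one
locus. Presence/absence per genome is then verified by the empty-site test:
the two reference flanks must map contiguously (absent) or separated by an
element-sized gap (present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import ERVElement, annotate_genome, library_from_template
from .simulate import reverse_complement


@dataclass(frozen=True)
class DiscoveryConfig:
    """Screening parameters; defaults are the published protocol values."""

    flank_len: int = 500
    min_identity: float = 90.0
    min_score: int = 450
    aln_len_window: tuple = (450, 550)
    poly_window: int = 50  # bp; 400 is the documented alternative preset
    merge_gap: int = 10
    k: int = 15  # seed length for the internal aligner
    empty_site_slack: int = 20
    min_insertion_gap: int = 1000  # smallest flank separation read as "present"
    match_family: bool = True

    def __post_init__(self):
        if min(self.flank_len, self.min_score, self.poly_window, self.merge_gap, self.k) <= 0:
            raise ValueError("all discovery parameters must be positive")
        lo, hi = self.aln_len_window
        if not 0 <= lo <= hi <= self.flank_len + self.empty_site_slack + 100:
            raise ValueError("aln_len_window inconsistent with flank length")


@dataclass(frozen=True)
class FlankAlignment:
    query_id: str
    query_len: int
    side: str  # upstream | downstream
    target_chrom: str
    target_start: int  # 1-based inclusive
    target_end: int
    strand: str
    matches: int
    aligned_cols: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_cols

    @property
    def score(self) -> int:
        return 2 * self.matches - self.aligned_cols  # matches - mismatches


@dataclass(frozen=True)
class ProjectedInsertion:
    genome_id: str
    ref_chrom: str
    ref_position: int  # insertion occurs before this base
    strand: str
    support: str  # upstream | downstream | both
    family: str = ""


@dataclass
class RIPLocus:
    """A merged reference-anchored insertion-polymorphism locus."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str
    members: list = field(default_factory=list)
    presence: dict = field(default_factory=dict)
    gene_context: Optional[tuple] = None  # (gene_id, transcript_id, feature)
    family: str = ""


# ---------------------------------------------------------------------------
# Internal seed-and-extend aligner
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Exact k-mer position index over a genome, built once per target."""

    def __init__(self, genome: Mapping[str, str], k: int = 15):
        self.genome = genome
        self.k = k
        self.index: dict = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))


def map_flank(
    flank: str,
    target: GenomeIndex,
    config: DiscoveryConfig = DiscoveryConfig(),
    query_id: str = "",
    side: str = "upstream",
) -> list:
    """Align one flank against an indexed genome and apply the screen filters.

    Exact k-mer seeds vote for (chromosome, diagonal, strand); each candidate
    diagonal is scored by full ungapped comparison. Alignments pass when
    identity >= min_identity, score >= min_score and the aligned span falls
    inside ``aln_len_window``.
    """
    k = config.k
    if len(flank) <= k:
        return []
    results = []
    for strand, query in (("+", flank), ("-", reverse_complement(flank))):
        diagonals = set()
        starts = list(range(0, len(query) - k + 1, k))
        if starts and starts[-1] != len(query) - k:
            starts.append(len(query) - k)
        for qpos in starts:
            for chrom, tpos in target.index.get(query[qpos : qpos + k], ()):
                diagonals.add((chrom, tpos - qpos))
        for chrom, diag in sorted(diagonals):
            seq = target.genome[chrom]
            t0 = max(diag, 0)
            t1 = min(diag + len(query), len(seq))
            q0 = t0 - diag
            q1 = t1 - diag
            span = t1 - t0
            if span <= 0:
                continue
            matches = sum(a == b for a, b in zip(seq[t0:t1], query[q0:q1]))
            aln = FlankAlignment(
                query_id=query_id,
                query_len=len(flank),
                side=side,
                target_chrom=chrom,
                target_start=t0 + 1,
                target_end=t1,
                strand=strand,
                matches=matches,
                aligned_cols=span,
            )
            lo, hi = config.aln_len_window
            if (
                aln.identity >= config.min_identity
                and aln.score >= config.min_score
                and lo <= aln.aligned_cols <= hi
            ):
                results.append(aln)
    results.sort(key=lambda a: -a.score)
    return results


def load_psl(path, config: DiscoveryConfig = DiscoveryConfig(), side: str = "upstream") -> list:
    """Ingest precomputed PSL alignments and apply the same screen filters."""
    alns = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 17 or not cols[0].isdigit():
                continue  # header block
            matches, mismatches = int(cols[0]), int(cols[1])
            strand = cols[8]
            qname, qsize = cols[9], int(cols[10])
            tname = cols[13]
            tstart, tend = int(cols[15]), int(cols[16])
            aln = FlankAlignment(
                query_id=qname,
                query_len=qsize,
                side=side,
                target_chrom=tname,
                target_start=tstart + 1,  # PSL is 0-based half-open
                target_end=tend,
                strand="-" if strand.startswith("-") else "+",
                matches=matches,
                aligned_cols=matches + mismatches,
            )
            lo, hi = config.aln_len_window
            if (
                aln.identity >= config.min_identity
                and aln.score >= config.min_score
                and lo <= tend - tstart <= hi
            ):
                alns.append(aln)
    return alns


# ---------------------------------------------------------------------------
# Flank extraction and projection
# ---------------------------------------------------------------------------


def extract_flanks(
    element: ERVElement, genome: Mapping[str, str], flank_len: int = 500
):
    """The ``flank_len`` bases immediately left/right of the element interval.

    Returns ``(upstream, downstream, truncated)`` in genome orientation;
    ``truncated`` flags a flank clipped at a contig edge.
    """
    seq = genome.get(element.chrom)
    if seq is None or element.start < 1 or element.end > len(seq):
        raise ValueError(
            f"element {element.chrom}:{element.start}-{element.end} outside its contig"
        )
    up_lo = max(0, element.start - 1 - flank_len)
    upstream = seq[up_lo : element.start - 1]
    downstream = seq[element.end : element.end + flank_len]
    truncated = len(upstream) < flank_len or len(downstream) < flank_len
    return upstream, downstream, truncated


def _insertion_point(aln: FlankAlignment) -> int:
    if aln.side == "upstream":
        return aln.target_end + 1 if aln.strand == "+" else aln.target_start
    return aln.target_start if aln.strand == "+" else aln.target_end + 1


def project_insertion(
    alignments_by_side: Mapping[str, Sequence[FlankAlignment]],
    config: DiscoveryConfig = DiscoveryConfig(),
    genome_id: str = "",
    element_strand: str = "+",
    family: str = "",
) -> Optional[ProjectedInsertion]:
    """Consolidate the two flank alignments into one reference point.

    The upstream flank decides when it maps uniquely; otherwise the
    downstream flank is used. A deciding side with more than one passing
    alignment means the insertion is multi-mapping and is omitted. When both
    sides are unique their points must agree within the merge gap (the
    target-site duplication shifts one side by its length, which the gap
    absorbs).
    """
    ups = list(alignments_by_side.get("upstream", ()))
    downs = list(alignments_by_side.get("downstream", ()))
    if len(ups) > 1 and len(downs) != 1:
        return None
    deciding = None
    support = None
    if len(ups) == 1:
        deciding = ups[0]
        support = "upstream"
        if len(downs) == 1:
            p_up = _insertion_point(ups[0])
            p_down = _insertion_point(downs[0])
            if (
                ups[0].target_chrom != downs[0].target_chrom
                or abs(p_up - p_down) > config.merge_gap
            ):
                return None
            support = "both"
    elif len(downs) == 1:
        deciding = downs[0]
        support = "downstream"
    else:
        return None
    strand = element_strand if deciding.strand == "+" else ("-" if element_strand == "+" else "+")
    return ProjectedInsertion(
        genome_id=genome_id,
        ref_chrom=deciding.target_chrom,
        ref_position=_insertion_point(deciding),
        strand=strand,
        support=support,
        family=family,
    )


# ---------------------------------------------------------------------------
# Polymorphism calling and merging
# ---------------------------------------------------------------------------


def call_rips(
    projected: Sequence[ProjectedInsertion],
    reference_ervs: Sequence[ERVElement],
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list:
    """Keep projected insertions occupying a window of their own.

    A projected point is a polymorphism candidate iff no reference element of
    the same family lies within ``poly_window`` bp (a reference element at the
    same spot means the insertion is shared, not polymorphic).
    """
    candidates = []
    for ins in projected:
        clash = False
        for erv in reference_ervs:
            if erv.chrom != ins.ref_chrom:
                continue
            if config.match_family and ins.family and erv.family and erv.family != ins.family:
                continue
            if ins.ref_position < erv.start:
                dist = erv.start - ins.ref_position
            elif ins.ref_position > erv.end:
                dist = ins.ref_position - erv.end
            else:
                dist = 0
            if dist <= config.poly_window:
                clash = True
                break
        if not clash:
            candidates.append(ins)
    return candidates


def _as_interval(item):
    if isinstance(item, RIPLocus):
        return item.ref_chrom, item.ref_start, item.ref_end, item.strand, list(item.members), item.family
    return (
        item.ref_chrom,
        item.ref_position,
        item.ref_position,
        item.strand,
        [item],
        item.family,
    )


def merge_rips(
    candidates: Sequence,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list:
    """Collapse same-strand candidates within ``merge_gap`` bp into loci.

    Accepts projected insertions or already-merged loci, so the operation is
    idempotent; opposite strands never merge.
    """
    items = [_as_interval(c) for c in candidates]
    groups: dict = {}
    for chrom, start, end, strand, members, family in items:
        groups.setdefault((chrom, strand), []).append((start, end, members, family))
    loci = []
    for (chrom, strand), rows in groups.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        cur = None
        for start, end, members, family in rows:
            if cur is not None and start - cur.ref_end <= config.merge_gap:
                cur.ref_end = max(cur.ref_end, end)
                cur.members.extend(members)
                cur.family = cur.family or family
            else:
                cur = RIPLocus(
                    ref_chrom=chrom,
                    ref_start=start,
                    ref_end=end,
                    strand=strand,
                    members=list(members),
                    family=family,
                )
                loci.append(cur)
    loci.sort(key=lambda l: (l.ref_chrom, l.ref_start, l.strand))
    return loci


# ---------------------------------------------------------------------------
# Presence / absence over genomes
# ---------------------------------------------------------------------------


def assess_presence(
    loci: Sequence[RIPLocus],
    reference: Mapping[str, str],
    genome_indexes: Mapping[str, GenomeIndex],
    config: DiscoveryConfig = DiscoveryConfig(),
) -> None:
    """Fill each locus's presence map by the empty-site test.

    For every genome, the locus's two reference flanks are mapped: uniquely
    mapped and contiguous (within the slack) means the empty reference allele
    (absent); separated by at least ``min_insertion_gap`` means an insertion
    (present); anything else is unknown. Genomes that contributed a projected
    member are present by construction.
    """
    for locus in loci:
        ref_seq = reference[locus.ref_chrom]
        s, e = locus.ref_start, locus.ref_end
        carrier_span = e - s + 1 if getattr(locus, "ref_carrier", False) else 0
        up = ref_seq[max(0, s - 1 - config.flank_len) : s - 1]
        down_start = s - 1 + carrier_span
        down = ref_seq[down_start : down_start + config.flank_len]
        member_genomes = {m.genome_id for m in locus.members}
        for gid, gindex in genome_indexes.items():
            if gid in member_genomes:
                locus.presence[gid] = "present"
                continue
            ups = map_flank(up, gindex, config, side="upstream")
            downs = map_flank(down, gindex, config, side="downstream")
            if len(ups) != 1 or len(downs) != 1:
                locus.presence[gid] = "unknown"
                continue
            u, d = ups[0], downs[0]
            if u.target_chrom != d.target_chrom or u.strand != d.strand:
                locus.presence[gid] = "unknown"
                continue
            if u.strand == "+":
                gap = d.target_start - u.target_end - 1
            else:
                gap = u.target_start - d.target_end - 1
            gap -= carrier_span  # a carrier reference contributes its own span
            if abs(gap) <= config.empty_site_slack:
                locus.presence[gid] = "absent"
            elif gap >= config.min_insertion_gap:
                locus.presence[gid] = "present"
            else:
                locus.presence[gid] = "unknown"


# ---------------------------------------------------------------------------
# Gene intersection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end), ascending genomic order


def parse_gff3_transcripts(path) -> list:
    """Read transcripts with ordered exons from a GFF3 annotation."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    transcripts = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        gene = tx.attributes.get("Parent", [tx.id])[0]
        transcripts.append(
            Transcript(
                gene_id=gene,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=tuple(exons),
            )
        )
    return transcripts


def locate_in_transcript(tx: Transcript, position: int) -> Optional[str]:
    """'exon k' / 'intron k' in transcript orientation, or None if outside."""
    n = len(tx.exons)
    if position < tx.exons[0][0] or position > tx.exons[-1][1]:
        return None
    for j, (start, end) in enumerate(tx.exons, start=1):
        if start <= position <= end:
            k = j if tx.strand == "+" else n + 1 - j
            return f"exon {k}"
        if position < start:  # in the intron before genomic exon j
            k = j - 1 if tx.strand == "+" else n - (j - 1)
            return f"intron {k}"
    return None


def intersect_genes(loci: Sequence[RIPLocus], transcripts: Sequence[Transcript]) -> None:
    """Label each locus with (gene, transcript, feature) or leave it None."""
    for locus in loci:
        locus.gene_context = None
        for tx in transcripts:
            if tx.chrom != locus.ref_chrom:
                continue
            feature = locate_in_transcript(tx, locus.ref_start)
            if feature is not None:
                locus.gene_context = (tx.gene_id, tx.transcript_id, feature)
                break


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def discover_rips(
    reference: Mapping[str, str],
    genomes: Mapping[str, Mapping[str, str]],
    template,
    config: DiscoveryConfig = DiscoveryConfig(),
    reference_id: str = "reference",
    transcripts: Optional[Sequence[Transcript]] = None,
) -> tuple:
    """Run the whole screen: annotate, project, call, merge, genotype in silico.

    Returns ``(loci, elements_by_genome)``; the presence map of every locus
    covers the reference and all non-reference genomes.
    """
    library = library_from_template(template)
    ref_index = GenomeIndex(reference, k=config.k)
    ref_elements = annotate_genome(reference, library, genome_id=reference_id, template=template)

    projected = []
    elements_by_genome = {}
    for gid, genome in genomes.items():
        elements = annotate_genome(genome, library, genome_id=gid, template=template)
        elements_by_genome[gid] = elements
        for element in elements:
            if not element.full_length:
                continue
            upstream, downstream, _ = extract_flanks(element, genome, config.flank_len)
            alns = {
                "upstream": map_flank(upstream, ref_index, config, query_id=gid, side="upstream"),
                "downstream": map_flank(
                    downstream, ref_index, config, query_id=gid, side="downstream"
                ),
            }
            ins = project_insertion(
                alns,
                config,
                genome_id=gid,
                element_strand=element.strand,
                family=element.family,
            )
            if ins is not None:
                projected.append(ins)

    candidates = call_rips(projected, ref_elements, config)
    loci = merge_rips(candidates, config)

    genome_indexes = {gid: GenomeIndex(g, k=config.k) for gid, g in genomes.items()}
    genome_indexes[reference_id] = ref_index
    assess_presence(loci, reference, genome_indexes, config)
    if transcripts:
        intersect_genes(loci, transcripts)
    return loci, elements_by_genome


def evaluate_discovery(
    loci: Sequence[RIPLocus], truth: pd.DataFrame, tolerance: int = 10
) -> dict:
    """Recall/precision of discovered loci against a planted-truth table."""
    truth_sites = []
    for (chrom, _pos), grp in truth.groupby(["chrom", "position"]):
        truth_sites.append((chrom, int(grp["position"].iloc[0]), set(grp["genome_id"])))
    matched_truth = set()
    matched_loci = set()
    for i, locus in enumerate(loci):
        for j, (chrom, pos, _genomes) in enumerate(truth_sites):
            if locus.ref_chrom == chrom and (
                locus.ref_start - tolerance <= pos <= locus.ref_end + tolerance
            ):
                matched_truth.add(j)
                matched_loci.add(i)
    recall = len(matched_truth) / len(truth_sites) if truth_sites else 1.0
    precision = len(matched_loci) / len(loci) if loci else 1.0
    return {
        "n_truth": len(truth_sites),
        "n_loci": len(loci),
        "recall": recall,
        "precision": precision,
    }
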