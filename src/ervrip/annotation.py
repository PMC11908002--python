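"""Structural characterization of ERV elements.

An endogenous retrovirus is carried as LTR-gag-pro-pol-env-LTR; elements
longer than 5 kb with both LTRs and the Gag/Pol/Env coding domains are
"full length". Because the two LTRs are identical at integration, their
Kimura two-parameter divergence K dates the insertion as T = K / (2r) for a
host substitution rate r (default 2.2e-9 substitutions/site/year).

Coordinates are 1-based inclusive throughout, so an element printed as
41,862,971..41,870,900 has length end - start + 1 = 7,930 bp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .simulate import reverse_complement

DEFAULT_SUBSTITUTION_RATE = 2.2e-9  # subs/site/year, LTR-dating default
FULL_LENGTH_MIN_BP = 5000
REQUIRED_DOMAINS = frozenset({"Gag", "Pol", "Env"})

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class RepeatMaskerParseError(ValueError):
    """A line of a RepeatMasker ``.out`` file could not be parsed."""


class SaturationError(ValueError):
    """The Kimura two-parameter distance is undefined (log of <= 0)."""


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval: end - start + 1."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start + 1


# ---------------------------------------------------------------------------
# Repeat hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatHit:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # + or -
    family: str
    divergence: float  # percent mismatch to the library consensus
    score: int = 0


def parse_repeatmasker_out(path) -> list:
    """Parse a RepeatMasker ``.out`` file into :class:`RepeatHit` rows.

    The format has three header lines followed by whitespace-delimited
    columns; query coordinates are 1-based inclusive and orientation ``C``
    means the minus strand.
    """
    hits = []
    with open(path) as fh:
        lines = fh.readlines()
    for line_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if line_no <= 3 and not stripped.split()[0].isdigit():
            continue  # the three-line banner
        cols = stripped.split()
        if len(cols) < 14:
            raise RepeatMaskerParseError(
                f"line {line_no}: expected >= 14 columns, got {len(cols)}"
            )
        try:
            score = int(cols[0])
            divergence = float(cols[1])
            chrom = cols[4]
            start = int(cols[5])
            end = int(cols[6])
            strand = "-" if cols[8] == "C" else "+"
            family = cols[9]
        except (ValueError, IndexError) as exc:
            raise RepeatMaskerParseError(f"line {line_no}: {exc}") from exc
        hits.append(
            RepeatHit(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                family=family,
                divergence=divergence,
                score=score,
            )
        )
    return hits


def library_from_template(template) -> dict:
    """LTR and internal consensus sequences keyed like a masking library."""
    return {
        f"{template.family_name}-LTR": template.ltr_seq,
        f"{template.family_name}-int": template.internal_seq,
    }


def scan_repeats(
    genome: Mapping[str, str],
    library: Mapping[str, str],
    k: int = 15,
    max_divergence: float = 0.10,
) -> list:
    """Locate near-exact copies of library consensus sequences in a genome.

    Exact k-mer seeds vote for alignment diagonals; each candidate diagonal is
    verified by a full-length ungapped comparison and kept when the mismatch
    fraction is at most ``max_divergence``. Both strands are searched. This
    stands in for an external masking run when annotating simulated genomes;
    real RepeatMasker output is ingested via :func:`parse_repeatmasker_out`.
    """
    hits = []
    for chrom, seq in genome.items():
        index: dict = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        for name, consensus in library.items():
            for strand, query in (("+", consensus), ("-", reverse_complement(consensus))):
                diagonals = set()
                starts = list(range(0, len(query) - k + 1, k))
                if starts and starts[-1] != len(query) - k:
                    starts.append(len(query) - k)
                for qpos in starts:
                    for tpos in index.get(query[qpos : qpos + k], ()):
                        diagonals.add(tpos - qpos)
                for diag in sorted(diagonals):
                    if diag < 0 or diag + len(query) > len(seq):
                        continue
                    window = seq[diag : diag + len(query)]
                    mismatches = sum(a != b for a, b in zip(window, query))
                    rate = mismatches / len(query)
                    if rate <= max_divergence:
                        hits.append(
                            RepeatHit(
                                chrom=chrom,
                                start=diag + 1,
                                end=diag + len(query),
                                strand=strand,
                                family=name,
                                divergence=round(rate * 100, 2),
                                score=len(query) - 2 * mismatches,
                            )
                        )
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits


# ---------------------------------------------------------------------------
# Elements
# ---------------------------------------------------------------------------


@dataclass
class ERVElement:
    """An annotated proviral interval (1-based inclusive coordinates)."""

    genome_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    ltr5_span: Optional[tuple] = None  # absolute (start, end)
    ltr3_span: Optional[tuple] = None
    ltr_similarity: Optional[int] = None  # nearest integer percent
    domains: tuple = ()  # of (name, aa_length)
    full_length: bool = False

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    def sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom][self.start - 1 : self.end]
        return reverse_complement(seq) if self.strand == "-" else seq


def _base_family(family: str) -> str:
    return re.sub(r"[-_](LTR|int)$", "", family)


def assemble_elements(
    hits: Sequence[RepeatHit],
    genome_id: str = "",
    max_join_gap: int = 1000,
) -> list:
    """Chain same-family, same-strand hits within ``max_join_gap`` bp into
    candidate elements spanning min(start)..max(end)."""
    groups: dict = {}
    for hit in hits:
        groups.setdefault((hit.chrom, _base_family(hit.family), hit.strand), []).append(hit)
    elements = []
    for (chrom, family, strand), members in groups.items():
        members.sort(key=lambda h: h.start)
        cluster = [members[0]]
        for hit in members[1:]:
            if hit.start - cluster[-1].end - 1 <= max_join_gap:
                cluster.append(hit)
            else:
                elements.append(
                    ERVElement(genome_id, chrom, cluster[0].start, max(h.end for h in cluster), strand, family)
                )
                cluster = [hit]
        elements.append(
            ERVElement(genome_id, chrom, cluster[0].start, max(h.end for h in cluster), strand, family)
        )
    elements.sort(key=lambda e: (e.chrom, e.start))
    return elements


def classify_full_length(
    element: ERVElement,
    min_length: int = FULL_LENGTH_MIN_BP,
    required_domains: frozenset = REQUIRED_DOMAINS,
) -> bool:
    """Full length: > 5 kb, both LTRs detected, Gag/Pol/Env domains present."""
    names = {name for name, _ in element.domains}
    return (
        element.length > min_length
        and element.ltr5_span is not None
        and element.ltr3_span is not None
        and required_domains <= names
    )


# ---------------------------------------------------------------------------
# LTR detection and comparison
# ---------------------------------------------------------------------------


def _alignment_identity(alignment) -> tuple:
    """(matches, aligned_columns) for a Bio.Align alignment, gaps counted."""
    target = alignment.target
    query = alignment.query
    blocks_t, blocks_q = alignment.aligned
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)
        seg_t = target[t0:t1]
        seg_q = query[q0:q1]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += t1 - t0
        prev_t, prev_q = t1, q1
    return matches, columns


def detect_ltrs(
    seq: str,
    min_len: int = 100,
    min_identity: float = 80.0,
    max_ltr_len: int = 1500,
):
    """Find the highest-scoring terminal direct repeat of a proviral sequence.

    The first and last ``max_ltr_len`` bp are locally aligned (gap-tolerant);
    returns ``((ltr5_start, ltr5_end), (ltr3_start, ltr3_end), similarity)``
    in 1-based element coordinates with similarity as the nearest integer
    percent of matching columns, or ``None`` if nothing reaches ``min_len``
    and ``min_identity``.
    """
    if len(seq) <= 2 * min_len:
        raise ValueError("sequence too short for terminal-repeat detection")
    window = min(max_ltr_len, len(seq) // 2)
    head = seq[:window]
    tail = seq[-window:]
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    alignments = aligner.align(head, tail)
    try:
        best = alignments[0]
    except IndexError:
        return None
    matches, columns = _alignment_identity(best)
    if columns == 0:
        return None
    identity = 100.0 * matches / columns
    blocks_t, blocks_q = best.aligned
    t0, t1 = blocks_t[0][0], blocks_t[-1][1]
    q0, q1 = blocks_q[0][0], blocks_q[-1][1]
    if min(t1 - t0, q1 - q0) < min_len or identity < min_identity:
        return None
    offset = len(seq) - window
    span5 = (t0 + 1, t1)
    span3 = (offset + q0 + 1, offset + q1)
    return span5, span3, int(round(identity))


# ---------------------------------------------------------------------------
# Kimura two-parameter divergence and insertion dating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceEstimate:
    """Kimura 2-parameter summary of an aligned pair of sequences."""

    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # K2P distance, substitutions/site
    n_sites: int
    r: Optional[float] = None  # substitution rate used for dating
    T: Optional[float] = None  # age in years, K / (2 r)


def kimura_k2p(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """K2P distance from an aligned pair; gap/ambiguous columns are excluded.

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions over comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    transitions = transversions = sites = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        sites += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"divergence saturated (1-2P-Q={w1:.4f}, 1-2Q={w2:.4f})"
        )
    K = -0.5 * np.log(w1 * np.sqrt(w2))
    return DivergenceEstimate(P=P, Q=Q, K=float(K), n_sites=sites)


def estimate_insertion_age(K: float, r: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """Insertion age T = K / (2 r) years from inter-LTR divergence."""
    if r <= 0:
        raise ValueError("substitution rate must be > 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * r)


def date_element(
    seq: str,
    ltr5_span: tuple,
    ltr3_span: tuple,
    r: float = DEFAULT_SUBSTITUTION_RATE,
) -> DivergenceEstimate:
    """Align the two LTR copies globally and date the element from their K2P."""
    ltr5 = seq[ltr5_span[0] - 1 : ltr5_span[1]]
    ltr3 = seq[ltr3_span[0] - 1 : ltr3_span[1]]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    best = aligner.align(ltr5, ltr3)[0]
    est = kimura_k2p(str(best[0]), str(best[1]))
    return replace(est, r=r, T=estimate_insertion_age(est.K, r))


# ---------------------------------------------------------------------------
# ORF / domain layout
# ---------------------------------------------------------------------------


def _orfs_in_frame(seq: str, frame: int, min_aa: int):
    """Yield (nt_start0, nt_end0_exclusive, aa_len) of ATG..stop ORFs."""
    i = frame
    start = None
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in ("TAA", "TAG", "TGA"):
            aa_len = (i - start) // 3  # includes the initiator Met
            if aa_len >= min_aa:
                yield start, i + 3, aa_len
            start = None
        i += 3


def find_orf_domains(
    seq: str,
    min_aa: int = 100,
    domain_table=None,
    layout: Optional[Sequence] = None,
    layout_offset: int = 0,
) -> list:
    """Report ORFs of at least ``min_aa`` amino acids across all six frames.

    A supplied ``domain_table`` (TSV with ``domain`` and ``aa_length``
    columns, e.g. exported from an external profile search) takes precedence.
    Otherwise ORF spans are named by their best overlap with a declared
    template ``layout`` of (name, start, end) spans (1-based, shifted by
    ``layout_offset`` into element coordinates); unmatched ORFs are labelled
    ``ORF``. Returns a list of ``(name, aa_length)``.
    """
    if domain_table is not None:
        if not isinstance(domain_table, pd.DataFrame):
            try:
                domain_table = pd.read_csv(domain_table, sep="\t")
            except Exception as exc:
                raise ValueError(f"malformed domain table: {exc}") from exc
        if not {"domain", "aa_length"} <= set(domain_table.columns):
            raise ValueError("domain table needs 'domain' and 'aa_length' columns")
        return [
            (row["domain"], int(row["aa_length"])) for _, row in domain_table.iterrows()
        ]

    seq = seq.upper()
    found = []  # (span_start1, span_end1, aa_len, strand)
    for frame in range(3):
        for s0, e0, aa in _orfs_in_frame(seq, frame, min_aa):
            found.append((s0 + 1, e0, aa))
    rc = reverse_complement(seq)
    for frame in range(3):
        for s0, e0, aa in _orfs_in_frame(rc, frame, min_aa):
            # map back to forward coordinates
            found.append((len(seq) - e0 + 1, len(seq) - s0, aa))
    found.sort()

    results = []
    for start, end, aa in found:
        name = "ORF"
        if layout:
            best_frac = 0.0
            for lname, lstart, lend in layout:
                ls, le = lstart + layout_offset, lend + layout_offset
                overlap = min(end, le) - max(start, ls) + 1
                frac = overlap / (le - ls + 1)
                if overlap > 0 and frac > best_frac:
                    best_frac = frac
                    if frac >= 0.5:
                        name = lname
        results.append((name, aa))
    return results


# ---------------------------------------------------------------------------
# End-to-end characterization and reporting
# ---------------------------------------------------------------------------


def characterize_element(
    element: ERVElement,
    genome: Mapping[str, str],
    template=None,
    min_aa: int = 100,
    domain_table=None,
) -> ERVElement:
    """Fill LTR spans/similarity, domains and full-length status in place."""
    seq = element.sequence(genome)
    ltrs = detect_ltrs(seq) if len(seq) > 300 else None
    if ltrs is not None:
        span5, span3, similarity = ltrs
        element.ltr5_span = (element.start + span5[0] - 1, element.start + span5[1] - 1)
        element.ltr3_span = (element.start + span3[0] - 1, element.start + span3[1] - 1)
        element.ltr_similarity = similarity
        layout_offset = span5[1]  # internal coordinates begin after the 5' LTR
    else:
        layout_offset = 0
    layout = template.domain_layout if template is not None else None
    element.domains = tuple(
        (n, aa)
        for n, aa in find_orf_domains(
            seq,
            min_aa=min_aa,
            domain_table=domain_table,
            layout=layout,
            layout_offset=layout_offset,
        )
        if n != "ORF"
    )
    element.full_length = classify_full_length(element)
    return element


def annotate_genome(
    genome: Mapping[str, str],
    library: Mapping[str, str],
    genome_id: str = "",
    template=None,
    max_join_gap: int = 1000,
) -> list:
    """Scan, assemble and characterize ERV elements in one genome."""
    hits = scan_repeats(genome, library)
    elements = assemble_elements(hits, genome_id=genome_id, max_join_gap=max_join_gap)
    return [characterize_element(e, genome, template=template) for e in elements]


def elements_to_table(elements: Sequence[ERVElement]) -> pd.DataFrame:
    """Carrier-table report: one row per element with LTR and domain summary."""
    rows = []
    for e in elements:
        aa = dict(e.domains)
        ltr_lens = (
            f"{interval_length(*e.ltr5_span)}/{interval_length(*e.ltr3_span)}"
            if e.ltr5_span and e.ltr3_span
            else ""
        )
        rows.append(
            {
                "genome": e.genome_id,
                "location": f"{e.chrom}:{e.start}-{e.end}",
                "strand": e.strand,
                "length_bp": e.length,
                "ltr_similarity_pct": e.ltr_similarity,
                "gag_aa": aa.get("Gag"),
                "pro_aa": aa.get("Pro"),
                "pol_aa": aa.get("Pol"),
                "env_aa": aa.get("Env"),
                "ltr_lengths": ltr_lens,
                "full_length": e.full_length,
            }
        )
    return pd.DataFrame(rows)


def elements_to_gff3(path, elements: Sequence[ERVElement]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(elements):
            attrs = f"ID=erv{i + 1};family={e.family};full_length={str(e.full_length).lower()}"
            fh.write(
                f"{e.chrom}\tervrip\tmobile_genetic_element\t{e.start}\t{e.end}\t.\t"
                f"{e.strand}\t.\t{attrs}\n"
            )
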