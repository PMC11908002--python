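"""Synthetic genomes, proviruses, populations and band patterns.

Everything downstream of this module (annotation, discovery, genotyping,
population genetics, association) is exercised against data produced here,
with full ground truth: reference assemblies are i.i.d. random backbones,
full-length proviruses (LTR-internal-LTR with Gag/Pro/Pol/Env ORFs) are
planted at chosen positions with target-site duplications, and diploid
populations are drawn from Hardy-Weinberg proportions with additive
fixed-effect trait values Y = mu + G_i + B_j + S_k + e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: genotype labels used throughout the package
GENOTYPES = ("+/+", "+/-", "-/-")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# ERV template
# ---------------------------------------------------------------------------

_DOMAIN_ORDER = ("Gag", "Pro", "Pol", "Env")


@dataclass(frozen=True)
class ERVTemplate:
    """A proviral sequence template: identical LTRs flanking an internal region.

    ``domain_layout`` holds ``(name, start, end)`` spans in 1-based internal
    coordinates, covering the ORF from its ATG through the stop codon, so the
    encoded protein length is ``(end - start + 1) / 3 - 1`` amino acids.
    """

    family_name: str
    ltr_seq: str
    internal_seq: str
    domain_layout: tuple = ()

    def __post_init__(self):
        prev_end = 0
        seen = []
        for name, start, end in self.domain_layout:
            if start <= prev_end:
                raise ValueError(f"domain {name} overlaps or is out of order")
            if end > len(self.internal_seq):
                raise ValueError(f"domain {name} extends past the internal region")
            prev_end = end
            seen.append(name)
        named = [n for n in seen if n in _DOMAIN_ORDER]
        if named != [d for d in _DOMAIN_ORDER if d in named]:
            raise ValueError("domains must appear in Gag < Pro < Pol < Env order")

    @property
    def total_length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    def domain_aa_lengths(self) -> dict:
        return {
            name: (end - start + 1) // 3 - 1 for name, start, end in self.domain_layout
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def _random_orf(rng: np.random.Generator, aa_length: int) -> str:
    """ATG + (aa_length - 1) random non-stop codons + stop codon."""
    codons = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
    sense = [c for c in codons if c not in STOP_CODONS]
    body = rng.choice(sense, size=aa_length - 1)
    return "ATG" + "".join(body) + "TAA"


# Study conditions for the default provirus: 444 bp LTRs and a 7,042 bp
# internal region (total 7,930 bp), encoding Gag 531 / Pro 278 / Pol 696 /
# Env 441 aa -- the reference-carrier structure of the CD36-intronic
# beta-retroviral element this package models.
_TEMPLATE_SEED = 1913
_DEFAULT_LTR_LEN = 444
_DEFAULT_INTERNAL_LEN = 7042
_DEFAULT_DOMAINS_AA = (("Gag", 531), ("Pro", 278), ("Pol", 696), ("Env", 441))


def default_template(family_name: str = "Ov-ERV-R13") -> ERVTemplate:
    """Deterministic full-length template with the default study geometry."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    ltr = _random_seq(rng, _DEFAULT_LTR_LEN)
    # lay the four ORFs head-to-tail with short untranslated spacers
    layout = []
    internal = []
    cursor = 1
    spacers = (200, 6, 10, 10)
    for (name, aa), spacer in zip(_DEFAULT_DOMAINS_AA, spacers):
        internal.append(_random_seq(rng, spacer))
        cursor += spacer
        orf = _random_orf(rng, aa)
        layout.append((name, cursor, cursor + len(orf) - 1))
        internal.append(orf)
        cursor += len(orf)
    tail = _DEFAULT_INTERNAL_LEN - (cursor - 1)
    if tail < 0:
        raise AssertionError("domain layout exceeds internal length")
    internal.append(_random_seq(rng, tail))
    return ERVTemplate(
        family_name=family_name,
        ltr_seq=ltr,
        internal_seq="".join(internal),
        domain_layout=tuple(layout),
    )


def build_erv_element(
    template: ERVTemplate, ltr_divergence: float, seed: int
) -> str:
    """Assemble 5'LTR + internal + 3'LTR, mutating the 3' LTR.

    The number of substitutions is a seeded binomial draw at the requested
    per-site rate; positions are uniform without replacement and transitions
    outnumber transversions 2:1 so both Kimura proportions are non-zero.
    """
    if not 0 <= ltr_divergence < 0.5:
        raise ValueError(f"ltr_divergence must be in [0, 0.5), got {ltr_divergence}")
    rng = np.random.default_rng(seed)
    ltr3 = mutate_sequence(template.ltr_seq, ltr_divergence, rng)
    return template.ltr_seq + template.internal_seq + ltr3


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute a Binomial(len, rate) draw of sites, ts:tv = 2:1."""
    n_sub = int(rng.binomial(len(seq), rate)) if rate > 0 else 0
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        base = out[pos]
        if rng.random() < 2.0 / 3.0:
            out[pos] = _TRANSITION[base]
        else:
            tv = [b for b in NUCLEOTIDES if b != base and b != _TRANSITION[base]]
            out[pos] = tv[int(rng.integers(0, 2))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference backbones and planted insertions
# ---------------------------------------------------------------------------


def random_genome(chrom_lengths: Mapping[str, int], seed: int) -> dict:
    """I.i.d. uniform ACGT backbone, one sequence per chromosome."""
    rng = np.random.default_rng(seed)
    return {name: _random_seq(rng, length) for name, length in chrom_lengths.items()}


def flanks_are_unique(
    genome: Mapping[str, str], chrom: str, position: int, flank: int = 500, k: int = 20
) -> bool:
    """True if every k-mer in the +/- ``flank`` window around ``position``
    occurs exactly once in the whole genome (multi-mapping screen)."""
    seq = genome[chrom]
    lo = max(0, position - 1 - flank)
    hi = min(len(seq), position - 1 + flank)
    window = seq[lo:hi]
    haystack = "".join(genome.values())
    for i in range(len(window) - k + 1):
        kmer = window[i : i + k]
        if haystack.count(kmer) != 1:
            return False
    return True


def choose_plant_positions(
    genome: Mapping[str, str],
    chrom: str,
    n: int,
    rng: np.random.Generator,
    flank: int = 500,
    min_gap: int = 3000,
    max_tries: int = 1000,
) -> list:
    """Draw ``n`` insertion points with unique flanks and pairwise separation."""
    length = len(genome[chrom])
    chosen: list = []
    for _ in range(max_tries):
        if len(chosen) == n:
            break
        pos = int(rng.integers(flank + 1, length - flank))
        if any(abs(pos - p) < min_gap for p in chosen):
            continue
        if not flanks_are_unique(genome, chrom, pos, flank=flank):
            continue
        chosen.append(pos)
    if len(chosen) < n:
        raise RuntimeError("could not place the requested number of insertions")
    return sorted(chosen)


@dataclass(frozen=True)
class PlantSpec:
    """One planted insertion: genome, site, strand, TSD and LTR divergence."""

    genome_id: str
    chrom: str
    position: int  # 1-based; the element is inserted before this base
    strand: str = "+"
    tsd_len: int = 6
    ltr_divergence: float = 0.0
    truncation: Optional[tuple] = None  # (side in {"5","3"}, bp removed)
    seed: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if not 0 <= self.ltr_divergence < 0.5:
            raise ValueError("ltr_divergence must be in [0, 0.5)")


def plant_insertions(
    reference: Mapping[str, str],
    specs: Sequence[PlantSpec],
    template: ERVTemplate,
    genome_ids: Optional[Sequence[str]] = None,
):
    """Insert the templated element into copies of the reference.

    Returns ``(genomes, truth)``: ``genomes`` maps genome_id -> {chrom: seq}
    (genome_ids listed without a spec receive an unmodified copy), and
    ``truth`` is a DataFrame of planted loci (genome_id, chrom, position,
    strand, element_length, tsd_len, ltr_divergence).

    The ``tsd_len`` reference bases starting at ``position`` are duplicated so
    that one copy flanks each side of the element, as at a real integration
    site.
    """
    ids = list(genome_ids) if genome_ids is not None else []
    for spec in specs:
        if spec.genome_id not in ids:
            ids.append(spec.genome_id)
        if spec.chrom not in reference:
            raise ValueError(f"unknown chromosome {spec.chrom!r}")
        if not 1 <= spec.position <= len(reference[spec.chrom]) - spec.tsd_len + 1:
            raise ValueError(
                f"position {spec.position} outside chromosome {spec.chrom!r}"
            )
    by_genome: dict = {gid: [] for gid in ids}
    for spec in specs:
        by_genome[spec.genome_id].append(spec)
    for gid, gspecs in by_genome.items():
        gspecs.sort(key=lambda s: (s.chrom, s.position))
        for a, b in zip(gspecs, gspecs[1:]):
            if a.chrom == b.chrom and b.position - a.position <= max(a.tsd_len, 1):
                raise ValueError(f"overlapping plants in genome {gid!r}")

    genomes: dict = {}
    rows = []
    for gid in ids:
        seqs = dict(reference)
        # apply right-to-left so earlier coordinates stay valid
        for spec in sorted(by_genome[gid], key=lambda s: -s.position):
            element = build_erv_element(template, spec.ltr_divergence, spec.seed)
            if spec.truncation is not None:
                side, removed = spec.truncation
                element = element[removed:] if side == "5" else element[: len(element) - removed]
            if spec.strand == "-":
                element = reverse_complement(element)
            seq = seqs[spec.chrom]
            p0 = spec.position - 1
            tsd = seq[p0 : p0 + spec.tsd_len]
            seqs[spec.chrom] = seq[:p0] + tsd + element + seq[p0:]
            rows.append(
                {
                    "genome_id": gid,
                    "chrom": spec.chrom,
                    "position": spec.position,
                    "strand": spec.strand,
                    "element_length": len(element),
                    "tsd_len": spec.tsd_len,
                    "ltr_divergence": spec.ltr_divergence,
                }
            )
        genomes[gid] = seqs
    truth = pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "chrom",
            "position",
            "strand",
            "element_length",
            "tsd_len",
            "ltr_divergence",
        ],
    )
    return genomes, truth.sort_values(["genome_id", "chrom", "position"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Populations and traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Breed-structured diploid population with additive trait effects.

    Trait values follow Y = mu + G_i + B_j + S_k + e, e ~ Normal(0, sigma_e^2);
    genotypes are drawn from Hardy-Weinberg proportions at each breed's
    insertion-allele frequency p.
    """

    breeds: tuple  # of (label, n, insertion_allele_freq)
    mu: float = 0.0
    genotype_effects: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GENOTYPES}
    )
    breed_effects: Mapping[str, float] = field(default_factory=dict)
    sex_effects: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.0, "F": 0.0}
    )
    sex_ratio: float = 0.5  # proportion of males
    residual_sd: float = 1.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self):
        for label, n, p in self.breeds:
            if n <= 0:
                raise ValueError(f"breed {label!r}: n must be > 0")
            if not 0 <= p <= 1:
                raise ValueError(f"breed {label!r}: allele frequency out of [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw animals (breed, sex, HWE genotype) and their trait values."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for label, n, p in spec.breeds:
        q = 1.0 - p
        probs = np.array([p * p, 2 * p * q, q * q])
        genos = rng.choice(GENOTYPES, size=n, p=probs / probs.sum())
        sexes = np.where(rng.random(n) < spec.sex_ratio, "M", "F")
        noise = rng.normal(0.0, spec.residual_sd, size=n) if spec.residual_sd > 0 else np.zeros(n)
        for g, s, e in zip(genos, sexes, noise):
            counter += 1
            y = (
                spec.mu
                + spec.genotype_effects.get(g, 0.0)
                + spec.breed_effects.get(label, 0.0)
                + spec.sex_effects.get(s, 0.0)
                + e
            )
            rows.append(
                {
                    "animal_id": f"A{counter:05d}",
                    "breed": label,
                    "sex": s,
                    "genotype": g,
                    spec.trait_name: y,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Band patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandPattern:
    """Observed PCR band sizes (bp) for one animal at one locus."""

    sizes: tuple

    def __post_init__(self):
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")


def simulate_band_pattern(
    genotype: str, assay, dropout_rate: float = 0.0, seed: int = 0
) -> BandPattern:
    """Expected dual-assay bands for a genotype, with optional band dropout.

    Homozygous carriers show only the insertion-allele product, homozygous
    non-carriers only the empty-site product, heterozygotes both.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(seed)
    bands = []
    if genotype in ("+/+", "+/-"):
        bands.append(assay.expected_ins_product)
    if genotype in ("-/-", "+/-"):
        bands.append(assay.expected_abs_product)
    kept = tuple(b for b in bands if rng.random() >= dropout_rate)
    return BandPattern(sizes=kept)


# ---------------------------------------------------------------------------
# Genome-survey scenario
# ---------------------------------------------------------------------------


def genome_survey_scenario(
    seed: int,
    chrom_length: int = 60000,
    n_genomes: int = 43,
    carriers: Sequence[int] = (22, 10, 30),
    tsd_len: int = 6,
):
    """One reference plus ``n_genomes - 1`` non-reference assemblies with
    planted full-length elements at ``len(carriers)`` shared sites.

    ``carriers[i]`` non-reference genomes carry the element at site ``i``;
    the first entry defaults to 22 so that, reference included, the panel
    splits 22 carriers / 21 empty sites at that locus — the published
    43-genome survey structure this generator emulates.

    Returns a dict with ``reference``, ``genomes``, ``truth``, ``positions``,
    ``template`` and ``reference_id``.
    """
    if max(carriers) > n_genomes - 1:
        raise ValueError("more carriers than non-reference genomes")
    rng = np.random.default_rng(seed)
    reference = random_genome({"chr1": chrom_length}, seed=int(rng.integers(2**31)))
    positions = choose_plant_positions(reference, "chr1", len(carriers), rng)
    template = default_template()
    ids = [f"g{i + 1:02d}" for i in range(n_genomes - 1)]
    specs = []
    for pos, n_carry in zip(positions, carriers):
        chosen = rng.choice(ids, size=n_carry, replace=False)
        for gid in chosen:
            specs.append(
                PlantSpec(
                    genome_id=str(gid),
                    chrom="chr1",
                    position=pos,
                    tsd_len=tsd_len,
                    ltr_divergence=0.0,
                    seed=int(rng.integers(2**31)),
                )
            )
    genomes, truth = plant_insertions(reference, specs, template, genome_ids=ids)
    return {
        "reference": reference,
        "genomes": genomes,
        "truth": truth,
        "positions": positions,
        "template": template,
        "reference_id": "reference",
    }


# ---------------------------------------------------------------------------
# Synthetic stand-in for the published CD36 locus sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticLocus:
    """A synthetic presence/absence locus with both allele sequences."""

    ins_allele: str
    abs_allele: str
    primers: Mapping[str, str]
    insertion_point: int  # 1-based in the absence allele
    tsd_len: int


def synthetic_cd36_locus(seed: int = 13) -> SyntheticLocus:
    """SYNTHETIC stand-in for the CD36 intron-1 locus alleles.

    The published allele sequences are not redistributed here; instead a
    random backbone is built around the published primer triplet
    (P1_13_F shared forward, P2_13_R inside the element, P3_13_R in the
    downstream flank) with the published product geometry: P1+P2 amplify
    1,056 bp from the insertion allele and P1+P3 amplify 1,159 bp from the
    empty-site allele. All coordinates are constructed, not measured.
    """
    from .io import load_cd36_primers  # local import to avoid a cycle

    primers = load_cd36_primers()
    p1, p2, p3 = primers["P1_13_F"], primers["P2_13_R"], primers["P3_13_R"]
    rng = np.random.default_rng(seed)
    backbone = list(_random_seq(rng, 2000))
    p1_start = 100  # 1-based start of the shared forward primer site
    insertion_point = 600
    tsd_len = 6
    abs_product = 1159
    ins_product = 1056
    # place the forward site and the empty-site reverse site on the backbone
    backbone[p1_start - 1 : p1_start - 1 + len(p1)] = list(p1)
    p3_site = reverse_complement(p3)
    p3_end = p1_start + abs_product - 1
    backbone[p3_end - len(p3_site) : p3_end] = list(p3_site)
    abs_allele = "".join(backbone)
    # element with the insertion-allele reverse site embedded in its 5' region
    element = list(build_erv_element(default_template(), 0.0, seed))
    p2_site = reverse_complement(p2)
    p2_end_in_element = ins_product - (insertion_point - 1) - tsd_len + (p1_start - 1)
    element[p2_end_in_element - len(p2_site) : p2_end_in_element] = list(p2_site)
    p0 = insertion_point - 1
    tsd = abs_allele[p0 : p0 + tsd_len]
    ins_allele = abs_allele[:p0] + tsd + "".join(element) + abs_allele[p0:]
    return SyntheticLocus(
        ins_allele=ins_allele,
        abs_allele=abs_allele,
        primers=primers,
        insertion_point=insertion_point,
        tsd_len=tsd_len,
    )
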