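"""Dual-primer presence/absence PCR genotyping of a RIP locus.

One shared forward primer (P1) sits in the upstream flank; one reverse primer
(P2) anneals inside the insertion's 5' region and one (P3) in the downstream
flank. The P1+P2 product diagnoses the insertion allele, the P1+P3 product
the empty-site allele (which is unamplifiable across a full-length element),
so the band pattern reads directly as a genotype: insertion band only ->
ERV+/+, empty-site band only -> ERV-/-, both -> ERV+/-.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .simulate import BandPattern, reverse_complement


class AssayDesignError(ValueError):
    """No primer satisfying the design rules could be found."""


@dataclass(frozen=True)
class PrimerRules:
    """Primer acceptance rules (Wallace-rule melting temperature)."""

    min_len: int = 18
    max_len: int = 25
    gc_min: float = 40.0
    gc_max: float = 60.0
    max_run: int = 4
    tm_min: float = 52.0
    tm_max: float = 68.0
    product_min: int = 800
    product_max: int = 1500


@dataclass(frozen=True)
class PrimerAssay:
    locus_id: str
    p1_fwd: str
    p2_rev: str
    p3_rev: str
    expected_ins_product: int
    expected_abs_product: int
    size_tolerance: int = 20

    def __post_init__(self):
        for name, primer in (("p1_fwd", self.p1_fwd), ("p2_rev", self.p2_rev), ("p3_rev", self.p3_rev)):
            if not 18 <= len(primer) <= 30:
                raise ValueError(f"{name} must be 18-30 nt, got {len(primer)}")
        if self.expected_ins_product <= 0 or self.expected_abs_product <= 0:
            raise ValueError("expected products must be positive")
        if self.expected_ins_product == self.expected_abs_product:
            raise ValueError("the two diagnostic products must differ in size")


@dataclass(frozen=True)
class GenotypeCall:
    call: str  # ERV+/+ | ERV+/- | ERV-/- | fail


#: map between assay calls and the plain genotype labels used elsewhere
CALL_TO_GENOTYPE = {"ERV+/+": "+/+", "ERV+/-": "+/-", "ERV-/-": "-/-"}
GENOTYPE_TO_CALL = {v: k for k, v in CALL_TO_GENOTYPE.items()}


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


def _site_matches(template: str, site: str, start: int, max_mismatch: int, anchor: str) -> bool:
    """Ungapped site match with a strict 3'-terminal base (``anchor`` end)."""
    window = template[start : start + len(site)]
    if len(window) != len(site):
        return False
    if anchor == "right" and window[-1] != site[-1]:
        return False
    if anchor == "left" and window[0] != site[0]:
        return False
    mismatches = sum(a != b for a, b in zip(window, site))
    return mismatches <= max_mismatch


def _find_sites(template: str, site: str, max_mismatch: int, anchor: str) -> list:
    if max_mismatch == 0:
        out = []
        start = template.find(site)
        while start != -1:
            out.append(start)
            start = template.find(site, start + 1)
        return out
    return [
        i
        for i in range(len(template) - len(site) + 1)
        if _site_matches(template, site, i, max_mismatch, anchor)
    ]


def insilico_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_product: int = 2000,
    max_mismatch: int = 0,
) -> list:
    """Product lengths amplifiable from ``template`` by a primer pair.

    The forward primer is matched on the plus strand, the reverse primer as
    its reverse complement downstream within ``max_product``; product length
    is (reverse site end) - (forward site start) + 1 in 1-based coordinates.
    The default zero-mismatch policy reflects assembly (not read) templates;
    when mismatches are allowed the 3'-terminal base must still match.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    template = template.upper()
    fwd = fwd.upper()
    rev_site = reverse_complement(rev.upper())
    fwd_starts = _find_sites(template, fwd, max_mismatch, anchor="right")
    rev_starts = _find_sites(template, rev_site, max_mismatch, anchor="left")
    products = set()
    for f in fwd_starts:
        for r in rev_starts:
            r_end = r + len(rev_site)  # 0-based exclusive = 1-based inclusive end
            length = r_end - f
            if len(fwd) < length <= max_product and r >= f + len(fwd):
                products.add(length)
    return sorted(products)


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def wallace_tm(seq: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C)."""
    gc = sum(b in "GC" for b in seq)
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def _check_rules(seq: str, rules: PrimerRules) -> Optional[str]:
    gc = _gc_percent(seq)
    if not rules.gc_min <= gc <= rules.gc_max:
        return f"GC content {gc:.1f}% outside [{rules.gc_min}, {rules.gc_max}]"
    if _max_run(seq) > rules.max_run:
        return f"homopolymer run > {rules.max_run}"
    tm = wallace_tm(seq)
    if not rules.tm_min <= tm <= rules.tm_max:
        return f"Tm {tm:.0f} outside [{rules.tm_min}, {rules.tm_max}]"
    return None


def _unique_in(contexts: Sequence[str], site: str) -> bool:
    """At most one (possibly reverse-complemented) occurrence per allele."""
    rc = reverse_complement(site)
    total = 0
    for ctx in contexts:
        n = ctx.count(site) + ctx.count(rc)
        if n > 1:
            return False
        total += n
    return total >= 1


def design_assay(
    ins_allele_seq: str,
    abs_allele_seq: str,
    insertion_point: Optional[int] = None,
    locus_id: str = "locus",
    rules: PrimerRules = PrimerRules(),
    size_tolerance: int = 20,
) -> PrimerAssay:
    """Design the P1/P2/P3 triplet for a locus given both allele sequences.

    ``insertion_point`` is the 1-based base in the absence allele before
    which the element sits (defaults to the centre, for locus-centred input).
    Primers must satisfy the length/GC/run/Tm rules and occur uniquely in the
    provided sequences; both diagnostic products must fall in the target size
    band. Raises :class:`AssayDesignError` naming the violated rule when no
    primer works.
    """
    ins = ins_allele_seq.upper()
    abs_ = abs_allele_seq.upper()
    x = insertion_point if insertion_point is not None else len(abs_) // 2 + 1
    block = len(ins) - len(abs_)
    if block <= 0:
        raise ValueError("insertion allele must be longer than the absence allele")
    violations: list = []

    def pick_forward() -> Optional[int]:
        lo = max(0, x - 1 - (rules.product_max - 200))
        for start in range(x - 1 - rules.min_len, lo - 1, -1):
            for length in range(rules.min_len, rules.max_len + 1):
                if start + length > x - 1:
                    continue
                cand = abs_[start : start + length]
                problem = _check_rules(cand, rules)
                if problem:
                    violations.append(f"P1 {problem}")
                    continue
                if not _unique_in((ins, abs_), cand):
                    violations.append("P1 not unique")
                    continue
                return start
        return None

    p1_start = pick_forward()
    if p1_start is None:
        raise AssayDesignError(
            "no forward primer satisfies the rules: "
            + (violations[-1] if violations else "no candidate window")
        )
    p1 = None
    for length in range(rules.min_len, rules.max_len + 1):
        cand = abs_[p1_start : p1_start + length]
        if p1_start + length <= x - 1 and _check_rules(cand, rules) is None and _unique_in(
            (ins, abs_), cand
        ):
            p1 = cand
            break
    assert p1 is not None

    def pick_reverse(target: str, end_lo: int, end_hi: int, label: str) -> Optional[tuple]:
        for end in range(end_lo, end_hi + 1):
            for length in range(rules.min_len, rules.max_len + 1):
                if end - length < 0 or end > len(target):
                    continue
                site = target[end - length : end]
                primer = reverse_complement(site)
                problem = _check_rules(primer, rules)
                if problem:
                    violations.append(f"{label} {problem}")
                    continue
                if not _unique_in((ins, abs_), site):
                    violations.append(f"{label} not unique")
                    continue
                return primer, end
        return None

    # P2: reverse site inside the inserted block's 5' region (insertion allele)
    ins_band_lo = p1_start + rules.product_min
    ins_band_hi = min(p1_start + rules.product_max, (x - 1) + block)
    picked = pick_reverse(ins, max(ins_band_lo, x - 1 + rules.min_len), ins_band_hi, "P2")
    if picked is None:
        raise AssayDesignError(
            "no insertion-allele reverse primer: "
            + (violations[-1] if violations else "no candidate window")
        )
    p2, p2_end = picked
    # P3: reverse site in the shared downstream flank (absence allele)
    abs_band_lo = max(p1_start + rules.product_min, x - 1 + rules.min_len)
    abs_band_hi = min(p1_start + rules.product_max, len(abs_))
    picked = pick_reverse(abs_, abs_band_lo, abs_band_hi, "P3")
    if picked is None:
        raise AssayDesignError(
            "no absence-allele reverse primer: "
            + (violations[-1] if violations else "no candidate window")
        )
    p3, p3_end = picked

    return PrimerAssay(
        locus_id=locus_id,
        p1_fwd=p1,
        p2_rev=p2,
        p3_rev=p3,
        expected_ins_product=p2_end - p1_start,
        expected_abs_product=p3_end - p1_start,
        size_tolerance=size_tolerance,
    )


# ---------------------------------------------------------------------------
# Band-pattern genotyping
# ---------------------------------------------------------------------------


def pcr_bands(
    templates: Sequence[str], assay: PrimerAssay, max_product: int = 2000
) -> BandPattern:
    """Run both assay reactions over a set of haplotype templates."""
    sizes = set()
    for template in templates:
        sizes.update(insilico_pcr(template, assay.p1_fwd, assay.p2_rev, max_product))
        sizes.update(insilico_pcr(template, assay.p1_fwd, assay.p3_rev, max_product))
    return BandPattern(sizes=tuple(sorted(sizes)))


def classify_genotype(pattern: BandPattern, assay: PrimerAssay) -> GenotypeCall:
    """Read a band pattern as a genotype call.

    Bands match an expected product within ``size_tolerance``; the insertion
    band alone is ERV+/+, the empty-site band alone ERV-/-, both ERV+/-,
    neither a failed reaction.
    """
    tol = assay.size_tolerance
    ins_seen = any(abs(b - assay.expected_ins_product) <= tol for b in pattern.sizes)
    abs_seen = any(abs(b - assay.expected_abs_product) <= tol for b in pattern.sizes)
    if ins_seen and abs_seen:
        return GenotypeCall("ERV+/-")
    if ins_seen:
        return GenotypeCall("ERV+/+")
    if abs_seen:
        return GenotypeCall("ERV-/-")
    return GenotypeCall("fail")
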