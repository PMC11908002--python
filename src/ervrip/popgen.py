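"""Per-population genetic indices for a biallelic presence/absence marker.

Given genotype counts (n_pp, n_pm, n_mm) the module computes allele
frequencies by counting, Nei gene diversity He = 1 - sum(p_i^2), observed
heterozygosity Ho, effective allele number Ne = 1 / sum(p_i^2), the biallelic
polymorphic information content PIC = He - 2 p^2 q^2, and the 1-df
Hardy-Weinberg chi-squared test against expected (n p^2, 2npq, n q^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from scipy import stats


class MonomorphicError(ValueError):
    """The HWE test is undefined for a monomorphic population."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of +/+, +/- and -/- animals in one population."""

    population: str
    n_pp: int
    n_pm: int
    n_mm: int

    def __post_init__(self):
        if min(self.n_pp, self.n_pm, self.n_mm) < 0:
            raise ValueError("genotype counts must be >= 0")
        if self.n == 0:
            raise ValueError("population must contain at least one animal")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pm + self.n_mm


@dataclass(frozen=True)
class PopGenSummary:
    population: str
    n: int
    p: float
    q: float
    Ho: float
    He: float
    Ne: float
    PIC: float
    chi2: float | None
    df: int | None
    p_value: float | None


def allele_frequencies(counts: GenotypeCounts) -> tuple:
    """Insertion-allele frequency by allele counting: p = (2 n_pp + n_pm) / 2n."""
    p = (2 * counts.n_pp + counts.n_pm) / (2 * counts.n)
    return p, 1.0 - p


def genotype_percentages(counts: GenotypeCounts, decimals: int = 2) -> tuple:
    """Percentages of (+/+, +/-, -/-), rounded half-up to ``decimals``."""
    quantum = Decimal(10) ** -decimals

    def pct(x: int) -> float:
        return float(
            (Decimal(100 * x) / Decimal(counts.n)).quantize(quantum, rounding=ROUND_HALF_UP)
        )

    return pct(counts.n_pp), pct(counts.n_pm), pct(counts.n_mm)


def heterozygosity(counts: GenotypeCounts) -> tuple:
    """(Ho, He): observed heterozygote share and Nei gene diversity."""
    p, q = allele_frequencies(counts)
    return counts.n_pm / counts.n, 1.0 - (p * p + q * q)


def expected_heterozygosity_corrected(counts: GenotypeCounts) -> float:
    """Small-sample-corrected He, 2n/(2n-1) * (1 - sum p^2) (optional variant)."""
    _, he = heterozygosity(counts)
    n2 = 2 * counts.n
    return n2 / (n2 - 1) * he


def effective_allele_number(p: float) -> float:
    """Ne = 1 / (p^2 + q^2), the equivalent number of equifrequent alleles."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency out of [0, 1]")
    q = 1.0 - p
    return 1.0 / (p * p + q * q)


def pic(p: float) -> float:
    """Biallelic polymorphic information content: 1 - (p^2+q^2) - 2 p^2 q^2."""
    if not 0 <= p <= 1:
        raise ValueError("allele frequency out of [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def hwe_chi_square(counts: GenotypeCounts) -> tuple:
    """(chi2, df, p_value) against Hardy-Weinberg expected counts, df = 1."""
    p, q = allele_frequencies(counts)
    if p == 0.0 or p == 1.0:
        raise MonomorphicError(
            f"population {counts.population!r} is monomorphic (p = {p})"
        )
    n = counts.n
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    observed = (counts.n_pp, counts.n_pm, counts.n_mm)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = 1  # 3 classes - 1 - 1 estimated allele frequency
    return chi2, df, float(stats.chi2.sf(chi2, df))


def summarize(counts: GenotypeCounts, corrected_he: bool = False) -> PopGenSummary:
    """All indices for one population; HWE fields are None when monomorphic."""
    p, q = allele_frequencies(counts)
    ho, he = heterozygosity(counts)
    if corrected_he:
        he = expected_heterozygosity_corrected(counts)
    try:
        chi2, df, p_value = hwe_chi_square(counts)
    except MonomorphicError:
        chi2 = df = p_value = None
    return PopGenSummary(
        population=counts.population,
        n=counts.n,
        p=p,
        q=q,
        Ho=ho,
        He=he,
        Ne=effective_allele_number(p),
        PIC=pic(p),
        chi2=chi2,
        df=df,
        p_value=p_value,
    )


def counts_from_calls(calls: pd.DataFrame, population_col: str = "breed") -> list:
    """GenotypeCounts per population from a per-animal genotype table."""
    out = []
    for pop, grp in calls.groupby(population_col):
        vc = grp["genotype"].value_counts()
        out.append(
            GenotypeCounts(
                population=str(pop),
                n_pp=int(vc.get("+/+", 0)),
                n_pm=int(vc.get("+/-", 0)),
                n_mm=int(vc.get("-/-", 0)),
            )
        )
    return out


def summary_table(counts_list, corrected_he: bool = False) -> pd.DataFrame:
    """Survey-style report: percentages plus the genetic indices per population."""
    rows = []
    for counts in counts_list:
        s = summarize(counts, corrected_he=corrected_he)
        pp, pm, mm = genotype_percentages(counts)
        rows.append(
            {
                "population": s.population,
                "n": s.n,
                "pct_pp": pp,
                "pct_pm": pm,
                "pct_mm": mm,
                "p": s.p,
                "Ho": s.Ho,
                "He": s.He,
                "Ne": s.Ne,
                "PIC": s.PIC,
                "chi2": s.chi2,
                "hwe_p": s.p_value,
            }
        )
    return pd.DataFrame(rows)
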