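# Methods

This note documents the models, conventions and design choices behind
`ervrip`: what each stage computes, which parameters matter, what the
synthetic data emulate, and where the genuinely open choices were made.

## Coordinates and conventions

All genomic intervals are 1-based inclusive in memory, so an element at
41,862,971–41,870,900 has length `end − start + 1 = 7,930` bp; BED output
converts to 0-based half-open and VCF stays 1-based. Insertion points are
recorded as "the element sits before base P". LTR similarity is reported as
the nearest integer percent of matching alignment columns, matching the
granularity of published carrier tables (100%, 99%, …).

## ERV structure and full-length classification

A provirus is modelled as 5′LTR + internal region + 3′LTR. An element is
*full length* when it is longer than 5 kb, both LTRs are detected, and its
ORF set covers Gag, Pol and Env. A protease (Pro) ORF is reported when found
but is deliberately not required: the full-length definition used in the
field names only the three core domains, while carrier tables routinely
list Pro as well.

**LTR detection.** No published method is prescribed for locating the
terminal repeat, so the package uses a banded local self-alignment: the
first and last `max_ltr_len` bp (default 1,500, clipped to half the element)
are aligned locally (match +1, mismatch −1, gap open −3, extend −1); the
best alignment is accepted when it spans ≥ `min_len` (default 100 bp) at
≥ `min_identity` (default 80%). For a random 3 kb sequence the best local
alignment between the two windows is far below these thresholds, so false
positives are not a practical concern.

**Insertion dating.** The two LTR copies are identical at integration and
diverge neutrally afterwards, so their Kimura two-parameter distance

```
K = −1/2 · ln((1 − 2P − Q) · √(1 − 2Q))
```

(P, Q = transition, transversion proportions over gap-free columns) dates
the insertion as `T = K / (2r)`. The host substitution rate is configurable
with default `r = 2.2 × 10⁻⁹` subs/site/year, a standard mammalian nuclear
value; the dating tool named in the source protocol does not state its rate.
Saturated alignments (either log argument ≤ 0) raise an error rather than
returning a clamped distance.

**Domains.** Profile-HMM domain search is delegated: an external result
table (TSV of domain, aa_length) can be imported verbatim. Absent that, a
six-frame ORF scan (default ≥ 100 aa) names ORFs by ≥ 50% overlap with a
template's declared domain layout. Re-implementing profile search would be
out of proportion for what the pipeline needs from it.

**Repeat input.** Real annotations are ingested from RepeatMasker `.out`
files (three header lines, whitespace columns, `C` = minus strand; malformed
lines are reported with their line number). For simulated genomes an
internal scanner finds near-exact library copies by exact k-mer seeding with
full-length verification at ≤ 10% mismatch — sufficient because simulated
divergence stays well below that, and deliberately not a general-purpose
repeat masker.

## Flank-anchored discovery

For each full-length element in a non-reference assembly the 500 bp flanks
are aligned to the reference with an internal seed-and-extend aligner
(exact 15-mer seeds vote for diagonals; candidates are scored by full
ungapped comparison, `score = matches − mismatches`). A perfect 500 bp flank
scores 500, so the score threshold 450 admits up to 25 mismatches — chosen
to approximate the published screen's scoring on ungapped hits. Filters:
identity ≥ 90%, score ≥ 450, aligned span within 450–550 bp. Precomputed
PSL alignments can be ingested and pass through the identical filters.

**Projection.** A uniquely mapping upstream flank places the insertion at
`target_end + 1` (strand-mirrored otherwise); if the upstream flank fails
(zero or multiple passing hits) the downstream flank decides
(`target_start`); when both sides are unique they must agree within the
merge gap — the target-site duplication shifts the upstream estimate by its
length (default 6 bp), which the 10 bp gap absorbs. More than one passing
hit on the deciding side means multi-mapping and the insertion is omitted.

**Calling and merging.** A projected point is a polymorphism candidate iff
no same-family reference element lies within the polymorphism window
(default `w = 50` bp, the literal screening command's value; 400 bp — the
window radius described in prose in the same protocol — is a documented
alternative preset). Same-strand candidates within `d = 10` bp merge into
one locus; opposite strands never merge; merging is idempotent. Family
matching is configurable and on by default.

**Presence/absence.** Published protocols imply but do not formalize absence
calling, so the package defines an explicit empty-site test: a genome is
*absent* at a locus iff both reference flanks map uniquely, on one
chromosome and strand, separated by at most 20 bp of slack; *present* iff
the separation is at least 1,000 bp (an element-sized gap); *unknown*
otherwise. The same rule handles reference-carrier loci by discounting the
reference span.

**Gene context.** Loci are placed as "exon k" / "intron k" counted in
transcript orientation (a 15-exon transcript has 14 introns; on the minus
strand intron 1 abuts the genomically last exon). GFF3 is read via gffutils.

## Genotyping assay

Primer rules: length 18–25 nt, GC 40–60%, no homopolymer run > 4, Wallace
melting temperature `2(A+T) + 4(G+C)` in 52–68 °C, uniqueness (≤ 1
occurrence per allele counting both strands), products in 800–1,500 bp.
The Wallace rule is adequate at this scale; no nearest-neighbour model is
attempted. In-silico PCR uses exact primer sites by default (templates are
assemblies, not reads); when mismatches are allowed the 3′-terminal base
must still match. Band classification tolerates ±20 bp, reflecting agarose
resolution. The pair semantics follow the published assay: the shared
forward primer with the internal reverse primer diagnoses the insertion
allele (1,056 bp at the modelled locus), with the flank reverse primer the
empty allele (1,159 bp; one figure legend prints 1,158 bp once — the
Methods value is used). The published allele sequences are not
redistributed: `synthetic_cd36_locus` builds a random backbone around the
published primer triplet with the published product geometry, and is
labelled synthetic wherever it appears.

## Population genetics

For genotype counts (n₊₊, n₊₋, n₋₋): `p = (2n₊₊ + n₊₋)/2n`, `Ho = n₊₋/n`,
`He = 1 − Σp²` (plain Nei gene diversity; the 2n/(2n−1) small-sample
correction is offered as an option but is not the default, since the source
analyses cite Nei without specifying), `Ne = 1/Σp²`, and the biallelic
`PIC = 1 − Σp² − 2p²q²`. The HWE test is the 1-df χ² against
(np², 2npq, nq²); monomorphic populations raise an error rather than
returning 0/0. Percentages are rounded half-up with no forcing of 100%
sums (published survey rows occasionally disagree by one unit in the last
digit, apparently from largest-remainder adjustment; this package does not
replicate that).

## Fixed-effects association

The trait model is `Y = μ + G + B + S + e` with reference-cell coding,
fitted by OLS (statsmodels). Factor tests use partial sums of squares
computed as `SSE(model without the factor) − SSE(full model)`; for this
additive no-interaction design that equals SAS Type III (and Type II), which
the tests confirm against `statsmodels.anova_lm`. Factors with one observed
level are dropped with a warning; complete confounding (e.g. breeds fixed
for a genotype) is detected by rank analysis and raises an error naming the
inestimable factors instead of silently dropping data. The analysis gate is
the Shapiro–Wilk W ≥ 0.90.

LSD comparisons are computed unconditionally (not gated on the omnibus F),
mirroring how such tables are published: for levels i, j the threshold is
`t(1−α/2, df_error) · √(MSE·(1/nᵢ + 1/nⱼ))` on raw level means. The compact
letter display assigns one letter per maximal set of mutually
non-significant levels (clique enumeration), ordered by descending mean, so
levels sharing a letter are never flagged different and every
non-significant pair shares at least one letter. With σₑ = 0 the fit
recovers generating effects to machine precision and F is reported as
infinite with p = 0.

## Synthetic data: what it does and does not emulate

Reference backbones are i.i.d. uniform ACGT with a uniqueness screen (no
repeated 20-mer near plant sites), so flanks map uniquely by construction —
matching the screen's discard-multi-mappers rule while keeping planted
recovery a meaningful round trip. Plants duplicate the target site (default
TSD 6 bp; no empirical TSD length is published for the modelled locus, so
this is configurable), optionally reverse-complement the element, truncate
it, and mutate the 3′ LTR with a seeded Binomial(L, rate) substitution draw
at transition:transversion 2:1 (so both Kimura proportions are exercised).
The default template reproduces the modelled element's geometry: 444 bp
LTRs, 7,042 bp internal region (7,930 bp total), ORFs of 531/278/696/441 aa
for Gag/Pro/Pol/Env. Populations draw genotypes from Hardy–Weinberg
proportions at per-breed allele frequencies and traits from the additive
model only — no interactions, no linkage, no solo-LTR recombinants, no
read-level sequencing error. Passing tests therefore demonstrate the
correctness of the algorithms under clean assembly conditions, not
robustness to assembly artifacts, segmental duplication or repeat-dense
flanks, which real genomes supply in abundance.

Problem sizes used by the test-bench scenarios: the survey panel is one
reference plus 42 non-reference assemblies of a 60 kb chromosome with three
planted loci (22, 10 and 30 carriers; with the reference counted the first
locus splits 22 present / 21 absent, the published survey structure);
null-model calibration uses 1,000 replicates of 144 animals. These sizes
keep the full suite fast while leaving every code path exercised; all of
them scale by argument.

## Known limitations

Assembly-vs-assembly only — no split-read MEI calling. The internal flank
aligner is ungapped; small indels inside a flank reduce identity rather
than opening a gap. The internal library scanner requires near-exact copies
and is not a substitute for a real repeat annotation run on real genomes.
The HWE χ² is asymptotic (no exact test); the association model has no
random effects or multiple-testing correction across traits, matching the
published analysis it mirrors.
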