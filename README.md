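# ervrip

Discovery, dating, genotyping and trait association of **full-length
endogenous retrovirus (ERV) insertion polymorphisms** between genome
assemblies.

ERVs are germline-inherited retroviral integrations with the structure
LTR–*gag*–*pro*–*pol*–*env*–LTR. A locus where such an insertion is present
in some assemblies and absent in others is a retrotransposon insertion
polymorphism (RIP) — a clean biallelic marker. A well-studied example in
sheep is a 7,930 bp beta-retroviral element inside intron 1 of the *CD36*
(fatty-acid translocase) gene, polymorphic across breeds and associated with
body-condition and fat traits. `ervrip` implements the complete
assembly-to-association workflow for markers of this kind:

1. **Annotation** (`ervrip.annotation`) — assemble repeat hits (parsed
   RepeatMasker `.out` or an internal k-mer library scan) into proviral
   elements; detect paired LTRs by banded terminal self-alignment; classify
   *full-length* elements (> 5 kb, both LTRs, Gag/Pol/Env ORFs); date
   insertions from inter-LTR Kimura two-parameter divergence,
   `K = -1/2 ln((1-2P-Q)√(1-2Q))`, as `T = K / (2r)` with
   `r = 2.2×10⁻⁹` subs/site/year by default.
2. **Discovery** (`ervrip.discovery`) — project each insertion onto the
   reference by aligning its 500 bp flanks (identity ≥ 90, score ≥ 450,
   aligned span 450–550 bp; multi-mapping flanks discarded); call a RIP when
   no same-family reference element lies within a 50 bp window; merge
   same-strand candidates within 10 bp; verify presence/absence per genome
   by the empty-site test; intersect loci with gene annotation
   (exon *k* / intron *k* in transcript orientation).
3. **Genotyping** (`ervrip.assay`) — design the dual-primer assay (shared
   forward primer, one reverse primer inside the element, one in the
   downstream flank), run in-silico PCR, and read band patterns as
   ERV⁺/⁺ / ERV⁺/⁻ / ERV⁻/⁻ calls.
4. **Population genetics** (`ervrip.popgen`) — allele frequencies, observed
   and expected (Nei) heterozygosity, effective allele number, PIC, and the
   1-df Hardy–Weinberg χ² test.
5. **Association** (`ervrip.association`) — the fixed-effects model
   `Y_ijkl = μ + G_i + B_j + S_k + e_ijkl` (genotype, breed, sex) fitted by
   OLS with partial sums of squares, LSD₀.₀₅ pairwise comparisons with a
   compact letter display, gated by a Shapiro–Wilk check (W ≥ 0.90).
6. **Simulation** (`ervrip.simulate`) — synthetic reference backbones,
   planted proviruses with target-site duplications and seeded LTR
   divergence, breed-structured Hardy–Weinberg populations and additive
   trait values, so every stage is testable with full ground truth.

## Worked example

Genetic indices for the published six-breed genotype survey (n = 24 per
breed) at the *CD36*-intronic ERV locus, plus the diagnostic products of the
published primer triplet:

```python
from ervrip.io import load_breed_genotype_counts
from ervrip.popgen import GenotypeCounts, summary_table
from ervrip.simulate import synthetic_cd36_locus
from ervrip.assay import insilico_pcr

counts = [GenotypeCounts(r.population, r.n_pp, r.n_pm, r.n_mm)
          for r in load_breed_genotype_counts().itertuples()]
print(summary_table(counts).round(4).to_string(index=False))

loc = synthetic_cd36_locus()
p = loc.primers
print("insertion-allele product (P1+P2):",
      insilico_pcr(loc.ins_allele, p["P1_13_F"], p["P2_13_R"]))
print("empty-site product    (P1+P3):",
      insilico_pcr(loc.abs_allele, p["P1_13_F"], p["P3_13_R"]))
```

```
     population  n  pct_pp  pct_pm  pct_mm      p     Ho     He     Ne    PIC    chi2  hwe_p
          Barki 24   16.67   54.17   29.17 0.4375 0.5417 0.4922 1.9692 0.3711  0.2425 0.6224
        Rahmani 24    0.00    0.00  100.00 0.0000 0.0000 0.0000 1.0000 0.0000     NaN    NaN
  RahmanixBarki 24    4.17   12.50   83.33 0.1042 0.1250 0.1866 1.2295 0.1692  2.6173 0.1057
         Awassi 24    0.00  100.00    0.00 0.5000 1.0000 0.5000 2.0000 0.3750 24.0000 0.0000
         Ossimi 24    0.00   83.33   16.67 0.4167 0.8333 0.4861 1.9459 0.3680 12.2449 0.0005
RomanovxRahmani 24    0.00    0.00  100.00 0.0000 0.0000 0.0000 1.0000 0.0000     NaN    NaN
insertion-allele product (P1+P2): [1056]
empty-site product    (P1+P3): [1159]
```

Reading the table: Barki carries the insertion at allele frequency
p = 0.4375 and sits comfortably in Hardy–Weinberg equilibrium
(χ² = 0.24, p = 0.62); Rahmani and Romanov×Rahmani are fixed for the empty
allele, so heterozygosity and PIC collapse to zero and the HWE test is
undefined; the all-heterozygote Awassi sample maximally violates HWE
(χ² = n = 24). The 1,056 bp and 1,159 bp bands are the insertion- and
empty-allele diagnostics: one band each for homozygotes, both for
heterozygotes.

The same machinery runs from the shell:

```sh
ervrip simulate --out sim --seed 5 --n-genomes 5 --n-carriers 3
ervrip discover --reference sim/reference.fa --genomes sim/genomes --out rips
ervrip popgen --counts counts.tsv --out summary.tsv
ervrip assoc --phenotypes pheno.tsv --trait trait --out assoc
```

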