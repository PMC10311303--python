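# lcrcall

Multilocus small-variant calling in low-copy repeats (LCRs, segmental
duplications) from short-read WGS data, with a self-contained simulator
for testing the whole pipeline without external data.

## The problem

LCRs are long duplicated DNA segments whose copies are ≥97% identical.
Short reads from an LCR map ambiguously between copies and receive
mapping quality zero, so conventional callers — which trust the mapped
location of each read — lose both precision and recall exactly where
many disease genes live (*SMN1/SMN2*, *PMS2*, …).  The only sequence
signal that distinguishes copies are paralogous sequence variants
(PSVs): positions where the copies' reference sequences differ.  But
many PSVs are themselves polymorphic in the population, so they cannot
be trusted blindly.

`lcrcall` is for researchers who need genotypes inside duplicated loci
and have (i) aligned reads, (ii) a homology map relating the repeat
copies (from a multiple sequence alignment of their reference
sequences), (iii) per-copy *paralog-specific copy numbers* for the
sample, and (iv) PSV population reference-allele frequencies — the last
two as produced by copy-number tools for duplicated genes.

## The method

Calling proceeds in three steps per locus, for a sample with
paralog-specific copy numbers `c = (c_1, …, c_n)` and aggregate copy
number `ĉ = Σ c_i`:

1. **Aggregate variant calling.**  Reads from all copies are projected
   onto one representative copy and genotyped as a polyploid of ploidy
   `ĉ`.  The allelic depth vector `X` over the allele set `A` is
   multinomial,

       P(X | ĝ) = MN(X; p(a₁, ĝ), …, p(a_|A|, ĝ)),
       p(a, ĝ) ∝ (|r̄| − |a| − 1) · max{ε·ĉ, μ(a, ĝ)},

   with `μ(a, ĝ)` the multiplicity of allele `a` in the aggregate
   genotype `ĝ`, `|r̄|` the mean read length and `ε` the error rate.
   Posteriors use a uniform prior over genotypes; candidates below
   quality 1 are dropped and all PSVs are kept.

2. **Informative-PSV identification.**  At each PSV, per-copy population
   reference-allele frequencies `f_i` give a paralog-genotype prior
   `P(g; f) = Π_i f_i^μ(ref_i, g_i) (1−f_i)^(c_i − μ(ref_i, g_i))`, which is
   combined with the aggregate posterior.  A PSV is *informative* when
   its MAP paralog genotype is reference-compatible with posterior
   ≥ 0.99.  Read pairs spanning two informative PSVs are tested for
   conflicts (one-tailed binomial, π = 2ε − ε², p < 10⁻³) and the
   conflict graph is pruned greedily, dropping the PSV with maximal
   `degree · √(1 − f̃)` until no edge remains (`f̃` = minimal frequency
   across copies).

3. **Paralog-specific genotyping.**  Each read pair is located among
   copies through the informative PSVs it covers,
   `p_r(i) ∝ c_i Π_{v∈W_r} P(a_vi | r)`, and the per-variant genotype
   posterior multiplies pair likelihoods
   `P(r | g) = Σ_i p_r(i)/c_i ((1−ε)μ(a_r, g_i) + ε(c_i − μ(a_r, g_i)))`
   with the PSV prior (PSV sites) or a mutation-rate prior ξ = 10⁻³
   (novel variants).  Variants with no pair linked to an informative PSV
   or a non-duplicated flank stay *unresolved* and keep their aggregate
   genotype.  A two-sided Fisher's exact test on strand counts flags
   strand-biased artifacts (p < 0.01).

The simulator generates everything the caller consumes — repeat-copy
contigs with substitution PSVs at a similarity target, population-like
PSV frequencies, diploid samples with placed variants and PSV
realisations, and error-bearing paired reads with mapper-like ambiguous
copy assignment — plus a truth VCF for benchmarking.

## Worked example

Pooled polyploid genotyping of one site (`examples/02_pooled_genotyping.py`):

```
allelic depths: 22 x A, 8 x G at aggregate copy number 4
  P(G/G/G/G | X) = 0.000000
  P(A/G/G/G | X) = 0.000000
  P(A/A/G/G | X) = 0.033084
  P(A/A/A/G | X) = 0.966916
  P(A/A/A/A | X) = 0.000000
MAP aggregate genotype: A/A/A/G
quality vs all-reference: 85.8 (Phred)
```

8 alternate reads out of 30 sit close to the 1-in-4 expectation of a
single alternate allele among four copies, so the posterior
concentrates on `A/A/A/G`; the Phred quality says the all-reference
genotype is ~10⁸·⁶ times less probable.

The full pipeline on five simulated noisy loci
(`examples/04_full_pipeline.py`) prints

```
locus1: 2200 read pairs -> 56 variants (34 resolved), 8/48 informative PSVs
...
242 truth variants; at quality >= 21:
  discovery precision 1.0000, recall 0.9669
  paralog-genotype concordance 177/177 = 1.0000
```

i.e. every emitted variant is real, ~97% of simulated variants are
found, and every confidently resolved per-copy genotype matches the
truth.  The other examples cover locus simulation and informative-PSV
selection.

## Command line

```bash
lcrcall simulate --seed 1 -o fixture/          # synthetic locus bundle
lcrcall call --reads fixture/reads.sam \
    --homology-maps fixture/homology_maps.tsv \
    --psv-table fixture/psv_table.tsv \
    --copy-numbers fixture/copy_numbers.tsv \
    --reference fixture/reference.fasta -o calls.vcf
lcrcall evaluate --calls calls.vcf --truth fixture/truth.vcf
```

Output VCF encodes the per-copy genotype in a `PGT` FORMAT field
(`0/1|0/0` = alternate allele on the first copy) next to the pooled
aggregate `GT`; see the VCF header for the full field documentation.

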