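# Methods

## Model

A low-copy repeat (LCR) locus has `n ≥ 2` repeat copies related by a
multiple sequence alignment of their reference sequences (the *homology
map*).  A joint variant site is an n-tuple of aligned positions with
per-copy reference alleles `ref_i`; a site where the `ref_i` differ is a
PSV.  For a sample with paralog-specific copy numbers
`c = (c_1, …, c_n)` and aggregate copy number `ĉ = Σ c_i`, the
*aggregate genotype* at a site is an unordered multiset of `ĉ` alleles;
a *paralog-specific genotype* is a tuple of per-copy multisets of sizes
`c_i` that flattens to the aggregate.  `μ(a, Z)` counts occurrences of
allele `a` in multiset `Z`; a paralog genotype is *reference-compatible*
when `μ(ref_i, g_i) = c_i` for all `i`.

Key modelling assumptions:

* reads cannot be assigned to copies by mapping position — pooling
  treats the reported alignment copy as noise and uses all reads
  regardless of mapping quality;
* sequencing errors are independent substitutions at a constant rate ε
  (indels share this error model, a known simplification that costs
  indel precision in low-complexity sequence);
* variant sites are genotyped independently of one another; read pairs
  connect a variant only to PSVs, not to other variants;
* paralog-specific and aggregate copy numbers are known inputs
  (estimated upstream from read-depth), as are PSV population
  reference-allele frequencies.

### Step 1 — pooled polyploid genotyping

All reads are projected through alignment columns onto the
representative copy (copy 0).  Projection is local: matched bases
follow their columns, bases in columns gapped on the representative
copy stay unaligned (tracked as insertions), and representative-only
columns spanned by a read imply deletions.  Candidate alleles are
non-reference alleles (left-aligned, minimal representation) supported
by at least two read pairs; every PSV is a candidate site regardless.
Allele observations are per read *pair* (agreeing mates collapse,
disagreeing mates are discarded), must span the full allele, and need
base quality ≥ 10.

The allelic depth vector `X` over a site's allele set `A` is modelled
as multinomial with genotype-dependent weights

    p(a, ĝ) ∝ (|r̄| − |a| − 1) · max{ε·ĉ, μ(a, ĝ)}

(`|r̄|` = mean aligned read length of the locus pileup, computed per
locus).  The `ε·ĉ` floor keeps every weight positive so errors never
zero out a likelihood; the length factor down-weights long alleles.
The genotype prior is uniform over all `C(ĉ+|A|−1, |A|−1)` multisets,
so the posterior argmax is the maximum-likelihood genotype.  Candidate
sites keep their place when the Phred quality against the all-reference
aggregate genotype is ≥ 1 (PSVs always stay).

### Step 2 — informative PSVs

At a PSV with per-copy reference-allele frequencies `f_i ∈ (0,1)`, the
prior of a paralog genotype is
`P(g; f) = Π_i f_i^μ(ref_i,g_i) (1−f_i)^(c_i−μ(ref_i,g_i))`.  The joint
posterior multiplies the aggregate posterior of each aggregate genotype
class by this prior renormalised within the class.  A PSV is
*informative* when the MAP paralog genotype is reference-compatible
with posterior ≥ 0.99 (configurable).  Because the class prior is
renormalised, PSVs whose frequencies are only moderately high
(f ≈ 0.9) rarely clear the bar — by design: such PSVs genuinely cannot
be trusted to separate copies.

Read pairs covering two informative PSVs are tabulated; a pair is
*discordant* when its allele combination matches no copy's reference
haplotype at the two PSVs.  For pairs co-covered by ≥ 3 read pairs a
one-tailed binomial test with `π = 2ε − ε²` flags conflicts at
p < 10⁻³.  Conflicting PSVs form an undirected graph; keeping an
edgeless subset with maximal total `f̃` (minimal frequency over copies)
is NP-hard, so the greedy heuristic repeatedly removes the node
maximising `degree · √(1 − f̃)` (ties: smaller `f̃`, then smaller
coordinate).  The retained set is provably edgeless; the test suite
measures its weight against the exhaustive optimum on small graphs
(mean ratio ≈ 0.97 on random 30%-density graphs up to 12 nodes).

### Step 3 — paralog-specific genotyping

Each read pair covering a variant is located among copies using the
retained informative PSVs `W_r` it covers:

    p_r(i) ∝ c_i · Π_{v∈W_r} P(a_vi | r)

with `P = 1−ε` on allele match, `ε` on mismatch and `ε²` when the PSV
is missing from copy `i` (alignment gap).  A pair whose mate aligns
≥ 20 bp into the copy-private flank beyond the homologous interval is
anchored there — the flank acts as one perfectly matching pseudo-PSV.
With no PSVs and no anchor, `p_r` reduces to the copy-number prior
`c_i/ĉ`.

Pair likelihoods mix per-copy emissions over locations,
`P(r|g) = Σ_i p_r(i)/c_i ((1−ε)μ(a_r,g_i) + ε(c_i−μ(a_r,g_i)))`.  The
genotype space is the union of paralog expansions of every aggregate
genotype with posterior > 10⁻⁶; each genotype's prior is its aggregate
posterior times the class prior (PSV population prior at PSVs, else the
novel-variant prior `Π_i (1−ξ)` or `ξ` per non-reference copy,
ξ = 10⁻³, penalising homozygous and heterozygous copies equally)
renormalised within the class.  A variant with no linked pair is
*unresolved*: its posterior is still computed (mirror-symmetric under
symmetric copy numbers) but only the aggregate genotype is reported.

Qualities: variant QUAL = −10·log₁₀ P(reference-compatible genotype |
reads) for resolved variants (aggregate-based for unresolved), per-copy
GQ = −10·log₁₀(1 − P(MAP per-copy genotype)), both capped at 1000.
The two-sided Fisher's exact strand-bias test on
(ref/alt × forward/reverse) pair counts flags records at p < 0.01
(`FILTER=StrandBias`); quality below the recommended output threshold
21 flags `LowQual`.  Flagged records stay in the VCF.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ε (`epsilon`) | 0.01 | per-base error rate used in every model term |
| ξ (`xi`) | 10⁻³ | mutation-rate prior for novel variants |
| informative threshold | 0.99 | posterior required of a reference-compatible PSV genotype |
| conflict p-value | 10⁻³ | one-tailed binomial threshold for PSV pairs |
| FET p-value | 0.01 | two-sided strand-bias threshold |
| min base quality | 10 | observation filter |
| candidate quality | 1 | discovery filter (Phred vs all-reference) |
| output threshold | 21 | recommended QUAL/GQ operating point |
| aggregate floor | 10⁻⁶ | aggregate classes below this are excluded from step 3 |

ε has no single canonical value for short-read data; 0.01 is a
conventional constant-error-rate choice and is configurable.  `|r̄|` is
computed per locus from the pooled pileup.

## Numerical choices

* Likelihoods are computed in log space with log-sum-exp
  normalisation (linear-scale multinomials underflow beyond ~100×).
* Alleles order canonically by (length, lexicographic); genotypes by
  index tuples — all argmax ties therefore break deterministically.
* Left alignment uses the standard trim/extend loop against the
  representative sequence; truth and calls normalise identically.
* The Fisher test sums hypergeometric probabilities ≤ the observed
  table's (1 + 10⁻¹²  relative tie tolerance so exactly-tied mirror
  tables are always included despite floating-point rounding); the
  binomial tail uses the survival function directly.
* Degenerate inputs: empty pileups give uniform posteriors; an empty
  read set leaves a variant unresolved with the aggregate genotype;
  a locus whose copy numbers are only partly known is called in
  aggregate-only mode after merging unknown copies into a pseudo-copy
  whose copy number is `ĉ` minus the known total (a documented
  approximation); loci with > 4 copies or no copy-number estimate are
  skipped with machine-readable reasons.

## Simulator

The simulator emulates the study conditions end to end:

* **Locus**: `n` contigs sharing a homologous core of length `L`
  (default 10 kb) that differ at substitution PSVs — the count is
  Poisson with mean `L·(1 − similarity)` (default similarity 0.995 ≈
  one PSV per 200 bp) — flanked by copy-private random sequence
  (default 500 bp) standing in for the non-duplicated neighbourhood.
  Because PSVs are substitutions, the inter-copy alignment is gap-free;
  gapped homology maps are exercised by constructed-alignment tests.
* **PSV frequencies**: drawn per copy from a mixture — 70%
  Uniform(0.9, 1.0) ("almost fixed"), 30% Uniform(0.5, 0.9) (clearly
  polymorphic) — standing in for empirical population frequencies,
  which cannot be shipped; a fixed-PSV mode sets every frequency to
  0.9999.
* **Sample**: per-copy haplotypes; polymorphic PSVs realise the
  homologous allele at rate `1 − f_i` per copy-chromosome; artificial
  variants at 1/kb by default (80% substitutions, 10% insertions, 10%
  deletions, 61.5% heterozygous), spaced so alleles never overlap, and
  discarded near PSVs.  The truth set carries aggregate and
  paralog-specific genotypes, including non-reference PSV realisations
  (gene-conversion-like events are expressed through per-copy reference
  alleles).
* **Reads**: uniform fragments per haplotype (150 bp pairs, fragment
  500 ± 50 bp, diploid-style coverage `depth` per copy so the pooled
  core sees `depth/2 · ĉ`), substitution errors at rate ε, flat base
  quality 30.  Mapping is emulated rather than run through an external
  aligner: pairs covering PSVs go to the best-matching copy, PSV-free
  pairs to a uniformly random copy, flank-touching pairs to their true
  copy; the true origin is recorded in the read name and SAM tags.

What the simulator does **not** emulate: position- and cycle-dependent
error profiles, indel sequencing errors, GC/coverage bias, reference
bias of a real aligner, multi-nucleotide variants, structurally
rearranged or partially deleted copies, and empirical PSV frequency
spectra.  Passing the recovery experiments therefore demonstrates the
pipeline's statistical and combinatorial correctness under its own
model class, not performance on real sequencing artefacts.

## Evaluation design

The internal evaluator matches on normalised position and compares at
three strictness levels: *allele* (same position, reference and a
shared alternate allele — discovery accuracy), *aggregate* (pooled
allele multiset identical) and *paralog* (per-copy genotype equal to
truth where the truth provides one).  Precision/recall/F₁/F₀.₅ are
reported per level, overall and split by SNV/indel, optionally
stratified.  An empty qualifying call set reports precision as NA.

Genotype concordance is tallied among resolved calls; when a minimum GQ
is given, assignments the caller itself reports below it are excluded
from the tally (they remain in the VCF).  Benchmark metrics in the
acceptance suite count all emitted records at QUAL ≥ 21 regardless of
the `StrandBias` annotation: under the simulator's strand-symmetric
error model the test can only false-flag (measured ≈ 0.5–1% of true
variants on error-free data, matching its nominal false rate), so
excluding flagged records would measure the filter's noise, not the
caller.

## Problem sizes

The recovery experiments use 20 loci × 10 kb, two copies, diploid each,
with 3 variants/kb (so one run yields 500–900 truth variants): once at
30× with ε = 0.01 and polymorphic PSV frequencies, once error-free at
60× with fixed PSVs (caller ε stays 0.01 — ε = 0 would be a degenerate
model).  Oracle-agreement checks run 1000 random instances per
posterior family (|A| ≤ 3, ĉ ≤ 6, ≤ 20 read pairs), filter checks 500
random tables per test, and pruning checks 200 random graphs of up to
12 nodes against exhaustive search.

## Known limitations

* Indels share the constant-error substitution model; precision on
  indels in repetitive contexts will trail SNV precision on real data.
* Aggregate genotype priors are uniform, so at polymorphic PSV sites
  the posterior is mildly overconfident against the reference relative
  to a full population-prior treatment; borderline gene-conversion
  calls near the quality threshold are the visible consequence.
* One sample and up to one locus pair at a time; no joint multi-sample
  calling, no phasing across variants.
* Reverse-strand repeat copies must be pre-flipped before building the
  homology map.
* Paralog genotypes cannot be resolved where no read pair reaches an
  informative PSV or a non-duplicated anchor; such variants keep
  aggregate genotypes only, which bounds recall at the paralog level in
  PSV-poor stretches.
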