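"""Simulate a two-copy LCR locus and a diploid sample.

Builds a 10 kb segmental duplication with ~0.995 inter-copy similarity,
draws per-copy PSV population frequencies, then realises one sample:
polymorphic PSVs flip to the homologous allele at rate 1 - f per
copy-chromosome and artificial variants land at 1 per kb.
"""

from lcrcall import SimConfig, simulate_locus, simulate_sample

cfg = SimConfig(seed=42)
locus = simulate_locus(cfg)
sample = simulate_sample(locus)

print(f"locus: {cfg.n_copies} copies x {cfg.copy_length} bp, "
      f"similarity target {cfg.similarity}")
print(f"PSVs between copies: {len(locus.psvs)} "
      f"(expected ~{cfg.copy_length * (1 - cfg.similarity):.0f})")
nearly_fixed = sum(1 for p in locus.psvs if p.min_freq >= 0.9)
print(f"nearly fixed PSVs (min freq >= 0.9): {nearly_fixed}")

snvs = sum(1 for t in sample.truth if t.is_snv and not t.at_psv)
indels = sum(1 for t in sample.truth if not t.is_snv)
psv_realised = sum(1 for t in sample.truth if t.at_psv)
print(f"truth variants: {snvs} SNVs + {indels} indels placed artificially, "
      f"{psv_realised} non-reference PSV realisations")
t = sample.truth[0]
print(f"first truth variant: pos {t.position} {t.ref}->{t.alleles[1:]} "
      f"paralog genotype {t.per_copy}")
# per_copy lists each repeat copy's allele multiset: the variant's true
# assignment that the caller will try to recover from reads alone
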