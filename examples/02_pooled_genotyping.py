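"""Aggregate (pooled polyploid) genotyping at a single site.

Reads from all repeat copies are pooled, so a diploid two-copy locus is
genotyped at ploidy 4.  With 22 reference and 8 alternate reads the
most likely aggregate genotype carries one alternate allele; the print
shows the full posterior over the five possible genotypes.
"""

from lcrcall import GenotypingParams, aggregate_posterior

params = GenotypingParams(epsilon=0.01, mean_read_len=150.0)
post = aggregate_posterior(depths=[22, 8], alleles=["A", "G"], agcn=4,
                           params=params)

print("allelic depths: 22 x A, 8 x G at aggregate copy number 4")
for g, p in zip(post.genotypes, post.posteriors):
    print(f"  P({'/'.join(g)} | X) = {p:.6f}")
print(f"MAP aggregate genotype: {'/'.join(post.map_genotype)}")
print(f"quality vs all-reference: "
      f"{post.quality_vs(('A',) * 4):.1f} (Phred)")
# 8/30 alternate reads sit between the expectations of 1/4 (het on one
# copy) and 0 (reference): the posterior strongly favours one G allele
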