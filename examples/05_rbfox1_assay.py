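"""The packaged rbfox1 exon-6 splice assay.

Blocking the splice donor site of exon 6 forces its exclusion; a
flanking-primer RT-PCR then yields a shorter product.  The synthetic gene
model reproduces the two product sizes: 259 bp with the 61-nt exon 6
included, 198 bp with it skipped.
"""

from skipscan import amplicon_length, rbfox1_fixture

gene, assay = rbfox1_fixture()
all_exons = set(range(gene.n_exons))
cassette = assay["cassette"]

inclusion = amplicon_length(gene, assay, all_exons)
skipping = amplicon_length(gene, assay, all_exons - {cassette})

print(f"gene {gene.gene_id}: {gene.n_exons} exons, "
      f"cassette exon {cassette + 1} (1-based) of {gene.exon_length(cassette)} nt")
print(f"product with exon {cassette + 1} included: {inclusion} bp")
print(f"product with exon {cassette + 1} skipped:  {skipping} bp")
print(f"difference = cassette exon length: {inclusion - skipping} nt")
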