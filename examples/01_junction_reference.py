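"""Enumerate exon-exon junctions of a gene and build a sequence reference.

Short single-end reads can only witness splicing where they span the joint
between two exons, so every pairwise exon combination of a gene becomes a
reference entry: a suffix of the donor exon glued to a prefix of the
acceptor exon.
"""

from skipscan import (
    GeneModel,
    build_junction_reference,
    default_flank,
    enumerate_junctions,
)

# a 4-exon gene with made-up sequences (60 nt per exon)
import numpy as np

rng = np.random.default_rng(0)
seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
gene = GeneModel.from_exon_lengths("demo_gene", [60, 60, 60, 60], sequences=seqs)

keys = enumerate_junctions(gene)
print(f"{gene.gene_id}: {gene.n_exons} exons -> {len(keys)} junctions (n(n-1)/2)")
for key in keys:
    kind = "inclusion" if key.acceptor == key.donor + 1 else "skipping"
    print(f"  exon {key.donor} -> exon {key.acceptor}  ({kind})")

# flanks sized for 50-bp reads anchored by >= 8 nt on each side
flank = default_flank(read_length=50, min_anchor=8)
reference = build_junction_reference([gene], flank, flank)
key, seq, boundary = reference.entries[0]
print(f"\nflank length for 50-bp reads with 8-nt anchors: {flank}")
print(f"first entry {key.gene_id}|{key.donor}|{key.acceptor}: "
      f"{len(seq)} nt, splice boundary at position {boundary}")
print("the boundary splits the entry into donor suffix | acceptor prefix.")
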