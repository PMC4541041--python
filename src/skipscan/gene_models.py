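"""Gene models, exon-exon junction enumeration, and junction sequence references.

A :class:`GeneModel` is one linear chain of exons in transcription order.
Splice-junction analysis of short single-end reads cannot see reads inside
exons crossing into introns; what it can see are reads spanning the joint
between two exons that were spliced together.  To count those, every pairwise
combination of two exons of a gene (donor index i < acceptor index j) is
turned into a short reference sequence: a suffix of exon i concatenated with a
prefix of exon j.  Reads are later matched against these entries
(:mod:`skipscan.junction_quant`).

Coordinates are 0-based half-open internally.  GTF input (1-based closed) is
converted on read; BED12 is native.  Exon indices always follow transcription
order, so on the minus strand index 0 is the genomically last exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_NT = np.array(list("ACGT"))


class GeneModelError(ValueError):
    """Raised for malformed annotation input or invariant violations."""


class JunctionKey(NamedTuple):
    """Identity of one exon-exon junction: gene and the two exon indices.

    ``donor < acceptor`` in transcription order.  ``acceptor == donor + 1``
    is a constitutive/inclusion junction; ``acceptor > donor + 1`` is a
    skipping junction (one or more exons spliced out).
    """

    gene_id: str
    donor: int
    acceptor: int


@dataclass
class GeneModel:
    """One gene as an ordered chain of non-overlapping exons.

    Parameters
    ----------
    gene_id:
        Unique identifier; must not contain ``|`` (reserved for FASTA headers).
    chrom, strand:
        Genomic location; ``strand`` is ``+`` or ``-``.
    exons:
        ``(start, end)`` intervals, 0-based half-open, listed in
        *transcription* order (descending genomic start on the minus strand).
    sequences:
        Optional per-exon nucleotide strings (transcript orientation),
        one per exon, each of the exon's length.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequences: list[str] | None = None

    def __post_init__(self) -> None:
        if "|" in self.gene_id:
            raise GeneModelError(f"gene_id may not contain '|': {self.gene_id!r}")
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: at least one exon required")
        for start, end in self.exons:
            if end <= start:
                raise GeneModelError(
                    f"{self.gene_id}: empty or inverted exon interval ({start}, {end})"
                )
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise GeneModelError(
                    f"{self.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        genomic = by_start if self.strand == "+" else by_start[::-1]
        if list(self.exons) != genomic:
            raise GeneModelError(
                f"{self.gene_id}: exons not in transcription order for strand {self.strand}"
            )
        if self.sequences is not None:
            if len(self.sequences) != len(self.exons):
                raise GeneModelError(f"{self.gene_id}: one sequence per exon required")
            for idx, ((start, end), seq) in enumerate(zip(self.exons, self.sequences)):
                if len(seq) != end - start:
                    raise GeneModelError(
                        f"{self.gene_id}: exon {idx} sequence length {len(seq)} "
                        f"!= interval length {end - start}"
                    )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, index: int) -> int:
        start, end = self.exons[index]
        return end - start

    def exon_sequence(self, index: int) -> str:
        if self.sequences is None:
            raise GeneModelError(f"{self.gene_id}: gene model carries no sequences")
        return self.sequences[index]

    @classmethod
    def from_exon_lengths(
        cls,
        gene_id: str,
        lengths: Sequence[int],
        *,
        chrom: str = "chrS",
        strand: str = "+",
        sequences: list[str] | None = None,
        intron_length: int = 100,
    ) -> "GeneModel":
        """Fabricate a plus-strand model from exon lengths (synthetic data)."""
        exons = []
        pos = 0
        for length in lengths:
            exons.append((pos, pos + length))
            pos += length + intron_length
        return cls(gene_id, chrom, strand, exons, sequences)


@dataclass
class JunctionReference:
    """Sequences representing every pairwise exon combination of each gene.

    Each entry is ``(key, sequence, boundary_offset)`` where
    ``sequence[:boundary_offset]`` is a suffix of the donor exon and
    ``sequence[boundary_offset:]`` a prefix of the acceptor exon.
    """

    entries: list[tuple[JunctionKey, str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> list[JunctionKey]:
        return [key for key, _, _ in self.entries]


def enumerate_junctions(gene: GeneModel) -> list[JunctionKey]:
    """All pairwise exon combinations (i, j) with i < j, sorted by (i, j).

    A single-exon gene has no junctions and yields an empty list; a gene with
    n exons yields n(n-1)/2 keys.
    """
    n = gene.n_exons
    return [
        JunctionKey(gene.gene_id, i, j) for i in range(n) for j in range(i + 1, n)
    ]


def default_flank(read_length: int = 50, min_anchor: int = 8) -> int:
    """Flank length so that any read anchored by >= min_anchor nt on each
    side of the boundary is fully contained in the junction entry."""
    if read_length <= 2 * min_anchor:
        raise GeneModelError("read_length must exceed twice the anchor length")
    return read_length - min_anchor


def build_junction_reference(
    genes: Iterable[GeneModel], left_flank: int = 42, right_flank: int = 42
) -> JunctionReference:
    """Concatenate exon flanks into one reference entry per junction.

    The donor contributes its last ``left_flank`` nt and the acceptor its
    first ``right_flank`` nt.  Exons shorter than the requested flank
    contribute their full sequence, and the boundary offset shrinks
    accordingly.
    """
    if left_flank < 1 or right_flank < 1:
        raise GeneModelError("flank lengths must be >= 1")
    entries: list[tuple[JunctionKey, str, int]] = []
    for gene in genes:
        if gene.sequences is None:
            raise GeneModelError(
                f"{gene.gene_id}: junction reference requires exon sequences"
            )
        for key in enumerate_junctions(gene):
            left = gene.exon_sequence(key.donor)[-left_flank:]
            right = gene.exon_sequence(key.acceptor)[:right_flank]
            entries.append((key, left + right, len(left)))
    return JunctionReference(entries)


def write_junction_fasta(reference: JunctionReference, path: str | Path) -> None:
    """Write the reference as FASTA with headers ``gene|donor|acceptor|offset``."""
    records = [
        SeqRecord(
            Seq(seq),
            id=f"{key.gene_id}|{key.donor}|{key.acceptor}|{offset}",
            description="",
        )
        for key, seq, offset in reference.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_junction_fasta(path: str | Path) -> JunctionReference:
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            gene_id, donor, acceptor, offset = record.id.split("|")
        except ValueError as exc:
            raise GeneModelError(
                f"malformed junction FASTA header: {record.id!r}"
            ) from exc
        entries.append(
            (JunctionKey(gene_id, int(donor), int(acceptor)), str(record.seq), int(offset))
        )
    return JunctionReference(entries)


# ---------------------------------------------------------------------------
# Annotation input
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (1-based closed) or BED12 (0-based half-open).

    GTF: only ``exon`` features are used; when a gene has several transcripts
    the one with the most exons is kept (ties broken by transcript id), since
    the triplet analysis assumes one linear exon chain per gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise GeneModelError(f"unknown annotation format: {format!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # transcript_id -> (gene_id, chrom, strand, [(start0, end)])
    transcripts: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    for feat in db.features_of_type("exon"):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GeneModelError(
                f"{path}: exon feature missing gene_id/transcript_id attribute"
            ) from exc
        entry = transcripts.setdefault(tx_id, (gene_id, feat.seqid, feat.strand, []))
        entry[3].append((feat.start - 1, feat.end))

    best: dict[str, tuple[str, str, str, str, list[tuple[int, int]]]] = {}
    for tx_id in sorted(transcripts):
        gene_id, chrom, strand, exons = transcripts[tx_id]
        if gene_id not in best or len(exons) > len(best[gene_id][4]):
            best[gene_id] = (tx_id, gene_id, chrom, strand, exons)

    models = []
    for gene_id in sorted(best):
        _, _, chrom, strand, exons = best[gene_id]
        exons = sorted(exons)
        if strand == "-":
            exons = exons[::-1]
        models.append(GeneModel(gene_id, chrom, strand, exons))
    return models


def _prevalidate_gtf(path: Path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise GeneModelError(
                    f"{path}:{lineno}: malformed GTF line (fewer than 9 tab fields)"
                )


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise GeneModelError(
                    f"{path}:{lineno}: BED12 requires 12 tab fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise GeneModelError(f"{path}:{lineno}: unparseable BED12 field") from exc
            if not (len(sizes) == len(offsets) == block_count):
                raise GeneModelError(
                    f"{path}:{lineno}: blockCount does not match blockSizes/blockStarts"
                )
            exons = [(start + off, start + off + size) for off, size in zip(offsets, sizes)]
            exons = sorted(exons)
            if strand == "-":
                exons = exons[::-1]
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def write_gene_summary(genes: Iterable[GeneModel], path: str | Path) -> None:
    """TSV summary: gene_id, chrom, strand, n_exons, comma-joined exon lengths."""
    with open(path, "w") as handle:
        handle.write("gene_id\tchrom\tstrand\tn_exons\texon_lengths\n")
        for gene in genes:
            lengths = ",".join(str(gene.exon_length(i)) for i in range(gene.n_exons))
            handle.write(
                f"{gene.gene_id}\t{gene.chrom}\t{gene.strand}\t{gene.n_exons}\t{lengths}\n"
            )


# ---------------------------------------------------------------------------
# rbfox1 exon-6 assay fixture
# ---------------------------------------------------------------------------

#: exon lengths of the synthetic rbfox1 model, transcription order.
#: Exon 6 (index 5) is the 61-nt cassette exon; the flanking-primer assay
#: spans 100 nt of exon 5 plus 98 nt of exon 7 (198 nt without the cassette).
#: The remaining lengths are arbitrary but fixed.
_RBFOX1_EXON_LENGTHS = (120, 90, 150, 80, 130, 61, 110, 95)
_RBFOX1_ASSAY = {
    "left": (4, 130 - 100),  # primer 5' end 100 nt before the end of exon 5
    "right": (6, 98),  # primer 3' end 98 nt into exon 7
    "cassette": 5,
}


def rbfox1_fixture() -> tuple[GeneModel, dict]:
    """Synthetic rbfox1 gene model reproducing the exon-6 splice assay.

    The flanking-primer RT-PCR across exon 6 yields a 259-bp product when the
    61-nt exon 6 is included and a 198-bp product when it is skipped.  Exon
    sequences are deterministic pseudo-random nucleotides.

    Returns the gene model and the assay description accepted by
    :func:`amplicon_length` (keys ``left``, ``right``, ``cassette``).
    """
    rng = np.random.default_rng(20150815)
    sequences = ["".join(rng.choice(_NT, size=n)) for n in _RBFOX1_EXON_LENGTHS]
    gene = GeneModel.from_exon_lengths(
        "rbfox1_fixture", _RBFOX1_EXON_LENGTHS, sequences=sequences
    )
    return gene, dict(_RBFOX1_ASSAY)


def amplicon_length(
    gene: GeneModel,
    assay: dict,
    included_exons: set[int] | frozenset[int],
) -> int:
    """RT-PCR product length for a given set of included exons.

    ``assay['left']`` is ``(exon_index, offset)`` of the forward primer's 5'
    end within its exon; ``assay['right']`` is ``(exon_index, offset)`` of the
    reverse primer's 3' end.  The product is the sum of included exonic
    lengths between and including the two anchor positions.  Both primer
    exons must be included (they are constitutive by assumption).
    """
    (left_exon, left_offset) = assay["left"]
    (right_exon, right_offset) = assay["right"]
    if left_exon not in included_exons or right_exon not in included_exons:
        raise GeneModelError("primer exon excluded from included_exons")
    if left_exon > right_exon:
        raise GeneModelError("left primer exon must not follow right primer exon")
    if left_exon == right_exon:
        return max(0, right_offset - left_offset)
    length = (gene.exon_length(left_exon) - left_offset) + right_offset
    for idx in range(left_exon + 1, right_exon):
        if idx in included_exons:
            length += gene.exon_length(idx)
    return length
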