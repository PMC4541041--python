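"""Assign reads to junction reference entries and normalize coverages.

A read counts for a junction only if it matches the junction's reference
sequence at an offset that covers the splice boundary with at least
``min_anchor`` nt on each side — a read lying entirely within one exon's
flank says nothing about splicing and is left unassigned.  Reads matching
entries of more than one junction are discarded as ambiguous rather than
assigned fractionally.

Two normalizations are provided: RPKM (reads per kilobase of exon model per
million mapped reads) for expression levels, and ppm (a junction's reads as
parts per million of all junction-assigned reads in the sample) for junction
usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .gene_models import JunctionKey, JunctionReference

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    pass


@dataclass
class JunctionCountTable:
    """Per-sample junction read counts with the sample's totals.

    ``total_junction_reads`` always equals the sum of ``counts``;
    ``total_mapped_reads`` covers all mapped reads and defaults to the
    junction total when no genome-wide mapping exists (simulated data).
    """

    sample_id: str
    counts: dict[JunctionKey, int]
    total_mapped_reads: int
    total_junction_reads: int
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_too_short: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise QuantError(f"{self.sample_id}: negative junction count")
        total = sum(self.counts.values())
        if self.total_junction_reads != total:
            raise QuantError(
                f"{self.sample_id}: total_junction_reads {self.total_junction_reads} "
                f"!= sum of counts {total}"
            )
        if self.total_junction_reads > self.total_mapped_reads:
            raise QuantError(
                f"{self.sample_id}: junction reads exceed total mapped reads"
            )

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: dict[JunctionKey, int],
        total_mapped_reads: int | None = None,
        **kwargs,
    ) -> "JunctionCountTable":
        total = sum(counts.values())
        return cls(
            sample_id,
            dict(counts),
            total if total_mapped_reads is None else total_mapped_reads,
            total,
            **kwargs,
        )

    def get(self, key: JunctionKey) -> int:
        return self.counts.get(key, 0)


@dataclass
class ExpressionRecord:
    feature_id: str
    raw_count: int
    length_bp: int
    rpkm: float


def rpkm(raw_count: int, length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if length_bp <= 0:
        raise QuantError("length_bp must be positive")
    if total_mapped_reads <= 0:
        raise QuantError("total_mapped_reads must be positive")
    return raw_count / (length_bp / 1000.0) / (total_mapped_reads / 1e6)


def junction_ppm(count: int, total_junction_reads: int) -> float:
    """A junction's reads as parts per million of all junction reads."""
    if total_junction_reads <= 0:
        raise QuantError("total_junction_reads must be positive")
    return 1e6 * count / total_junction_reads


def expression_records(
    features: Sequence[tuple[str, int, int]], total_mapped_reads: int
) -> list[ExpressionRecord]:
    """RPKM-normalize ``(feature_id, raw_count, length_bp)`` triples."""
    return [
        ExpressionRecord(fid, raw, length, rpkm(raw, length, total_mapped_reads))
        for fid, raw, length in features
    ]


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA/FASTQ path, SeqRecords, or pairs."""
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
        for record in SeqIO.parse(str(path), fmt):
            yield record.id, str(record.seq)
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item
        else:  # SeqRecord
            yield item.id, str(item.seq)


def _spanning_window(boundary: int, entry_len: int, read_len: int, min_anchor: int):
    """Admissible start offsets for a read of read_len covering the boundary
    with >= min_anchor nt on both sides; empty range if impossible."""
    lo = max(0, boundary - (read_len - min_anchor))
    hi = min(boundary - min_anchor, entry_len - read_len)
    return lo, hi


def count_junction_reads(
    reads,
    reference: JunctionReference,
    *,
    min_anchor: int = 8,
    mode: str = "exact",
    max_mismatch: int = 2,
    sample_id: str = "sample",
    total_mapped_reads: int | None = None,
) -> JunctionCountTable:
    """Count reads against a junction reference.

    Parameters
    ----------
    reads:
        FASTA/FASTQ path, iterable of SeqRecords, or ``(name, seq)`` pairs.
    mode:
        ``exact`` — a read must equal a boundary-spanning substring of an
        entry; ``hamming`` — up to ``max_mismatch`` mismatches are allowed.
    min_anchor:
        Minimum overlap with both sides of the splice boundary.

    A read matching entries of more than one junction is discarded
    (``n_ambiguous``); one matching nothing, or shorter than twice the
    anchor, is tallied separately.
    """
    if len(reference) == 0:
        raise QuantError("empty junction reference")
    if mode not in {"exact", "hamming"}:
        raise QuantError(f"unknown matching mode {mode!r}")

    counts: dict[JunctionKey, int] = {}
    n_ambiguous = n_unassigned = n_too_short = 0
    # exact mode: hash every admissible boundary-spanning window, per length
    window_index: dict[int, dict[str, set[JunctionKey]]] = {}

    def _index_for(read_len: int) -> dict[str, set[JunctionKey]]:
        if read_len not in window_index:
            index: dict[str, set[JunctionKey]] = {}
            for key, seq, boundary in reference.entries:
                lo, hi = _spanning_window(boundary, len(seq), read_len, min_anchor)
                for start in range(lo, hi + 1):
                    index.setdefault(seq[start : start + read_len], set()).add(key)
            window_index[read_len] = index
        return window_index[read_len]

    for _, seq in _iter_reads(reads):
        if len(seq) < 2 * min_anchor:
            n_too_short += 1
            continue
        if mode == "exact":
            hits = _index_for(len(seq)).get(seq, set())
        else:
            hits = _hamming_hits(seq, reference, min_anchor, max_mismatch)
        if len(hits) == 1:
            key = next(iter(hits))
            counts[key] = counts.get(key, 0) + 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_unassigned += 1

    if n_too_short:
        logger.info("%s: %d reads shorter than 2x anchor skipped", sample_id, n_too_short)
    if n_ambiguous:
        logger.info("%s: %d ambiguous reads discarded", sample_id, n_ambiguous)
    return JunctionCountTable.from_counts(
        sample_id,
        counts,
        total_mapped_reads,
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
        n_too_short=n_too_short,
    )


def _hamming_hits(
    seq: str, reference: JunctionReference, min_anchor: int, max_mismatch: int
) -> set[JunctionKey]:
    hits: set[JunctionKey] = set()
    read_len = len(seq)
    for key, entry, boundary in reference.entries:
        if key in hits:
            continue
        lo, hi = _spanning_window(boundary, len(entry), read_len, min_anchor)
        for start in range(lo, hi + 1):
            window = entry[start : start + read_len]
            mism = 0
            for a, b in zip(seq, window):
                if a != b:
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                hits.add(key)
                break
    return hits


def ppm_table(table: JunctionCountTable) -> pd.DataFrame:
    """Per-junction counts and ppm for one sample, sorted by key."""
    rows = [
        {
            "gene_id": k.gene_id,
            "donor": k.donor,
            "acceptor": k.acceptor,
            "count": v,
            "ppm": junction_ppm(v, table.total_junction_reads),
        }
        for k, v in sorted(table.counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "donor", "acceptor", "count", "ppm"])
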