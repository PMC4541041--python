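"""Splice-out scoring, event detection and classification.

For a cassette exon, the skipping fraction in one sample is

    sigma = skip / (skip + (up + down) / 2)

computed on ppm-normalized junction coverages (with equal-length junction
entries the per-sample normalization cancels; it is applied anyway so that
coverages of the two samples are on a common scale before the comparison).
The removal score contrasts two samples,

    score(A, B) = sigma_A - sigma_B  in [-1, 1],

positive when the exon is spliced out more in A than in B.  The score is
exactly antisymmetric, so applying it a second time with the samples swapped
detects removal in either direction; an event is called when either
direction reaches the threshold.  Called events are then classified by the
test:reference PSI ratio: above 1 + delta increased inclusion, below
1 - delta increased exclusion, otherwise no difference.

The scoring function is pluggable (``score_fn`` of ``detect_events``) so an
alternative removal statistic can be swapped in without touching detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd
from scipy import stats

from .gene_models import GeneModel
from .junction_quant import JunctionCountTable, junction_ppm
from .psi_core import (
    DEFAULT_MIN_COVERAGE,
    ExonTriplet,
    PSIRecord,
    extract_triplets,
    inclusion_density,
    make_psi_record,
)

logger = logging.getLogger(__name__)

LABEL_INCLUSION = "increased_inclusion"
LABEL_EXCLUSION = "increased_exclusion"
LABEL_NONE = "no_difference"
LABEL_UNDETERMINED = "undetermined"

DEFAULT_THRESHOLD = 0.2
DEFAULT_DELTA = 0.1


@dataclass
class SpliceEvent:
    """A cassette exon called as differentially spliced between two samples."""

    gene_id: str
    cassette_index: int
    score_fwd: float  # removal in test relative to reference
    score_rev: float  # after swapping the samples (= -score_fwd)
    psi_record: PSIRecord
    label: str
    tissue: str = ""

    @property
    def identity(self) -> tuple[str, int]:
        return (self.gene_id, self.cassette_index)


def skipping_fraction(
    triplet: ExonTriplet, total_junction_reads: int, inclusion_mode: str = "mean"
) -> float:
    """ppm-based fraction of the triplet's density on the skipping junction."""
    skip = junction_ppm(triplet.skip_count, total_junction_reads)
    up = junction_ppm(triplet.up_count, total_junction_reads)
    down = junction_ppm(triplet.down_count, total_junction_reads)
    if inclusion_mode == "mean":
        inc = (up + down) / 2.0
    elif inclusion_mode == "sum":
        inc = up + down
    else:
        raise ValueError(f"unknown inclusion_mode {inclusion_mode!r}")
    denom = skip + inc
    if denom == 0.0:
        raise ValueError("skipping fraction undefined for an all-zero triplet")
    return skip / denom


def score_exon_removal(
    triplet_a: ExonTriplet,
    triplet_b: ExonTriplet,
    total_a: int,
    total_b: int,
    inclusion_mode: str = "mean",
) -> float:
    """Removal score for one cassette exon: sigma_A - sigma_B in [-1, 1].

    Both triplets must describe the same cassette exon and are assumed to
    have passed the coverage filter.
    """
    if (triplet_a.gene_id, triplet_a.cassette_index) != (
        triplet_b.gene_id,
        triplet_b.cassette_index,
    ):
        raise ValueError("triplets refer to different cassette exons")
    return skipping_fraction(triplet_a, total_a, inclusion_mode) - skipping_fraction(
        triplet_b, total_b, inclusion_mode
    )


def classify_event(psi_record: PSIRecord, delta: float = DEFAULT_DELTA) -> str:
    """Label a called event by its test:reference PSI ratio.

    ratio > 1 + delta: increased inclusion; ratio < 1 - delta: increased
    exclusion; in between: no difference.  A zero reference PSI with a
    positive test PSI is an extreme inclusion gain; zero over zero is no
    difference.  Any other undefined ratio is 'undetermined' and excluded
    from summary counts.
    """
    if psi_record.psi_ratio is None:
        if "ref_zero" in psi_record.flags:
            if psi_record.psi_test is not None and psi_record.psi_test > 0.0:
                return LABEL_INCLUSION
            return LABEL_NONE
        return LABEL_UNDETERMINED
    if psi_record.psi_ratio > 1.0 + delta:
        return LABEL_INCLUSION
    if psi_record.psi_ratio < 1.0 - delta:
        return LABEL_EXCLUSION
    return LABEL_NONE


def _passes_coverage(
    triplet: ExonTriplet, min_coverage: float, inclusion_mode: str
) -> bool:
    return inclusion_density(triplet, inclusion_mode) + triplet.skip_count >= min_coverage


def detect_events(
    table_test: JunctionCountTable,
    table_ref: JunctionCountTable,
    genes: Iterable[GeneModel],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    delta: float = DEFAULT_DELTA,
    inclusion_mode: str = "mean",
    tissue: str = "",
    score_fn: Callable[[ExonTriplet, ExonTriplet, int, int, str], float] | None = None,
    fisher: bool = False,
) -> list[SpliceEvent]:
    """Scan every cassette triplet, score both directions, select and label.

    The score is computed test-vs-reference (``score_fwd``) and again with
    the samples swapped (``score_rev``); the exon is called when either
    direction reaches ``threshold``.  Triplets below ``min_coverage`` in
    either sample are skipped.  Output is sorted by |score| descending, ties
    broken by (gene_id, cassette_index).

    With ``fisher=True`` a two-sided Fisher exact test on the 2x2 table
    (inclusion reads, skip reads) x (test, ref) with Benjamini-Hochberg
    correction is attached to each event (``fisher_q`` attribute) as an
    annotation only — it plays no part in selection.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    score = score_fn or score_exon_removal
    events: list[SpliceEvent] = []
    n_low_coverage = 0
    for gene in genes:
        if gene.n_exons < 3:
            continue
        trip_test = extract_triplets(gene, table_test)
        trip_ref = extract_triplets(gene, table_ref)
        for t_test, t_ref in zip(trip_test, trip_ref):
            if t_test.total == 0 and t_ref.total == 0:
                continue  # cassette without any junction evidence
            if not (
                _passes_coverage(t_test, min_coverage, inclusion_mode)
                and _passes_coverage(t_ref, min_coverage, inclusion_mode)
            ):
                n_low_coverage += 1
                continue
            fwd = score(
                t_test,
                t_ref,
                table_test.total_junction_reads,
                table_ref.total_junction_reads,
                inclusion_mode,
            )
            rev = score(
                t_ref,
                t_test,
                table_ref.total_junction_reads,
                table_test.total_junction_reads,
                inclusion_mode,
            )
            if max(fwd, rev) < threshold:
                continue
            record = make_psi_record(t_test, t_ref, min_coverage, inclusion_mode)
            events.append(
                SpliceEvent(
                    gene_id=gene.gene_id,
                    cassette_index=t_test.cassette_index,
                    score_fwd=fwd,
                    score_rev=rev,
                    psi_record=record,
                    label=classify_event(record, delta),
                    tissue=tissue,
                )
            )
    if n_low_coverage:
        logger.info(
            "%d triplets skipped below min_coverage=%s", n_low_coverage, min_coverage
        )
    events.sort(key=lambda e: (-abs(e.score_fwd), e.gene_id, e.cassette_index))
    if fisher and events:
        _annotate_fisher(events, table_test, table_ref)
    return events


def _annotate_fisher(
    events: list[SpliceEvent],
    table_test: JunctionCountTable,
    table_ref: JunctionCountTable,
) -> None:
    from .gene_models import JunctionKey

    pvalues = []
    for event in events:
        def _counts(table: JunctionCountTable) -> tuple[int, int]:
            g, i = event.gene_id, event.cassette_index
            inc = table.get(JunctionKey(g, i - 1, i)) + table.get(JunctionKey(g, i, i + 1))
            skip = table.get(JunctionKey(g, i - 1, i + 1))
            return inc, skip

        inc_t, skip_t = _counts(table_test)
        inc_r, skip_r = _counts(table_ref)
        _, p = stats.fisher_exact([[inc_t, skip_t], [inc_r, skip_r]])
        pvalues.append(p)
    qvalues = stats.false_discovery_control(pvalues, method="bh")
    for event, q in zip(events, qvalues):
        event.fisher_q = float(q)


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        r = e.psi_record
        row = {
            "tissue": e.tissue,
            "gene_id": e.gene_id,
            "cassette_index": e.cassette_index,
            "score_fwd": e.score_fwd,
            "score_rev": e.score_rev,
            "psi_test": r.psi_test,
            "psi_ref": r.psi_ref,
            "psi_ratio": r.psi_ratio,
            "label": e.label,
            "coverage_test": r.coverage_test,
            "coverage_ref": r.coverage_ref,
            "flags": ";".join(sorted(r.flags)),
        }
        if hasattr(e, "fisher_q"):
            row["fisher_q"] = e.fisher_q
        rows.append(row)
    columns = [
        "tissue",
        "gene_id",
        "cassette_index",
        "score_fwd",
        "score_rev",
        "psi_test",
        "psi_ref",
        "psi_ratio",
        "label",
        "coverage_test",
        "coverage_ref",
        "flags",
    ]
    if any("fisher_q" in r for r in rows):
        columns.append("fisher_q")
    return pd.DataFrame(rows, columns=columns)


def write_events(events: Iterable[SpliceEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False, float_format="%.6g")
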