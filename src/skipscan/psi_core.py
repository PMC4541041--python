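"""Percent-spliced-in (PSI) estimation for cassette exon triplets.

Each internal exon i of a gene defines a triplet: the upstream inclusion
junction (i-1, i), the downstream inclusion junction (i, i+1), and the
skipping junction (i-1, i+1).  PSI is the ratio of the inclusion read
density to the sum of inclusion and exclusion densities, on the 0-100
percent scale: 100% means the exon is always included, 0% never.

Density here means reads per contributing junction: the two inclusion
junctions are averaged (summation is available via ``inclusion_mode``) and
the single skipping junction is taken as-is.  Junction reference entries
have equal length, so explicit length normalization cancels.  A PSI is
undefined (None) below ``min_coverage`` total density, where the estimate
is numerically unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gene_models import GeneModel, JunctionKey
from .junction_quant import JunctionCountTable

DEFAULT_MIN_COVERAGE = 10


@dataclass(frozen=True)
class ExonTriplet:
    """Junction read counts around one cassette exon in one sample."""

    gene_id: str
    cassette_index: int
    up_count: int
    down_count: int
    skip_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if min(self.up_count, self.down_count, self.skip_count) < 0:
            raise ValueError("triplet counts must be non-negative")

    @property
    def total(self) -> int:
        return self.up_count + self.down_count + self.skip_count


@dataclass
class PSIRecord:
    """PSI in test and reference samples for one cassette exon."""

    gene_id: str
    cassette_index: int
    psi_test: float | None
    psi_ref: float | None
    psi_ratio: float | None
    coverage_test: int
    coverage_ref: int
    flags: frozenset[str] = field(default_factory=frozenset)


def extract_triplets(gene: GeneModel, table: JunctionCountTable) -> list[ExonTriplet]:
    """One triplet per internal exon; missing junction keys count as zero.

    Genes with fewer than three exons have no internal exon and yield an
    empty list.
    """
    triplets = []
    for i in range(1, gene.n_exons - 1):
        triplets.append(
            ExonTriplet(
                gene_id=gene.gene_id,
                cassette_index=i,
                up_count=table.get(JunctionKey(gene.gene_id, i - 1, i)),
                down_count=table.get(JunctionKey(gene.gene_id, i, i + 1)),
                skip_count=table.get(JunctionKey(gene.gene_id, i - 1, i + 1)),
                sample_id=table.sample_id,
            )
        )
    return triplets


def inclusion_density(triplet: ExonTriplet, inclusion_mode: str = "mean") -> float:
    if inclusion_mode == "mean":
        return (triplet.up_count + triplet.down_count) / 2.0
    if inclusion_mode == "sum":
        return float(triplet.up_count + triplet.down_count)
    raise ValueError(f"unknown inclusion_mode {inclusion_mode!r}")


def compute_psi(
    triplet: ExonTriplet,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    inclusion_mode: str = "mean",
) -> float | None:
    """PSI in percent, or None below the coverage floor.

    PSI = 100 * D_inc / (D_inc + D_exc) with D_inc the (mean) inclusion
    junction count and D_exc the skipping junction count.
    """
    d_inc = inclusion_density(triplet, inclusion_mode)
    d_exc = float(triplet.skip_count)
    if d_inc + d_exc < min_coverage:
        return None
    return 100.0 * d_inc / (d_inc + d_exc)


def psi_ratio(
    psi_test: float | None, psi_ref: float | None
) -> tuple[float | None, frozenset[str]]:
    """Test:reference PSI ratio with flags.

    Returns ``(ratio, flags)``.  The ratio is undefined (None) when either
    PSI is undefined or the reference PSI is zero; the ``ref_zero`` flag
    marks the latter so downstream classification can treat a positive test
    PSI over a zero reference as an extreme inclusion gain.
    """
    if psi_test is None or psi_ref is None:
        return None, frozenset({"undefined_psi"})
    if psi_ref == 0.0:
        return None, frozenset({"ref_zero"})
    return psi_test / psi_ref, frozenset()


def make_psi_record(
    triplet_test: ExonTriplet,
    triplet_ref: ExonTriplet,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    inclusion_mode: str = "mean",
) -> PSIRecord:
    """Pair the test and reference triplets of one cassette into a record."""
    if (triplet_test.gene_id, triplet_test.cassette_index) != (
        triplet_ref.gene_id,
        triplet_ref.cassette_index,
    ):
        raise ValueError("triplets refer to different cassette exons")
    p_test = compute_psi(triplet_test, min_coverage, inclusion_mode)
    p_ref = compute_psi(triplet_ref, min_coverage, inclusion_mode)
    ratio, flags = psi_ratio(p_test, p_ref)
    return PSIRecord(
        gene_id=triplet_test.gene_id,
        cassette_index=triplet_test.cassette_index,
        psi_test=p_test,
        psi_ref=p_ref,
        psi_ratio=ratio,
        coverage_test=triplet_test.total,
        coverage_ref=triplet_ref.total,
        flags=flags,
    )
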