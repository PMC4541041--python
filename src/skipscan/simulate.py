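"""Synthetic two-condition junction-count datasets with known splicing truth.

The generator emulates the statistical structure the downstream analysis
assumes: a pooled library per condition (no replicate variance by default),
per-gene junction depths drawn Poisson around library_size x relative
expression (scaled so the sample's expected junction-read total equals
library_size), and for each cassette exon a Binomial split of the gene depth
into inclusion
(upstream and downstream junctions, independent draws at the true inclusion
level psi) and skipping (one junction at 1 - psi) reads.  Constitutive
junctions not adjacent to a cassette carry the full gene total.  Optional
Beta-Binomial overdispersion (``rho``) adds extra-binomial variance.

Read-level output re-expresses each junction count as 50-bp single-end reads
sampled uniformly over boundary-spanning start positions, for exercising the
junction counter end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_models import (
    GeneModel,
    JunctionKey,
    build_junction_reference,
    default_flank,
)
from .junction_quant import JunctionCountTable

logger = logging.getLogger(__name__)

_NT = np.array(list("ACGT"))

LABEL_INCLUSION = "increased_inclusion"
LABEL_EXCLUSION = "increased_exclusion"
LABEL_NONE = "no_difference"


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    n_exons: int
    expression_weight: float


@dataclass(frozen=True)
class CassetteSpec:
    """A planted cassette exon with its true inclusion level per condition."""

    gene_id: str
    exon_index: int
    psi_control: float
    psi_test: float


@dataclass
class SimTruth:
    """Ground truth driving one two-condition simulation."""

    genes: list[SimGene]
    cassettes: list[CassetteSpec]
    library_size: float
    seed: int
    n_replicates: int = 1
    overdispersion: float = 0.0  # Beta-Binomial rho; 0 = pure Binomial
    delta: float = 0.1  # ratio band for the implied truth label

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise SimConfigError("library_size must be positive")
        if not self.genes:
            raise SimConfigError("gene list must not be empty")
        n_exons = {g.gene_id: g.n_exons for g in self.genes}
        if any(g.expression_weight <= 0 for g in self.genes):
            raise SimConfigError("expression weights must be positive")
        seen: set[tuple[str, int]] = set()
        by_gene: dict[str, list[int]] = {}
        for cas in self.cassettes:
            if cas.gene_id not in n_exons:
                raise SimConfigError(f"cassette references unknown gene {cas.gene_id}")
            n = n_exons[cas.gene_id]
            if not (0 < cas.exon_index < n - 1):
                raise SimConfigError(
                    f"{cas.gene_id}: cassette index {cas.exon_index} not internal (n={n})"
                )
            if not (0.0 <= cas.psi_control <= 1.0 and 0.0 <= cas.psi_test <= 1.0):
                raise SimConfigError("psi values must lie in [0, 1]")
            if (cas.gene_id, cas.exon_index) in seen:
                raise SimConfigError(
                    f"duplicate cassette {cas.gene_id}:{cas.exon_index}"
                )
            seen.add((cas.gene_id, cas.exon_index))
            by_gene.setdefault(cas.gene_id, []).append(cas.exon_index)
        for gene_id, idxs in by_gene.items():
            idxs = sorted(idxs)
            if any(b - a < 2 for a, b in zip(idxs, idxs[1:])):
                raise SimConfigError(
                    f"{gene_id}: cassette exons must not be adjacent"
                )


@dataclass
class SimOutput:
    count_tables: dict[str, JunctionCountTable]
    truth_table: pd.DataFrame
    reads: dict[str, list[SeqRecord]] | None = None
    gene_models: list[GeneModel] | None = None


def _truth_label(psi_control: float, psi_test: float, delta: float) -> str:
    if psi_control == 0.0:
        return LABEL_INCLUSION if psi_test > 0.0 else LABEL_NONE
    ratio = psi_test / psi_control
    if ratio > 1.0 + delta:
        return LABEL_INCLUSION
    if ratio < 1.0 - delta:
        return LABEL_EXCLUSION
    return LABEL_NONE


def _truth_frame(truth: SimTruth) -> pd.DataFrame:
    rows = []
    for cas in truth.cassettes:
        ratio = np.nan if cas.psi_control == 0 else cas.psi_test / cas.psi_control
        rows.append(
            {
                "gene_id": cas.gene_id,
                "cassette_index": cas.exon_index,
                "psi_control": cas.psi_control,
                "psi_test": cas.psi_test,
                "psi_ratio_true": ratio,
                "label": _truth_label(cas.psi_control, cas.psi_test, truth.delta),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cassette_index",
            "psi_control",
            "psi_test",
            "psi_ratio_true",
            "label",
        ],
    )


def _binomial(rng: np.random.Generator, n: int, p: float, rho: float) -> int:
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    if rho > 0.0:
        nu = 1.0 / rho - 1.0
        p = rng.beta(p * nu, (1.0 - p) * nu)
    return int(rng.binomial(n, p))


def simulate_counts(truth: SimTruth) -> SimOutput:
    """Draw junction-count tables for every condition x replicate.

    Each gene receives a Poisson-distributed read depth proportional to its
    expression weight; every constitutive junction not adjacent to a
    cassette carries that depth, while a cassette exon at true inclusion
    level psi splits it into Binomial(depth, psi) reads on each inclusion
    junction (independent draws) and Binomial(depth, 1 - psi) on the
    skipping junction.  Depths are scaled so the expected junction-read
    total per sample equals ``library_size``.

    Sample ids are ``control_rep<k>`` and ``test_rep<k>``.  Each sample uses
    an independent child of the truth seed, so replicates are independent and
    the whole output is reproducible bit-exactly from (truth, seed).
    """
    seeds = np.random.SeedSequence(truth.seed).spawn(2 * truth.n_replicates)
    weights = np.array([g.expression_weight for g in truth.genes], dtype=float)
    cassettes_by_gene: dict[str, list[CassetteSpec]] = {}
    for cas in truth.cassettes:
        cassettes_by_gene.setdefault(cas.gene_id, []).append(cas)

    tables: dict[str, JunctionCountTable] = {}
    sample_idx = 0
    for condition in ("control", "test"):
        # Per-gene sequencing depth is scaled so the expected junction-read
        # total of the sample equals library_size: each gene contributes its
        # depth once per constitutive junction and (1 + psi) x depth per
        # cassette (up + down + skip in expectation), so the multiplicity is
        # (n_exons - 1) + sum_cassettes (psi - 1).
        multiplicity = []
        for gene in truth.genes:
            m = gene.n_exons - 1
            for cas in cassettes_by_gene.get(gene.gene_id, []):
                psi = cas.psi_control if condition == "control" else cas.psi_test
                m += psi - 1.0
            multiplicity.append(m)
        depth_mean = (
            truth.library_size
            * weights
            / float(np.dot(weights, np.array(multiplicity)))
        )
        for rep in range(1, truth.n_replicates + 1):
            rng = np.random.default_rng(seeds[sample_idx])
            sample_idx += 1
            counts: dict[JunctionKey, int] = {}
            for gene, lam in zip(truth.genes, depth_mean):
                total = int(rng.poisson(lam))
                if total == 0:
                    continue
                cassette_adjacent: set[int] = set()
                for cas in cassettes_by_gene.get(gene.gene_id, []):
                    c = cas.exon_index
                    psi = cas.psi_control if condition == "control" else cas.psi_test
                    up = _binomial(rng, total, psi, truth.overdispersion)
                    down = _binomial(rng, total, psi, truth.overdispersion)
                    skip = _binomial(rng, total, 1.0 - psi, truth.overdispersion)
                    if up:
                        counts[JunctionKey(gene.gene_id, c - 1, c)] = up
                    if down:
                        counts[JunctionKey(gene.gene_id, c, c + 1)] = down
                    if skip:
                        counts[JunctionKey(gene.gene_id, c - 1, c + 1)] = skip
                    cassette_adjacent.update({c - 1, c})
                for i in range(gene.n_exons - 1):
                    if i not in cassette_adjacent:
                        counts[JunctionKey(gene.gene_id, i, i + 1)] = total
            sample_id = f"{condition}_rep{rep}"
            tables[sample_id] = JunctionCountTable.from_counts(sample_id, counts)
    return SimOutput(count_tables=tables, truth_table=_truth_frame(truth))


def simulate_gene_models(
    truth: SimTruth,
    *,
    min_exon: int = 80,
    max_exon: int = 300,
    seed: int | None = None,
) -> list[GeneModel]:
    """Fabricate sequence-bearing gene models matching the truth's gene list.

    Exon lengths are uniform in [min_exon, max_exon]; sequences are i.i.d.
    nucleotides.  Deterministic given the (derived) seed.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    models = []
    for gene in truth.genes:
        lengths = rng.integers(min_exon, max_exon + 1, size=gene.n_exons)
        sequences = ["".join(rng.choice(_NT, size=n)) for n in lengths]
        models.append(
            GeneModel.from_exon_lengths(gene.gene_id, list(lengths), sequences=sequences)
        )
    return models


def simulate_reads(
    truth: SimTruth,
    genes: list[GeneModel] | None = None,
    read_length: int = 50,
    *,
    min_anchor: int = 8,
) -> SimOutput:
    """Simulate counts, then emit each count as boundary-spanning reads.

    Every read of a junction covers its splice boundary by at least
    ``min_anchor`` nt on both sides; start positions are uniform over the
    admissible window.  Read names encode the true junction
    (``gene|donor|acceptor|serial``) so counting can be checked read by read.
    Junctions whose flanks cannot host an anchored read are skipped with a
    warning.
    """
    if read_length < 2 * min_anchor:
        raise SimConfigError("read_length must be at least twice min_anchor")
    if genes is None:
        genes = simulate_gene_models(truth)
    by_id = {g.gene_id: g for g in genes}
    missing = [g.gene_id for g in truth.genes if g.gene_id not in by_id]
    if missing:
        raise SimConfigError(f"gene models missing for: {missing[:3]}...")

    flank = default_flank(read_length, min_anchor)
    reference = build_junction_reference(
        [by_id[g.gene_id] for g in truth.genes], flank, flank
    )
    entry_map = {key: (seq, off) for key, seq, off in reference.entries}

    output = simulate_counts(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    reads: dict[str, list[SeqRecord]] = {}
    n_skipped = 0
    for sample_id, table in output.count_tables.items():
        records: list[SeqRecord] = []
        realized: dict[JunctionKey, int] = {}
        for key in sorted(table.counts):
            count = table.counts[key]
            seq, boundary = entry_map[key]
            lo = max(0, boundary - (read_length - min_anchor))
            hi = min(boundary - min_anchor, len(seq) - read_length)
            if hi < lo:
                n_skipped += 1
                continue
            starts = rng.integers(lo, hi + 1, size=count)
            for serial, start in enumerate(starts):
                rec = SeqRecord(
                    Seq(seq[start : start + read_length]),
                    id=f"{key.gene_id}|{key.donor}|{key.acceptor}|{sample_id}.{serial}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * read_length
                records.append(rec)
            realized[key] = count
        reads[sample_id] = records
        # keep the count tables in sync with what was actually emitted
        output.count_tables[sample_id] = JunctionCountTable.from_counts(
            sample_id, realized
        )
    if n_skipped:
        logger.warning(
            "%d junction/sample pairs skipped: flanks shorter than min_anchor",
            n_skipped,
        )
    output.reads = reads
    output.gene_models = genes
    return output


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    from Bio import SeqIO

    return SeqIO.write(list(records), str(path), "fastq")


def write_truth(truth_table: pd.DataFrame, path: str | Path) -> None:
    """Write the ground-truth table as TSV (lossless round-trip)."""
    truth_table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_table(table: JunctionCountTable, path: str | Path) -> None:
    rows = [
        {"gene_id": k.gene_id, "donor": k.donor, "acceptor": k.acceptor, "count": v}
        for k, v in sorted(table.counts.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "donor", "acceptor", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_count_table(
    path: str | Path, sample_id: str, total_mapped_reads: int | None = None
) -> JunctionCountTable:
    frame = pd.read_csv(path, sep="\t")
    counts = {
        JunctionKey(str(r.gene_id), int(r.donor), int(r.acceptor)): int(r.count)
        for r in frame.itertuples()
    }
    return JunctionCountTable.from_counts(sample_id, counts, total_mapped_reads)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_truth(
    seed: int = 17,
    *,
    n_genes: int = 300,
    n_events: int = 30,
    n_null_cassettes: int = 60,
    delta_psi: float = 0.3,
    library_size: float = 1e5,
    weight_sigma: float = 0.8,
) -> SimTruth:
    """Desk-scale default dataset: 300 genes of 4-10 exons, 30 differential
    cassette exons with |delta psi| = 0.3, 60 unchanged cassette exons as
    background, expected 1e5 junction reads per sample.

    Expression weights are log-normal (sigma 0.8), a moderate realistic
    spread for a pooled embryo library at this scale.
    """
    rng = np.random.default_rng(seed)
    genes = [
        SimGene(
            f"gene{i:04d}",
            int(rng.integers(4, 11)),
            float(rng.lognormal(0.0, weight_sigma)),
        )
        for i in range(n_genes)
    ]
    n_cassettes = n_events + n_null_cassettes
    if n_cassettes > n_genes:
        raise SimConfigError("more cassettes requested than genes available")
    chosen = rng.choice(n_genes, size=n_cassettes, replace=False)
    cassettes = []
    for rank, gene_idx in enumerate(chosen):
        gene = genes[gene_idx]
        exon_index = int(rng.integers(1, gene.n_exons - 1))
        if rank < n_events:
            # alternate gain and loss of inclusion
            if rank % 2 == 0:
                psi_control = float(rng.uniform(0.1, 1.0 - delta_psi))
                psi_test = psi_control + delta_psi
            else:
                psi_control = float(rng.uniform(delta_psi, 0.9))
                psi_test = psi_control - delta_psi
        else:
            psi_control = psi_test = float(rng.uniform(0.2, 0.8))
        cassettes.append(CassetteSpec(gene.gene_id, exon_index, psi_control, psi_test))
    return SimTruth(genes=genes, cassettes=cassettes, library_size=library_size, seed=seed)


def null_truth(seed: int = 17, **kwargs) -> SimTruth:
    """Same structure as :func:`default_truth` but no differential events."""
    return default_truth(seed, n_events=0, **kwargs)


def two_tissue_truths(
    seed: int = 17,
    *,
    n_genes: int = 200,
    n_shared_concordant: int = 8,
    n_discordant: int = 4,
    n_heart_only: int = 10,
    n_other_only: int = 6,
    library_size: float = 1e5,
    delta_psi: float = 0.3,
) -> tuple[dict[str, SimTruth], pd.DataFrame]:
    """Two tissues sharing one gene set, with planted concordant, discordant
    and tissue-exclusive differential events.

    Discordant events change inclusion in opposite directions in the two
    tissues (the flot2a pattern: inclusion gain in heart, near-complete
    exclusion in the whole fish).  Returns per-tissue truths and an expected
    cross-tissue assignment table (gene_id, cassette_index, category, labels).
    """
    rng = np.random.default_rng(seed)
    genes = [
        SimGene(f"gene{i:04d}", int(rng.integers(4, 11)), float(rng.lognormal(0.0, 0.8)))
        for i in range(n_genes)
    ]
    n_total = n_shared_concordant + n_discordant + n_heart_only + n_other_only
    chosen = rng.choice(n_genes, size=n_total, replace=False)
    heart_cas: list[CassetteSpec] = []
    other_cas: list[CassetteSpec] = []
    expected_rows = []

    def _pair(direction: str) -> tuple[float, float]:
        if direction == "up":
            base = float(rng.uniform(0.1, 1.0 - delta_psi))
            return base, base + delta_psi
        base = float(rng.uniform(delta_psi + 0.05, 0.9))
        return base, base - delta_psi

    cursor = 0
    for _ in range(n_shared_concordant):
        gene = genes[chosen[cursor]]
        cursor += 1
        idx = int(rng.integers(1, gene.n_exons - 1))
        direction = "up" if rng.random() < 0.5 else "down"
        hc, ht = _pair(direction)
        oc, ot = _pair(direction)
        heart_cas.append(CassetteSpec(gene.gene_id, idx, hc, ht))
        other_cas.append(CassetteSpec(gene.gene_id, idx, oc, ot))
        expected_rows.append((gene.gene_id, idx, "both_concordant"))
    for _ in range(n_discordant):
        gene = genes[chosen[cursor]]
        cursor += 1
        idx = int(rng.integers(1, gene.n_exons - 1))
        hc, ht = _pair("up")  # inclusion gain in heart
        oc, ot = float(rng.uniform(0.5, 0.9)), 0.02  # near-complete exclusion
        heart_cas.append(CassetteSpec(gene.gene_id, idx, hc, ht))
        other_cas.append(CassetteSpec(gene.gene_id, idx, oc, ot))
        expected_rows.append((gene.gene_id, idx, "both_discordant"))
    for _ in range(n_heart_only):
        gene = genes[chosen[cursor]]
        cursor += 1
        idx = int(rng.integers(1, gene.n_exons - 1))
        hc, ht = _pair("up" if rng.random() < 0.5 else "down")
        heart_cas.append(CassetteSpec(gene.gene_id, idx, hc, ht))
        psi = float(rng.uniform(0.2, 0.8))
        other_cas.append(CassetteSpec(gene.gene_id, idx, psi, psi))
        expected_rows.append((gene.gene_id, idx, "heart_only"))
    for _ in range(n_other_only):
        gene = genes[chosen[cursor]]
        cursor += 1
        idx = int(rng.integers(1, gene.n_exons - 1))
        oc, ot = _pair("up" if rng.random() < 0.5 else "down")
        other_cas.append(CassetteSpec(gene.gene_id, idx, oc, ot))
        psi = float(rng.uniform(0.2, 0.8))
        heart_cas.append(CassetteSpec(gene.gene_id, idx, psi, psi))
        expected_rows.append((gene.gene_id, idx, "other_only"))

    truths = {
        "heart": SimTruth(genes=genes, cassettes=heart_cas, library_size=library_size, seed=seed * 2 + 1),
        "whole_fish": SimTruth(genes=genes, cassettes=other_cas, library_size=library_size, seed=seed * 2 + 2),
    }
    expected = pd.DataFrame(expected_rows, columns=["gene_id", "cassette_index", "category"])
    return truths, expected
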