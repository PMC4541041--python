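"""Cross-tissue comparison, isoform-diversity summary, and the pipeline driver.

Differential-splicing calls from two tissues are intersected by event
identity (gene, cassette exon index) into exclusive and shared sets; shared
events whose labels disagree between tissues are flagged discordant — the
pattern where the same exon gains inclusion in one tissue but is almost
completely excluded in the other.

The isoform-diversity summary counts, per gene, 1 + the number of distinct
skipping junctions supported by at least ``min_reads`` reads, and reports
the fraction of genes with one, two, or three-plus isoforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from . import __version__
from .gene_models import (
    GeneModel,
    build_junction_reference,
    default_flank,
    read_gene_models,
    write_junction_fasta,
)
from .junction_quant import JunctionCountTable, count_junction_reads
from .spliceout import (
    DEFAULT_DELTA,
    DEFAULT_THRESHOLD,
    SpliceEvent,
    detect_events,
    events_to_frame,
    write_events,
)
from .psi_core import DEFAULT_MIN_COVERAGE

logger = logging.getLogger(__name__)

EventId = tuple[str, int]


class ReportError(ValueError):
    pass


@dataclass
class TissueComparison:
    """Partition of differential-splicing calls across two tissues.

    ``heart_only``, ``other_only`` and ``both`` partition the union of event
    identities; ``discordant`` is the subset of ``both`` whose labels differ
    between the tissues.
    """

    heart_only: set[EventId]
    other_only: set[EventId]
    both: set[EventId]
    discordant: set[EventId]
    labels_heart: dict[EventId, str] = field(default_factory=dict)
    labels_other: dict[EventId, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _fmt(ids: set[EventId]) -> list[str]:
            return [f"{g}:{i}" for g, i in sorted(ids)]

        return {
            "n_heart_only": len(self.heart_only),
            "n_other_only": len(self.other_only),
            "n_both": len(self.both),
            "n_discordant": len(self.discordant),
            "heart_only": _fmt(self.heart_only),
            "other_only": _fmt(self.other_only),
            "both": _fmt(self.both),
            "discordant": _fmt(self.discordant),
        }


def _index_events(events: Iterable[SpliceEvent], tissue: str) -> dict[EventId, SpliceEvent]:
    indexed: dict[EventId, SpliceEvent] = {}
    for event in events:
        if event.identity in indexed:
            raise ReportError(
                f"duplicate event identity {event.identity} within tissue {tissue!r}"
            )
        indexed[event.identity] = event
    return indexed


def compare_tissues(
    events_heart: Iterable[SpliceEvent], events_other: Iterable[SpliceEvent]
) -> TissueComparison:
    """Intersect two tissues' calls by (gene, cassette) identity."""
    heart = _index_events(events_heart, "heart")
    other = _index_events(events_other, "other")
    both = set(heart) & set(other)
    discordant = {eid for eid in both if heart[eid].label != other[eid].label}
    return TissueComparison(
        heart_only=set(heart) - both,
        other_only=set(other) - both,
        both=both,
        discordant=discordant,
        labels_heart={eid: e.label for eid, e in heart.items()},
        labels_other={eid: e.label for eid, e in other.items()},
    )


def isoform_diversity(
    tables: JunctionCountTable | Iterable[JunctionCountTable],
    min_reads: int = 3,
) -> dict[str, float]:
    """Fraction of genes with 1, 2, or >= 3 junction-supported isoforms.

    A gene's isoform count is 1 + the number of distinct skipping junctions
    (acceptor > donor + 1) with at least ``min_reads`` reads, summed over the
    given tables.  Only genes with any junction evidence are counted; the
    three fractions sum to 1.
    """
    if min_reads < 1:
        raise ReportError("min_reads must be >= 1")
    if isinstance(tables, JunctionCountTable):
        tables = [tables]
    merged: dict = {}
    for table in tables:
        for key, count in table.counts.items():
            merged[key] = merged.get(key, 0) + count

    genes_with_evidence: set[str] = set()
    skip_junctions: dict[str, set[tuple[int, int]]] = {}
    for key, count in merged.items():
        if count > 0:
            genes_with_evidence.add(key.gene_id)
        if key.acceptor > key.donor + 1 and count >= min_reads:
            skip_junctions.setdefault(key.gene_id, set()).add((key.donor, key.acceptor))

    categories = {"1": 0, "2": 0, "3+": 0}
    for gene_id in genes_with_evidence:
        n_isoforms = 1 + len(skip_junctions.get(gene_id, set()))
        if n_isoforms == 1:
            categories["1"] += 1
        elif n_isoforms == 2:
            categories["2"] += 1
        else:
            categories["3+"] += 1
    total = len(genes_with_evidence)
    if total == 0:
        return {"1": 0.0, "2": 0.0, "3+": 0.0, "n_genes": 0}
    result = {k: v / total for k, v in categories.items()}
    result["n_genes"] = total
    return result


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS = {
    "min_anchor": 8,
    "min_coverage": DEFAULT_MIN_COVERAGE,
    "score_threshold": DEFAULT_THRESHOLD,
    "delta": DEFAULT_DELTA,
    "read_length": 50,
    "inclusion_mode": "mean",
    "isoform_min_reads": 3,
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full analysis described by a config mapping or file.

    Two input modes:

    - ``mode: simulate`` (default): generates per-tissue two-condition count
      tables from the built-in truth generator (``seed``, optional scale
      overrides under ``simulation``), runs detection per tissue, and, when
      two tissues are present, the cross-tissue comparison.
    - ``mode: counts``: ingests per-tissue count TSVs listed under
      ``tissues: {name: {test: path, ref: path}}`` with an ``annotation``
      (GTF or BED12) naming the gene models.

    Writes events TSV per tissue, a comparison JSON (two tissues), an
    isoform-diversity JSON, and a run manifest; returns the output directory.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = dict(config)
    out = Path(out_dir or config.get("out_dir", "skipscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    params = {**_DEFAULT_PARAMS, **config.get("params", {})}
    mode = config.get("mode", "simulate")
    manifest: dict = {
        "version": __version__,
        "mode": mode,
        "params": params,
        "stages": [],
        "complete": False,
    }

    try:
        if mode == "simulate":
            tissue_data = _stage_simulate(config, params, out, manifest)
        elif mode == "counts":
            tissue_data = _stage_ingest(config, params, manifest)
        else:
            raise ReportError(f"config: unknown mode {mode!r}")

        events_by_tissue: dict[str, list[SpliceEvent]] = {}
        all_tables: list[JunctionCountTable] = []
        for tissue, (genes, table_test, table_ref) in tissue_data.items():
            events = detect_events(
                table_test,
                table_ref,
                genes,
                threshold=params["score_threshold"],
                min_coverage=params["min_coverage"],
                delta=params["delta"],
                inclusion_mode=params["inclusion_mode"],
                tissue=tissue,
            )
            events_by_tissue[tissue] = events
            write_events(events, out / f"events_{tissue}.tsv")
            all_tables.extend([table_test, table_ref])
            manifest["stages"].append(f"events:{tissue}:{len(events)}")

        diversity = isoform_diversity(all_tables, params["isoform_min_reads"])
        (out / "isoform_diversity.json").write_text(json.dumps(diversity, indent=2))
        manifest["stages"].append("isoform_diversity")

        if len(tissue_data) == 2:
            t1, t2 = list(events_by_tissue)
            comparison = compare_tissues(events_by_tissue[t1], events_by_tissue[t2])
            (out / "comparison.json").write_text(
                json.dumps({"tissues": [t1, t2], **comparison.to_dict()}, indent=2)
            )
            manifest["stages"].append("comparison")
        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _stage_simulate(config, params, out: Path, manifest) -> dict:
    from . import simulate as sim

    seed = int(config.get("seed", 17))
    manifest["seed"] = seed
    sim_cfg = dict(config.get("simulation", {}))
    two_tissue = sim_cfg.pop("two_tissue", False)
    tissue_data = {}
    if two_tissue:
        truths, expected = sim.two_tissue_truths(seed, **sim_cfg)
        expected.to_csv(out / "planted_events.tsv", sep="\t", index=False)
        for tissue, truth in truths.items():
            output = sim.simulate_counts(truth)
            sim.write_truth(output.truth_table, out / f"truth_{tissue}.tsv")
            genes = [
                GeneModel.from_exon_lengths(g.gene_id, [100] * g.n_exons)
                for g in truth.genes
            ]
            tissue_data[tissue] = (
                genes,
                output.count_tables["test_rep1"],
                output.count_tables["control_rep1"],
            )
            manifest["stages"].append(f"simulate:{tissue}")
    else:
        truth = sim.default_truth(seed, **sim_cfg)
        output = sim.simulate_counts(truth)
        sim.write_truth(output.truth_table, out / "truth.tsv")
        genes = [
            GeneModel.from_exon_lengths(g.gene_id, [100] * g.n_exons)
            for g in truth.genes
        ]
        tissue_data["default"] = (
            genes,
            output.count_tables["test_rep1"],
            output.count_tables["control_rep1"],
        )
        manifest["stages"].append("simulate")
    for tissue, (_, t_test, t_ref) in tissue_data.items():
        from .simulate import write_count_table

        write_count_table(t_test, out / f"counts_{tissue}_test.tsv")
        write_count_table(t_ref, out / f"counts_{tissue}_control.tsv")
    return tissue_data


def _stage_ingest(config, params, manifest) -> dict:
    from .simulate import read_count_table

    if "annotation" not in config:
        raise ReportError("config: 'annotation' path is required in counts mode")
    fmt = config.get("annotation_format", "gtf")
    genes = read_gene_models(config["annotation"], fmt)
    manifest["stages"].append(f"annotation:{len(genes)} genes")
    tissues = config.get("tissues")
    if not tissues:
        raise ReportError("config: 'tissues' mapping is required in counts mode")
    tissue_data = {}
    for tissue, paths in tissues.items():
        table_test = read_count_table(paths["test"], f"{tissue}_test")
        table_ref = read_count_table(paths["ref"], f"{tissue}_ref")
        tissue_data[tissue] = (genes, table_test, table_ref)
        manifest["stages"].append(f"ingest:{tissue}")
    return tissue_data
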