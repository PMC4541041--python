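"""Generator determinism, the Binomial splitting model, and truth output."""

import numpy as np
import pandas as pd
import pytest

from skipscan.gene_models import JunctionKey
from skipscan.simulate import (
    CassetteSpec,
    SimConfigError,
    SimGene,
    SimTruth,
    default_truth,
    read_truth,
    simulate_counts,
    simulate_reads,
    two_tissue_truths,
    write_truth,
)


def one_gene_truth(psi_control, psi_test, *, library=3000.0, seed=5, n_replicates=1):
    return SimTruth(
        genes=[SimGene("g", 3, 1.0)],
        cassettes=[CassetteSpec("g", 1, psi_control, psi_test)],
        library_size=library,
        seed=seed,
        n_replicates=n_replicates,
    )


class TestSimulateCounts:
    def test_same_truth_and_seed_reproduce_counts_bit_exactly(self):
        truth = default_truth(3, n_genes=40, n_events=5, n_null_cassettes=5)
        a = simulate_counts(truth)
        b = simulate_counts(truth)
        for sample in a.count_tables:
            assert a.count_tables[sample].counts == b.count_tables[sample].counts

    def test_full_inclusion_yields_no_skipping_reads(self):
        truth = one_gene_truth(1.0, 1.0, n_replicates=5)
        output = simulate_counts(truth)
        for table in output.count_tables.values():
            assert table.get(JunctionKey("g", 0, 2)) == 0

    def test_replicates_are_independent_draws(self):
        truth = one_gene_truth(0.5, 0.5, n_replicates=2)
        output = simulate_counts(truth)
        t1 = output.count_tables["control_rep1"].counts
        t2 = output.count_tables["control_rep2"].counts
        assert t1 != t2

    def test_mean_inclusion_fraction_matches_binomial_model(self):
        """Monte Carlo: 1000 samples at psi=0.7, gene depth mean 500."""
        psi = 0.7
        # multiplicity for a 3-exon gene with one cassette: 2 + (psi - 1)
        truth = one_gene_truth(psi, psi, library=500 * (2 + psi - 1), n_replicates=500)
        output = simulate_counts(truth)
        fractions = []
        for table in output.count_tables.values():
            up = table.get(JunctionKey("g", 0, 1))
            down = table.get(JunctionKey("g", 1, 2))
            skip = table.get(JunctionKey("g", 0, 2))
            inc = (up + down) / 2
            fractions.append(inc / (inc + skip))
        assert len(fractions) == 1000
        assert abs(np.mean(fractions) - psi) < 0.01

    def test_sample_totals_concentrate_around_library_size(self):
        truth = default_truth(11, n_genes=200, n_events=10, n_null_cassettes=20)
        output = simulate_counts(truth)
        for table in output.count_tables.values():
            # Poisson-scale tolerance: totals within 5 sd of the target
            assert abs(table.total_junction_reads - truth.library_size) < 5 * np.sqrt(
                truth.library_size * 10
            )

    def test_empirical_psi_converges_to_truth_at_high_depth(self):
        rng = np.random.default_rng(0)
        genes = [SimGene(f"g{i}", 4, 1.0) for i in range(200)]
        cassettes = [
            CassetteSpec(f"g{i}", int(rng.integers(1, 3)), p, p)
            for i, p in enumerate(rng.uniform(0.1, 0.9, size=200))
        ]
        multiplicity = 3 - 1 + np.mean([c.psi_control for c in cassettes])
        truth = SimTruth(
            genes=genes,
            cassettes=cassettes,
            library_size=5000 * multiplicity * 200,
            seed=8,
        )
        output = simulate_counts(truth)
        table = output.count_tables["control_rep1"]
        errors = []
        for cas in cassettes:
            up = table.get(JunctionKey(cas.gene_id, cas.exon_index - 1, cas.exon_index))
            down = table.get(JunctionKey(cas.gene_id, cas.exon_index, cas.exon_index + 1))
            skip = table.get(
                JunctionKey(cas.gene_id, cas.exon_index - 1, cas.exon_index + 1)
            )
            inc = (up + down) / 2
            errors.append(abs(inc / (inc + skip) - cas.psi_control))
        assert np.mean(errors) <= 0.005

    def test_config_validation(self):
        with pytest.raises(SimConfigError):
            SimTruth(genes=[], cassettes=[], library_size=1e4, seed=1)
        with pytest.raises(SimConfigError):
            SimTruth(genes=[SimGene("g", 3, 1.0)], cassettes=[], library_size=0, seed=1)
        with pytest.raises(SimConfigError, match="not internal"):
            one_gene = [SimGene("g", 3, 1.0)]
            SimTruth(
                genes=one_gene,
                cassettes=[CassetteSpec("g", 0, 0.5, 0.5)],
                library_size=1e4,
                seed=1,
            )


class TestSimulateReads:
    def test_reads_are_substrings_of_their_junction_entry(self):
        from skipscan.gene_models import build_junction_reference
        from skipscan.simulate import simulate_gene_models

        truth = one_gene_truth(0.6, 0.4, library=200, seed=9)
        output = simulate_reads(truth, read_length=50, min_anchor=8)
        genes = output.gene_models
        ref = build_junction_reference(genes, 42, 42)
        entries = {key: seq for key, seq, _ in ref.entries}
        for records in output.reads.values():
            for rec in records:
                gene_id, donor, acceptor, _ = rec.id.split("|")
                key = JunctionKey(gene_id, int(donor), int(acceptor))
                assert str(rec.seq) in entries[key]

    def test_reads_anchor_both_sides_of_boundary(self):
        from skipscan.gene_models import build_junction_reference

        truth = one_gene_truth(0.5, 0.5, library=200, seed=9)
        output = simulate_reads(truth, read_length=50, min_anchor=8)
        ref = build_junction_reference(output.gene_models, 42, 42)
        info = {key: (seq, off) for key, seq, off in ref.entries}
        for records in output.reads.values():
            for rec in records:
                gene_id, donor, acceptor, _ = rec.id.split("|")
                seq, boundary = info[JunctionKey(gene_id, int(donor), int(acceptor))]
                start = seq.index(str(rec.seq))
                assert boundary - start >= 8
                assert start + 50 - boundary >= 8

    def test_read_counts_match_count_table(self):
        truth = one_gene_truth(0.5, 0.5, library=300, seed=10)
        output = simulate_reads(truth, read_length=50)
        for sample_id, records in output.reads.items():
            assert len(records) == output.count_tables[sample_id].total_junction_reads

    def test_read_length_must_fit_anchors(self):
        with pytest.raises(SimConfigError):
            simulate_reads(one_gene_truth(0.5, 0.5), read_length=10, min_anchor=8)


class TestTruthTable:
    @pytest.mark.parametrize(
        "psi_control,psi_test,ratio,label",
        [
            (0.8, 0.4, 0.5, "increased_exclusion"),
            (0.5, 0.5, 1.0, "no_difference"),
            (0.4, 0.8, 2.0, "increased_inclusion"),
        ],
    )
    def test_ratio_and_label(self, psi_control, psi_test, ratio, label, tmp_path):
        truth = one_gene_truth(psi_control, psi_test)
        row = simulate_counts(truth).truth_table.iloc[0]
        assert row.psi_ratio_true == pytest.approx(ratio)
        assert row.label == label

    def test_round_trips_through_tsv(self, tmp_path):
        truth = default_truth(2, n_genes=30, n_events=4, n_null_cassettes=4)
        table = simulate_counts(truth).truth_table
        path = tmp_path / "truth.tsv"
        write_truth(table, path)
        again = read_truth(path)
        pd.testing.assert_frame_equal(table, again, check_exact=False, atol=1e-9)

    def test_empty_cassette_spec_gives_header_only_file(self, tmp_path):
        truth = SimTruth(
            genes=[SimGene("g", 3, 1.0)], cassettes=[], library_size=100, seed=1
        )
        path = tmp_path / "truth.tsv"
        write_truth(simulate_counts(truth).truth_table, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene_id\t")


class TestTwoTissueTruths:
    def test_tissues_share_genes_but_not_seeds(self):
        truths, expected = two_tissue_truths(4)
        heart, other = truths["heart"], truths["whole_fish"]
        assert [g.gene_id for g in heart.genes] == [g.gene_id for g in other.genes]
        assert heart.seed != other.seed
        assert set(expected.category) == {
            "both_concordant",
            "both_discordant",
            "heart_only",
            "other_only",
        }

    def test_discordant_events_flip_direction(self):
        truths, expected = two_tissue_truths(4)
        heart = {(c.gene_id, c.exon_index): c for c in truths["heart"].cassettes}
        other = {(c.gene_id, c.exon_index): c for c in truths["whole_fish"].cassettes}
        for row in expected[expected.category == "both_discordant"].itertuples():
            hc = heart[(row.gene_id, row.cassette_index)]
            oc = other[(row.gene_id, row.cassette_index)]
            assert hc.psi_test > hc.psi_control  # inclusion gain in heart
            assert oc.psi_test < 0.1  # near-complete exclusion elsewhere
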