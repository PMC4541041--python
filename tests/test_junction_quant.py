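"""Read counting against junction references, and RPKM/ppm normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skipscan.gene_models import (
    JunctionKey,
    JunctionReference,
    build_junction_reference,
)
from skipscan.junction_quant import (
    JunctionCountTable,
    QuantError,
    count_junction_reads,
    junction_ppm,
    ppm_table,
    rpkm,
)
from conftest import make_table, random_gene


def brute_force_count(reads, reference, min_anchor):
    """Independent oracle: test every read against every entry at every offset."""
    counts: dict[JunctionKey, int] = {}
    n_ambiguous = 0
    for _, seq in reads:
        hits = set()
        for key, entry, boundary in reference.entries:
            for start in range(len(entry) - len(seq) + 1):
                if entry[start : start + len(seq)] != seq:
                    continue
                if boundary - start >= min_anchor and start + len(seq) - boundary >= min_anchor:
                    hits.add(key)
        if len(hits) == 1:
            key = hits.pop()
            counts[key] = counts.get(key, 0) + 1
        elif len(hits) > 1:
            n_ambiguous += 1
    return counts, n_ambiguous


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,length,total,expected",
        [(10, 500, 1_000_000, 20.0), (0, 500, 1_000_000, 0.0), (1000, 1000, 10**6, 1000.0)],
    )
    def test_rpkm_closed_form(self, raw, length, total, expected):
        assert rpkm(raw, length, total) == pytest.approx(expected)

    def test_rpkm_linear_in_counts(self):
        assert rpkm(20, 777, 12345) == pytest.approx(2 * rpkm(10, 777, 12345))

    def test_rpkm_domain_errors(self):
        with pytest.raises(QuantError):
            rpkm(1, 0, 1000)
        with pytest.raises(QuantError):
            rpkm(1, 100, 0)

    @pytest.mark.parametrize("count,total,expected", [(5, 1000, 5000.0), (7, 7, 1e6)])
    def test_ppm_definition(self, count, total, expected):
        assert junction_ppm(count, total) == pytest.approx(expected)

    def test_ppm_sums_to_one_million_over_a_sample(self, rng):
        counts = {
            ("g", int(i), int(j)): int(c)
            for (i, j), c in zip(
                [(0, 1), (1, 2), (0, 2), (2, 3), (1, 3)],
                rng.integers(1, 500, size=5),
            )
        }
        table = make_table("s", counts)
        frame = ppm_table(table)
        assert frame.ppm.sum() == pytest.approx(1e6, rel=1e-6)


class TestCountTableInvariants:
    def test_totals_consistency_enforced(self):
        with pytest.raises(QuantError):
            JunctionCountTable("s", {JunctionKey("g", 0, 1): 5}, 10, 4)

    def test_junction_reads_cannot_exceed_mapped_reads(self):
        with pytest.raises(QuantError):
            JunctionCountTable("s", {JunctionKey("g", 0, 1): 5}, 3, 5)


class TestCountJunctionReads:
    def test_anchored_exact_matching(self):
        gene = random_gene("g", 3, np.random.default_rng(7), min_exon=60, max_exon=60)
        ref = build_junction_reference([gene], 42, 42)
        entry = ref.entries[0]  # junction (0,1), boundary at 42
        seq, boundary = entry[1], entry[2]
        spanning = seq[boundary - 20 : boundary + 20]
        inside_one_exon = seq[:40]  # never crosses the boundary with anchors
        table = count_junction_reads(
            [("r1", spanning), ("r2", inside_one_exon)], ref, min_anchor=8
        )
        assert table.get(entry[0]) == 1
        assert table.n_unassigned == 1

    def test_read_matching_two_junctions_is_discarded(self):
        shared = "ACGTACGTACGTACGTACGT"
        ref = JunctionReference(
            entries=[
                (JunctionKey("g1", 0, 1), "A" * 10 + shared + "C" * 10, 20),
                (JunctionKey("g2", 0, 1), "T" * 10 + shared + "G" * 10, 20),
            ]
        )
        table = count_junction_reads([("r", shared)], ref, min_anchor=8)
        assert table.total_junction_reads == 0
        assert table.n_ambiguous == 1

    def test_short_reads_skipped(self):
        gene = random_gene("g", 2, np.random.default_rng(7))
        ref = build_junction_reference([gene], 42, 42)
        table = count_junction_reads([("r", "ACGTACGTACGTAC")], ref, min_anchor=8)
        assert table.n_too_short == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(QuantError):
            count_junction_reads([("r", "ACGT" * 15)], JunctionReference(), min_anchor=8)

    def test_counting_is_order_independent(self, rng):
        genes = [random_gene(f"g{i}", 4, rng) for i in range(3)]
        ref = build_junction_reference(genes, 42, 42)
        reads = []
        for key, seq, boundary in ref.entries[:10]:
            reads.append((f"{key}", seq[boundary - 25 : boundary + 25]))
        fwd = count_junction_reads(reads, ref, min_anchor=8)
        rev = count_junction_reads(reads[::-1], ref, min_anchor=8)
        assert fwd.counts == rev.counts

    def test_hamming_mode_tolerates_mismatches(self):
        gene = random_gene("g", 2, np.random.default_rng(3), min_exon=60, max_exon=60)
        ref = build_junction_reference([gene], 42, 42)
        key, seq, boundary = ref.entries[0]
        read = list(seq[boundary - 25 : boundary + 25])
        read[3] = "A" if read[3] != "A" else "C"
        read[40] = "A" if read[40] != "A" else "C"
        mutated = "".join(read)
        exact = count_junction_reads([("r", mutated)], ref, min_anchor=8, mode="exact")
        fuzzy = count_junction_reads(
            [("r", mutated)], ref, min_anchor=8, mode="hamming", max_mismatch=2
        )
        assert exact.get(key) == 0
        assert fuzzy.get(key) == 1

    def test_matches_brute_force_oracle_on_random_reads(self, rng):
        genes = [random_gene(f"g{i}", int(rng.integers(2, 6)), rng) for i in range(4)]
        ref = build_junction_reference(genes, 42, 42)
        assert len(ref) <= 50
        reads = []
        for k in range(300):
            key, seq, boundary = ref.entries[int(rng.integers(0, len(ref)))]
            if rng.random() < 0.7:  # boundary-spanning window
                lo = max(0, boundary - 42)
                hi = min(boundary - 8, len(seq) - 50)
                start = int(rng.integers(lo, hi + 1))
                reads.append((f"r{k}", seq[start : start + 50]))
            else:  # random 50-mer, mostly unassignable
                reads.append((f"r{k}", "".join(rng.choice(list("ACGT"), size=50))))
        table = count_junction_reads(reads, ref, min_anchor=8)
        expected, expected_ambiguous = brute_force_count(reads, ref, 8)
        assert table.counts == expected
        assert table.n_ambiguous == expected_ambiguous

    def test_recovers_planted_counts_from_simulated_reads(self):
        from skipscan.gene_models import default_flank
        from skipscan.simulate import default_truth, simulate_reads

        truth = default_truth(
            21, n_genes=15, n_events=3, n_null_cassettes=3, library_size=3000
        )
        output = simulate_reads(truth, read_length=50, min_anchor=8)
        flank = default_flank(50, 8)
        ref = build_junction_reference(output.gene_models, flank, flank)
        for sample_id, records in output.reads.items():
            table = count_junction_reads(
                records, ref, min_anchor=8, sample_id=sample_id
            )
            planted = output.count_tables[sample_id]
            # every planted read must be recovered; ambiguous reads (possible
            # when two junctions share a window by chance) may only remove
            assert table.n_too_short == 0
            recovered = dict(table.counts)
            assert recovered == planted.counts


@settings(derandomize=True, max_examples=30)
@given(counts=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=12))
def test_ppm_conservation_property(counts):
    table = make_table(
        "s", {("g", i, i + 1): c for i, c in enumerate(counts)}
    )
    total = sum(junction_ppm(c, table.total_junction_reads) for c in counts)
    assert total == pytest.approx(1e6, rel=1e-9)
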