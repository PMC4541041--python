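# Methods

## Scope and data model

`skipscan` analyses single-exon (cassette) inclusion/exclusion events from
exon–exon junction read counts in a two-sample contrast (test vs
reference), optionally across two tissues. Each gene is one linear chain of
exons in transcription order (for annotations with several transcripts per
gene, the transcript with the most exons is kept). Multi-exon skips are
observed as junction evidence but differential calling is restricted to
exon triplets: one internal exon with its two flanking neighbours. Other
event classes — alternative 5'/3' splice sites, intron retention, mutually
exclusive exons — are out of scope.

Coordinates are 0-based half-open internally; GTF (1-based closed) is
converted on read, BED12 is native. Exon indices follow transcription
order, so triplets and PSI are defined on the transcript regardless of
strand.

## Junction reference and read counting

Every exon pair (i, j), i < j, of a gene becomes a reference entry: the
last `flank` nt of exon i joined to the first `flank` nt of exon j (shorter
exons contribute fully, and the recorded boundary offset shrinks). The
default flank is `read_length − min_anchor` = 42 for 50-bp reads: a read
required to overlap the boundary by at least `min_anchor` = 8 nt on each
side can cover at most 42 nt on one side, so anchored reads are always
fully contained in an entry. The 8-nt anchor guards against spurious
single-side matches; no maximum exon distance is imposed on the pairs.

Counting assigns a read to a junction when it matches a boundary-spanning
window of that junction's entry — exactly by default (the generator emits
error-free reads), or within `max_mismatch` Hamming mismatches in
`hamming` mode for noisy input. Exact mode hashes all admissible windows
per read length, so matching is a dictionary lookup. A read matching
windows of more than one junction is discarded as ambiguous, never split
fractionally; reads matching nothing, or shorter than twice the anchor,
are tallied separately. An optional decoy is unnecessary here because the
generator emits junction reads only; for real data the unassigned tally
plays that role.

## Quantification

- **ppm**: a junction's reads per million junction-assigned reads in its
  sample; the ppm mass of a sample sums to 1e6 by construction.
- **RPKM** = raw / (length/1000) / (total_mapped/1e6) for expression-level
  comparison. On simulated data, where no genome-wide mapping exists,
  `total_mapped_reads` defaults to the junction-read total.

## PSI and the removal score

For triplet counts (u, d, s) (upstream inclusion, downstream inclusion,
skipping):

- PSI = 100 · D_inc/(D_inc + D_exc) with D_inc = (u + d)/2, D_exc = s.
  The two inclusion junctions are *averaged*: with equal-length junction
  entries, a per-length density reduces to the plain count, and averaging
  keeps inclusion and exclusion evidence on the same per-junction scale
  (summing would double the inclusion weight; both are exposed via
  `inclusion_mode`). PSI is undefined below `min_coverage` = 10 units of
  density — low-coverage ratios are numerically unstable and a defined
  value there would be noise.
- Removal score: with skipping fraction σ = s/(s + (u+d)/2) on
  ppm-normalized coverages, score(A, B) = σ_A − σ_B. Within one sample the
  ppm normalization cancels in σ; it is applied regardless so the two
  samples enter the comparison on a common per-million scale, and so that
  alternative score functions plugged into `detect_events` (the `score_fn`
  hook) receive normalized coverages. The score equals (Ψ_B − Ψ_A)/100, is
  bounded in [−1, 1], and is exactly antisymmetric — applying it twice
  with the samples swapped, as detection does, treats removal in either
  sample symmetrically.
- Event selection: an exon is called when either direction's score reaches
  `threshold` = 0.2, a 20-PSI-point shift — large enough to clear binomial
  noise at the default coverage, small enough to catch the planted 0.3
  shifts. Output ordering is deterministic: |score| descending, ties by
  (gene_id, cassette_index).
- Classification by PSI ratio (test/reference): > 1 + δ increased
  inclusion, < 1 − δ increased exclusion, otherwise no difference, with
  δ = 0.1. A zero reference PSI with positive test PSI is an extreme
  inclusion gain (`ref_zero` flag); zero over zero is no difference; an
  otherwise undefined ratio is `undetermined` and excluded from summary
  counts. A score-selected event can still be ratio-neutral (label
  `no_difference`) — selection and classification are deliberately
  separate steps.
- Optional annotation: a two-sided Fisher exact test on (inclusion reads,
  skip reads) × (test, reference) with Benjamini–Hochberg correction can
  be attached per event. It is an extension for prioritisation only and
  never participates in selection.

## Two-tissue comparison and isoform diversity

Calls from two tissues are partitioned by event identity
(gene_id, cassette_index) — strictly finer than gene-level intersection,
so two distinct cassettes of one gene are never collapsed — into
tissue-exclusive and shared sets; shared events with disagreeing labels
are flagged discordant (inclusion gain in one tissue, exclusion in the
other). Isoform diversity is a junction-evidence proxy: a gene's isoform
count is 1 + the number of distinct skipping junctions supported by
`min_reads` = 3 reads, reported as fractions of genes with 1 / 2 / ≥3
isoforms over genes with any junction evidence.

## Synthetic data generator

The generator emulates a pooled-library two-condition design:

- Per-gene expression weights are log-normal (σ = 0.8), a moderate
  realistic spread for a pooled embryo library at desk scale.
- Per-gene read depth is Poisson with mean
  λ_g = library_size · w_g / Σ_h w_h·m_h, where the junction multiplicity
  m_h = (n_exons − 1) + Σ_cassettes(ψ − 1) counts each gene's expected
  junction reads per unit depth; the sample's expected junction-read total
  therefore equals `library_size` exactly.
- Constitutive junctions not adjacent to a cassette carry the gene depth;
  a cassette exon at true inclusion ψ receives independent
  Binomial(depth, ψ) draws on each inclusion junction and
  Binomial(depth, 1 − ψ) on the skipping junction. Optional Beta-Binomial
  overdispersion (ρ > 0) adds extra-binomial variance; the default ρ = 0
  matches a pooled design with no replicate variance model.
- Defaults: 300 genes of 4–10 exons, 30 differential cassette exons with
  |Δψ| = 0.3 (alternating gain and loss of inclusion), 60 unchanged
  cassette exons as background so that false-discovery measurement is
  non-trivial, expected 1e5 junction reads per sample. One pooled
  replicate per condition; `n_replicates` raises it.
- Two-tissue simulation builds two truths over one shared gene set with
  planted concordant, discordant (inclusion gain in heart, near-complete
  exclusion in the whole fish) and tissue-exclusive events.
- Read-level output re-expresses each junction count as 50-bp reads
  uniform over boundary-spanning start positions with ≥ 8 nt anchors,
  constant base quality, and names encoding the true junction.

What the generator does *not* emulate: sequencing errors, ambiguous
multi-gene mappability, fragment-length or positional bias, paired ends,
biological replicate variance (unless ρ > 0), and non-cassette splicing
noise (non-cassette triplets have exactly zero skipping reads). Passing
tests therefore demonstrate the correctness of the counting, estimation
and detection machinery under the stated model, not performance on real
libraries, where anchor choice, decoys and mismatch tolerance matter.

## Numerical and design choices

- Determinism: every stochastic step derives from one integer seed through
  independent spawned child generators per sample; identical truth + seed
  reproduces counts and reads bit-exactly, and pipeline runs with equal
  config + seed are byte-identical.
- Degenerate inputs: genes with < 3 exons yield no triplets; an all-zero
  triplet has no skipping fraction (detection skips cassettes with no
  evidence); empty junction references and invalid thresholds are
  rejected with explicit errors.
- Test problem sizes (counter fidelity at ~8k reads, estimator consistency
  at depth 5000 over 200 cassettes, recovery at the 300-gene default) are
  chosen so the full suite runs in seconds while keeping Monte-Carlo
  tolerances (±0.01 on a mean inclusion fraction, ±0.005 mean PSI error)
  comfortably above their standard errors.
- The rbfox1 fixture packages a synthetic 8-exon gene whose 61-nt exon 6
  and flanking-primer assay reproduce the 259-bp (inclusion) and 198-bp
  (skipping) RT-PCR products; all other exon lengths are arbitrary but
  fixed constants.

## Known limitations

- One test vs one reference sample per tissue; no dispersion-aware
  inference across replicates (replicates can be simulated but detection
  consumes one table per side).
- The removal score is a reconstruction from the quantities the method is
  defined over (junction coverages of two samples per exon); the
  `score_fn` hook exists precisely so an alternative statistic can be
  substituted.
- Exact-mode counting assumes error-free reads; `hamming` mode is a
  convenience for noisy input, not a replacement for a spliced aligner on
  real data.
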