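# Methods

## The editing statistic

At each reference position with base counts `n_A, n_C, n_G, n_T` and
coverage `N` (the sum of the counts; Ns and deleted bases are excluded),
the conversion frequency of an alternative base `b` is `f_b = n_b / N`. A
position is called an editing site when its best allowed conversion has
`f_b > t` with `t = 0.05` by default (**strict** inequality: a site at
exactly 5% is not called) and `N ≥ min_coverage` (default 10). Conversion
content is reported on the gene strand: under a minus-strand gene the
plus-strand ref/alt bases are complemented before labeling, so a
plus-strand G→A signal is reported as C-to-U. The allowed-content default
is {C-to-U, U-to-C, A-to-G, G-to-A} — the canonical plastid C↔U pairs plus
A↔G, which observed plastid site tables require — and an "all" mode
accepts any substitution. If two alternative bases both pass, the
higher-frequency one is reported and the site flagged multi-allelic.

There is deliberately no statistical error model (no binomial test): the
method is a plain frequency threshold, and its behaviour under sequencing
error is characterized by simulation instead (below).

`SitePileup.coverage` defaults to the sum of its counts — the invariant
for pileups built by this package. It may be supplied explicitly when
working from published per-site tables whose printed coverage includes
reads not broken out by base; the fixture-derived frequencies divide by
printed coverage for that reason.

## Alignment handling

SAM input is read with pysam. Unmapped, secondary and supplementary
records are skipped; a read is discarded entirely when its aligned bases
mismatch the reference at more than `max_mismatches` positions (default
2, emulating a strict short-read mapping filter). Inserted bases are
counted nowhere; deleted reference positions get no count. Base-quality
filtering defaults to off (reads are assumed quality-trimmed upstream);
a `min_base_quality` knob exists. Duplicate reads are not removed. Reads
mapping into the inverted repeats are counted at their reported position
only — no multi-mapping reallocation.

## Codon annotation

For a site in a protein gene, the CDS offset is `nt = pos − start + 1` on
plus-strand genes and `nt = end − pos + 1` on minus-strand genes; then
`aa_index = ⌈nt/3⌉` and `codon_pos = ((nt−1) mod 3) + 1`. The codon is
read from the spliced gene-strand sequence (genes are modelled
intronless), transcribed T→U, the edited base substituted, and both
codons translated under NCBI table 11 (the standard code for land-plant
plastids; 64 entries, AUG=M, UAA/UAG/UGA=stop). Classes:

- `start_gain` — `aa_index == 1` and the edited codon is AUG (elsewhere an
  ACG→AUG edit is ordinary nonsynonymous T→M);
- `stop_gain` / `stop_loss` — a stop appears/disappears;
- `synonymous` — equal amino acids, neither a stop (two stops differing
  in codon never count as synonymous);
- `nonsynonymous` — everything else.

Pseudogenes are detected generically as an internal stop in frame; this
also covers frameshift-type homopolymer defects without a dedicated
homopolymer analyzer.

Rows of the packaged site-table fixture are classified from their printed
codons; rows whose printed codons differ at more than one position (one
row) are classified anyway and flagged inconsistent. The fixture keeps
every printed value verbatim — including percentages that are
arithmetically inconsistent with their counts — alongside a recomputed
frequency column. Amino-acid spectra over the fixture use the table's
printed amino-acid letters; the synonymous/nonsynonymous split uses
classification from codons, and the count of printed synonymous flags is
reported separately because the two disagree for two rows.

## Expression

A read is assigned to the gene containing its alignment midpoint —
unambiguous single assignment without a transcript model; reads midway
over no gene stay unassigned. RPKM is
`assigned_reads × 10⁹ / (length_bp × total_assigned)`, zero iff no reads
were assigned; doubling all counts leaves RPKM unchanged. Ranking is by
RPKM descending with gene-name tie-break. The packaged expression fixture
is used only for ranking statements; its printed RPKM magnitudes cannot
be recomputed without the unpublished read counts.

## Intergenic-spacer identity

Spacers are the gaps (≥ 1 bp) between consecutive genes sorted by start
(tRNAs count as genes; overlapping or abutting genes yield nothing; a
gene nested in another never opens a spacer), named
`upstreamGene-downstreamGene` along the plus strand. Percent identity
comes from a global Needleman–Wunsch alignment with match +1, mismatch
−1, gap −2, and equals 100 × identical columns / total columns, gap
columns included in the denominator (so identity is sensitive to indels,
matching the hotspot intent). Spacers under 95% identity are hotspots
(strict `<`).

Identity over "the" optimal alignment is ill-defined when co-optimal
alignments disagree on identical-column counts, which would break the
symmetry of the measure. The DP therefore canonicalizes lexicographically:
maximize score, then identities, then prefer the fewest columns. This
makes identity exactly invariant under sequence swap and under joint
reverse complement. The DP is quadratic and written for spacer-scale
sequences (tens to a few thousand bp); Biopython's `PairwiseAligner`
under the same scores serves as an independent score cross-check in the
tests, not as the implementation. Published hotspot tables produced by
other aligners with unspecified scoring are not expected to be reproduced
number-for-number under this contract.

## RNA secondary structure

Folding is Nussinov base-pair maximization: the maximum number of nested
pairs (Watson–Crick plus G·U wobble by default) with hairpin loops of at
least `min_loop = 3` unpaired bases. Traceback is deterministic: the
pairing branch is preferred, taking the smallest admissible partner. This
is a combinatorial stand-in for thermodynamic folding — deterministic and
dependency-free, adequate for asking whether a single editing event
changes predicted pairing (`structure_delta` reports the symmetric
difference of the two pair sets), not for predicting real minimum-free-
energy structures or base-pair probabilities.

A subtlety surfaced by property testing: the maximum pair count is *not*
invariant under reverse complement when wobble is allowed, because a G·U
pair maps onto the unpairable A·C (a 28-nt sequence with maxima 8 vs 9
witnesses this). The invariance holds exactly, and is tested, for
Watson–Crick-only pairing.

## The simulator: what it emulates and what it does not

`SimulationConfig` defaults define the package's reference scenario:

| parameter | default | meaning |
|---|---|---|
| `lsc_len`, `ssc_len`, `ir_len` | 18 000 / 6 000 / 3 000 bp | reduced quadripartite geometry; IRB is the exact reverse complement of IRA |
| `n_genes` | 24 | intronless ATG…stop genes, no internal stops, both strands, single-copy regions only |
| `gene_codon_range` | 100–300 codons | gene sizes |
| `expression_weights` | log-uniform over one decade | heterogeneous expression |
| `n_editing_sites` | 20 | C-to-U/U-to-C sites, one gene at a time round-robin |
| `editing_fraction_range` | 0.15–0.9 | per-site target conversion fraction |
| `read_length` | 76 bp | RNA read length of the emulated platform |
| `error_rate` | 0.001/base | independent substitution errors (no indels, no quality scores) |
| `n_reads` | auto | smallest count giving ≥ 300× expected coverage at every injected site |

Editing is applied per read, Bernoulli-independently at the target
fraction — the sampling model the frequency statistic assumes. Injected
sites are restricted to gene interiors (at least one read length from
each end) so they sit in the flat-coverage zone, and outside start/stop
codons. Everything (FASTA, GFF3, SAM, truth tables) is byte-identical
under a fixed seed.

The recovery experiment (`run_recovery`) simulates the reference
scenario, calls sites, and scores sensitivity (over injected sites whose
target fraction exceeds the calling threshold) and false positives
(called positions never injected). Calling there uses
`min_coverage = 100`, matched to the scenario's ≥ 200× depth guarantee at
real sites: at ≥ 100× a position needs six or more co-located error reads
to cross 5% (probability ~10⁻¹³), whereas at the generic floor of 10 a
single error read among a dozen at a gene-end coverage ramp can exceed
5%. The scenario sizes (30 kb genome, ~10⁵–10⁵·⁵ reads) keep a full run
under ten seconds on one core.

What passing simulations do **not** show about real data: no intergenic
transcription (expression truth stays clean; the caller's IGS labeling is
exercised separately), no indel errors, no coverage biases, no
IR multi-mapping ambiguity, no splicing, and mapper behaviour is idealized
(truth alignments are exact; the SAM path adds only the mismatch filter).

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive throughout (GenBank/GFF3 convention).
Mean coverage (`reads × read_length / genome_length`) is reported to one
decimal and mapped fraction to two, matching how such numbers are
conventionally printed. Zero-coverage positions cannot yield frequencies
(error); empty alignment sets yield empty pileups and zero-valued
expression; an empty gene list is a valid plastome for everything except
read simulation. Thresholds outside (0, 1), genes outside sequence
bounds, non-RNA letters, and mismatched edit bases all raise `ValueError`
early with context.

## Known limitations

- Substitution-only editing; insertion/deletion editing is out of scope.
- Intronless gene models; trans-spliced or intron-containing genes must
  be provided pre-spliced.
- RPKM only; no TPM or isoform-aware quantification.
- The folding stand-in ignores thermodynamics; its structures are for
  differential comparison, not figure-quality prediction.
- The 91-row site-table fixture reflects its printed source exactly,
  including internal inconsistencies (duplicate count pairs across two
  gene pairs, one two-position codon change, a handful of percentage
  typos); summary counts over it are defined on the fixture as shipped.
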