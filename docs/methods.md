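# Methods

This note records what `adarcall` computes, the assumptions baked into each
stage, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Discovery model

Editing is detected as an RNA-vs-DNA-consensus mismatch whose frequency
collapses when the responsible deaminase is knocked down. The procedure is
a deterministic filter cascade — no statistical test, no multiple-testing
correction — so every threshold is an explicit part of the model:

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 0.80 | minimum gapped alignment identity per read |
| `min_aligned_fraction` | 0.80 | minimum fraction of the read aligned |
| `dna_variant_max` | 0.005 | DNA variant frequency above which a position is masked (strict >) |
| `min_dna_coverage` | 4 | DNA depth below which a position is unassessable and masked |
| `control_min_freq` | 0.02 | minimum mismatch frequency in each control replicate |
| `control_min_cov` | 10 | minimum coverage in each control replicate |
| `min_support_reads` | 4 | minimum unique reads carrying the alt in each control replicate |
| `kd_min_cov` | 4 | minimum coverage in each knockdown replicate |
| `max_kd_to_control_ratio` | 0.5 | knockdown frequency ceiling, relative to the mean control frequency |

Filter semantics and deliberate conventions:

- **Thresholds are inclusive** (≥ / ≤): the language of the procedure is
  "at least", so boundary evidence passes. The DNA mask is the one strict
  inequality: a variant frequency *above* 0.5 % masks.
- **Per-replicate enforcement.** The frequency, coverage and support
  floors apply to *every* control replicate, and the ≥ 50 % reduction to
  *every* knockdown replicate, measured against the mean control
  frequency. This is the stricter of the two defensible readings of
  "found in all four control samples … absent or reduced in all four
  knockdown samples"; pooled-control evidence and mean-vs-mean reduction
  are available as flags (`per_replicate_control`,
  `per_replicate_reduction`).
- **Unique supporting reads** are distinct read identifiers. In a pileup a
  read contributes at most one base per position, so the count of distinct
  supporting reads equals the base count unless a read id occurs in
  multiple records; identities are tracked explicitly when
  `collect_read_ids=True`.
- **Gapped identity** counts insertion and deletion columns in the
  denominator (matched = match-like columns − substitutions, with
  substitutions recovered from the NM-style edit distance). The upstream
  mapper's exact definition is not recoverable, so this CLC-style gapped
  definition is a documented, configurable choice.
- **Consensus calling** takes the plurality base over A/C/G/T; ties and
  uncovered positions keep the reference base (conservative and
  reproducible). The variant frequency pools all non-consensus bases into
  one scalar per position.
- **Multiple alt bases** at one position are evaluated independently; a
  position can in principle yield two calls.
- **No strand normalization.** Sites are reported in transcript-strand
  space, so A>G and T>C remain distinct classes and their sum is the
  A-to-I signature. Codon effects for T>C sites therefore refer to the
  assembled transcript's frame, not the antisense gene's.
- Coordinates are 0-based half-open internally; all written tables are
  1-based.

Because alignments are positioned on transcript coordinates and the
consensus differs from the reference only by substitutions, reads aligned
to the reference remain valid against the consensus; mismatch counting is
always performed against the consensus base.

## Detection power

With per-replicate depth $d$ and true editing frequency $f$, one control
replicate passes the floors with probability
$P\left(X \ge \max(4, \lceil 0.02\,d\rceil)\right)$, $X \sim \mathrm{Binom}(d, f)$,
and a site must pass in all $n$ controls independently
(`edcall.detection_power`). At 30× coverage this is ≈ 0.06 per replicate
for $f = 0.05$ and ≈ 0.88 for $f = 0.20$: the four-read support floor, not
the 2 % frequency floor, dominates at low coverage. Consequently, on
designs that plant sites uniformly over 5–60 % frequency at 30×, a
substantial minority of true sites is undetectable *by design*, and
empirical recall tracks the analytic power prediction (a tested property).
Perfect recall is only achievable where evidence floors are nearly
certainly met (higher coverage or higher editing frequencies); conditional
on the realized evidence passing the floors, recovery is exact (also a
tested property). Precision is essentially 1 in both clean and 1e-3-error
regimes, because random errors cannot reach a 2 % frequency with four
supporting reads in four independent replicates.

## Synthetic data

The generator emulates the experimental design the caller assumes:

- ~1 kb transcripts (default 30 of 800–1200 nt) at AT-rich, planarian-like
  base composition (GC 0.38), each carrying one planted ATG→stop ORF
  (≥ 300 nt) so annotation stages always have substrate;
- 40 editing sites planted on A (or T on the ~25 % of transcripts treated
  as antisense-assembled), at control frequencies uniform in 5–60 %,
  reduced by `kd_reduction` (default: complete loss) in the matching
  knockdown; non-matching knockdowns behave as controls;
- editing is per-read Bernoulli — each overlapping RNA read independently
  carries the alt base with the site's frequency; there is no molecular
  haplotype structure;
- DNA variants planted at per-base rate 1e-3 with population frequencies
  in a 0.3–1 % band straddling the 0.5 % mask cutoff (homozygous variants
  can be simulated by setting the frequency range to 1);
- fixed-length (100 nt) single-end reads with uniform starts at the
  nominal fold-coverage, uniform substitution error (default 1e-3),
  constant base quality; true alignments are emitted as SAM with correct
  CIGAR and NM;
- sites are planted in the read-length interior of each transcript, where
  realized depth matches nominal coverage, so the design's coverage regime
  is actually delivered at the sites;
- DNA variants appear in DNA reads only; RNA reads carry planted edits and
  errors. The 0.5 % mask is therefore exercised by the masking tests
  rather than by false-call pressure.

Everything is deterministic under `SimConfig.seed` (byte-identical files).
Not emulated: PCR duplicates, indels, quality-dependent error models,
paired ends, expression heterogeneity between replicates, splicing. Tests
passing on this generator show the *procedure* is implemented correctly
and behaves as its counting statistics predict; they do not certify
performance on real libraries, where mapping artifacts, duplicates and
strand bias add failure modes this model excludes.

## ORF, codon and context annotation

ORF prediction is the longest forward-strand ATG→stop frame (stop
included), ties broken 5'-most, minimum 150 nt — the simplest defensible
convention, since no specific predictor is mandated; both the minimum
length and (off by default) alternative start codons are configurable.
Region boundaries: the start codon's first base is CDS, the position just
past the stop codon is 3'UTR. Codon effects substitute the alt base at the
in-codon offset and translate with the standard genetic code. The context
matrix tallies the ±5 nt window on the consensus (DNA-corrected) sequence;
windows truncated by transcript ends are skipped only for the missing
columns.

## Secondary structure

The built-in folding engine is a base-pair-maximization dynamic program
(Watson–Crick + G·U wobble, hairpin loops ≥ 3 nt, deterministic traceback
preferring a pair for the right endpoint with the smallest partner index).
It exists so the pairing/stretch logic — the actual analysis step — is
exercisable with no external binary; it systematically *over-pairs*
relative to a thermodynamic minimum-free-energy folder, so pairing and
stretch fractions derived from it are upper-bound-flavored. For faithful
thermodynamic structures, fold externally (e.g. RNAfold) and supply the
dot-bracket file via `load_external_structure`; all downstream annotation
is engine-agnostic, and an integration test verifies identical handling of
RNAfold-produced structures.

A site's dsRNA stretch is the longest sequence interval containing it
whose endpoint positions are paired and in which ≥ 80 % of positions are
paired (bulges up to 20 % allowed; endpoints must be paired so stretches
cannot dangle into loops). The stretch is measured on the single strand
containing the site, with the search confined to ±500 nt
(`stretch_window`) for tractability; `window_cap` optionally folds only a
window around each site instead of the whole transcript. "Long" means
strictly more than 3 nt. The 80 %-interval interpretation and the
single-strand length are documented choices; the alternative (counting
both duplex strands) would roughly double reported lengths.

## Pipeline conventions

The run directory is fixed (not timestamped): a timestamped path would
break byte-identical re-runs, which the pipeline guarantees under a fixed
config and seed. The manifest records the tool version, the full config
and a hash of its analysis-relevant fields (output location and log level
excluded); every written table carries that hash in a `#` header. The
pipeline is single-threaded; `--threads` is accepted for interface
stability. Stages re-derive cheap intermediates (pileups, consensus) from
the primary files rather than caching binaries, keeping every output
reproducible from SAM + FASTA + YAML inputs alone.

## Problem sizes

The test suite and the acceptance script run the reference design at 30
transcripts × ~1 kb × 13 samples × 30× coverage (≈ 120 k reads per
experiment), five seeds for the noisy regime, 1000 sequences for the
folding oracle, and 1000 repetitions for the read-level binomial
calibration check — sizes chosen so the full suite completes in a few
minutes on one core while leaving every statistical check adequately
powered.

## Known limitations

- Recall at 30× is power-limited for low-frequency sites (see above);
  this is a property of the thresholds and is quantified, not hidden.
- The identity definition, ORF predictor and folding engine are
  documented stand-ins for unspecified upstream tool behavior; their
  conventions are configurable but may not match any particular tool
  exactly.
- Indel-containing variation is not modeled: indel reads are handled in
  pileups (deleted bases contribute nothing) but indel variants as such
  are not called or masked beyond the frequency rule.
- Hyper-editing clusters, significance testing of editing differences,
  and tissue-level attribution are out of scope.
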