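# Methods

## Overlap model

Two reads are connected by an edge when they share an alignment of at
least `b` bases on either strand.  By default an *alignment* is a maximal
exact common substring (`max_mismatches = 0`); `N` bases never match
anything, including other `N`s.  This choice keeps the detector provably
complete: a shared substring of length ≥ b contains a shared b-mer, so a
canonical b-mer index (each k-mer keyed by the lexicographic minimum of
itself and its reverse complement) yields a complete candidate-pair set,
and each candidate's maximal shared length is recovered exactly from the
longest run of consecutive shared b-mers along a diagonal (a shared
substring of length L contributes exactly L − b + 1 consecutive hits).
The brute-force oracle used in the tests computes the same quantity by an
independent route — a vectorized longest-common-substring dynamic
programme over all read pairs — and the two must agree edge-for-edge,
including lengths and strand flags.

One edge is kept per read pair (the maximal alignment, with strand ties
resolved to "same"), because the degree statistic counts distinct
partners.  A mismatch-tolerant mode exists (exact seeds of length
⌈b/(m+1)⌉, complete by pigeonhole, verified by an ungapped all-offset
scan whose windows must start and end on a match) but is not the default:
with a substitution-only read simulator it mainly complicates the
equivalence argument.

## Bin extraction and the MAD filter

Candidate bins are connected components.  Within a component the degree
histogram is computed first (it is reported per bin and its counts always
sum to bin size + removed outliers); then the robust rule removes reads
with |d − median| > cutoff · σ̂, where σ̂ = 1.4826 · MAD and the default
cutoff is 3.  The factor 1.4826 ≈ 1/Φ⁻¹(3/4) makes σ̂ a consistent
estimator of a normal standard deviation, so the rule behaves like a
3-sigma cut on a clean bin (removing ≈ 0.27% of reads) while being immune
to the heavy upper tail it is meant to find.  Two deliberate choices:

* **Degenerate histograms.** If MAD = 0 (uniform degrees) nothing is
  removed and the bin is flagged `mad_degenerate`.  A flat histogram is
  what a clean single-molecule bin looks like; any removal rule at
  MAD = 0 would delete arbitrary reads.
* **Scaled vs raw.** The threshold uses cutoff · σ̂ (3 · 1.4826 · MAD)
  because σ̂ is introduced as the standard-deviation estimator
  immediately before the rule; a raw-MAD threshold (cutoff · MAD) is
  available behind `scale_to_sigma=False`.

After removal, connectivity is recomputed; every remaining sub-component
with at least `min_bin_size` reads is reported as a bin, everything else
(outliers, small fragments, isolated reads) goes to the leftover pool.
When a component splits into several reported bins, its outliers are
attributed to the largest resulting bin (tie: smallest member id) so the
per-bin histogram invariant stays exact.  The rule is two-sided, which has
a consequence worth knowing: a read sitting over a local coverage trough
has an unusually *low* degree, and removing it can cut a thin component
in two.  On simulated communities this occasionally splits one genome
across two reported bins — purity is unaffected, but best-bin
completeness drops for that genome on such seeds.  We keep the two-sided
rule because the distance-from-median formulation is the defined
statistic; the split behavior is a property of the method, not a defect
of the implementation.

## Iterative schedule and blocks

The default schedule is b = 70, 50, 30.  Each pass detects overlaps over
the current pool only; reported bins are withdrawn; MAD-removed outliers
re-enter the pool for later, looser passes.  Lowering b increases
sensitivity but also the chance of joining reads from different
molecules, which is why the strict pass runs first and why each bin
records the `b_used` that produced it.

`block_binning` splits the input into consecutive blocks (default block
size 20 million reads — at desk scale effectively "one block"), bins each
independently, and then merges bins from *different* blocks whenever some
cross-bin read pair overlaps by at least the smaller of the two bins'
b values (an edge either bin would have accepted).  Merged bins take the
smaller b, summed histograms and a recomputed spread.  With a single
block no merge pass runs, so the result is bit-identical to the plain
path.

## Paired-read preparation

For binning only, mates are collapsed into one fragment: an overlap merge
joins the suffix of the forward read to a prefix of the mate's reverse
complement (longest overlap ≥ `min_overlap` = 10 whose mismatch fraction
is ≤ `max_mismatch_rate` = 0.1; disagreements take the higher-quality
base, ties go to the forward read; merged qualities take the per-position
maximum).  Pairs that cannot be merged are force-joined as
`r1 + NNN + revcomp(r2)`; because `N` matches nothing, the three-base
spacer can never create a spurious alignment, yet both mates travel as
one graph node.  The spacer bases carry quality 0.  After binning,
`restore_original` maps every bin back to the original read ids, which is
what gets exported per bin for assembly.

## Ribosomal screening

The screen takes any 16S reference FASTA (NCBI-16S, SILVA, Rfam, … — the
choice is the user's).  Both reference strands are k-mer indexed
(`seed_k` = 21, N-free k-mers only).  A read is classified ribosomal when
a shared seed lies on an ungapped diagonal containing a window of
`min_aligned` = 50 bases with identity ≥ `min_identity` = 0.9.  The rule
is deterministic and strand-symmetric.  Defaults were chosen so that a
read must carry ≥ 50 bases of near-identical ribosomal sequence to be set
aside — long enough not to discard reads that merely brush the gene, and
shorter than the default binning b of 70 so screened-out reads cannot be
the ones holding a first-pass bin together.  Only separation is
performed; taxonomic classification of the ribosomal fraction is out of
scope (the fraction is written to its own FASTA for external tools), and
`partition_from_id_list` accepts an external mapper's output instead.

## Synthetic communities

The generator emulates what the binning stage actually sees: several
random genomes (i.i.d. uniform bases) with controlled relative
abundances, optionally one conserved segment written into every genome at
a random position (a stand-in for a shared ribosomal gene), and single or
paired reads with uniform start positions, both strands at probability
1/2, and per-base substitution errors.  `coverage` is the mean per-genome
fold coverage: the per-genome read count is
`n_genomes · abundance · genome_length · coverage / read_length` (pairs
count two reads, keeping the sequenced yield fixed).  Every read carries
its source genome and span in a truth table, so purity (fraction of a
bin's reads from its plurality genome) and completeness (fraction of a
genome's reads captured by its best bin) are computed exactly at read
level rather than estimated from marker genes.

What the generator does *not* emulate — indels and platform-specific
error profiles, GC bias, real genomic repeat structure, circular
replicons, strain-level variation — bounds what passing tests show:
they validate the graph construction, the robust filter, the screening
logic and the orchestration, not performance on real instrument data.
The substitution-only error model is deliberate: the default overlap
detector is exact-match, and indels would conflate error modeling with
aligner behavior.

## Pipeline and determinism

The workflow is a task DAG (trim → merge → [screen] → binning, then one
task per reported bin, then a report).  Configuration is a flat
`key = value` file; the minimum viable configuration is the input path,
the input format and the output directory, with everything else
defaulted; unknown keys are rejected with the list of valid keys.  Two
backends execute the graph — serial, and a local thread pool — under a
hard determinism contract: artifacts are byte-identical between backends
(no timestamps in outputs, all iteration orders fixed by sorted ids, the
run log sorted by task name).  Re-execution with `--resume` skips tasks
whose outputs are newer than their inputs and rehydrates their in-memory
products from the artifacts.  A failing task is recorded in the manifest
and its transitive dependents are marked `not_run`.  External assemblers
are not invoked; each bin task emits a ready-to-run command line, and a
tiny greedy overlap-consensus assembler is available (off by default) so
end-to-end tests can produce contigs without external tools.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `min_quality` / `min_length` | 30 / 60 bp | end-trim threshold and length floor |
| `min_overlap` / `max_mismatch_rate` | 10 bp / 0.1 | pair overlap-merge acceptance |
| `seed_k` / `min_identity` / `min_aligned` | 21 / 0.9 / 50 bp | ribosomal screen |
| `b_schedule` | 70, 50, 30 bp | minimum alignment length per pass |
| `max_mismatches` | 0 | overlap alignment mismatch budget |
| `min_bin_size` | 2000 reads | smallest reported bin (production default; examples and tests use 20–50 at desk scale) |
| `mad_cutoff` | 3 | outlier distance in σ̂ units |
| `block_size` | 2×10⁷ reads | reads per processing block |

## Problem sizes used in tests

The test and acceptance workloads are sized for a laptop-class budget:
communities of 2–3 genomes of 4–20 kb at 15–20× coverage (≈ 0.5–8 k
reads), 50 randomized oracle-equivalence instances of 20–60 reads, and
pipeline runs repeated under both backends.  These sizes keep every
stochastic property (purity, completeness, tail mass, oracle agreement)
measurable in seconds while exercising exactly the same code paths a
full-scale run would use.

## Known limitations

* Exact-match overlaps make the default pipeline sensitive to sequencing
  errors; at realistic error rates the mismatch-tolerant mode (or
  pre-correction) is required, at a cost in speed.
* The all-vs-all candidate stage is quadratic in local coverage depth;
  very deep, very uneven communities inflate candidate counts.
* The two-sided MAD rule can split thin components (see above).
* The screen's ungapped mapper will miss ribosomal reads with indels
  relative to the reference; use the id-list adapter with a full mapper
  when that matters.
* SFF input is rejected; convert to FASTA/FASTQ first.
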