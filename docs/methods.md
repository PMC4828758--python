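# Methods

This note documents the models, parameter choices and numerical conventions
behind the `smallrna` pipeline, and what the synthetic-data experiments do
and do not demonstrate.

## The synthetic library

`smallrna.simdata` generates the entire study deterministically from a
`SimConfig` (all randomness flows from `rng_seed` through three independent
child streams for genome, references and library, so `make_genome` and
`simulate_library` are individually reproducible).

**Genome and hairpins.** A uniform-random DNA genome (default 50,000 nt)
carries `n_mirna_genes` (default 20) planted precursors at non-overlapping
loci (≥ 40 nt spacing, random strand): mature arm + loop + star arm, where
the star is the reverse complement of the mature with substitutions at
`stem_mismatch_rate` (default 0.08/position) and the mature sits on a
random arm.  Mature lengths are drawn from 20–24 nt with 60 % of the mass
on the modal 22 nt, so the library's insert-length mode is the canonical
miRNA size.  Loops (8–15 nt) are drawn from {A, C} only — a pairing-inert
alphabet that keeps the designed stem the dominant fold.  Each draw is
additionally screened with the package's own folder: a candidate hairpin is
re-drawn until the exact precursor satisfies the discovery criteria
(single stem-loop, mature on one arm, ≥ 60 % mature pairing).  This is a
generator contract, not a test shortcut: ground-truth loci are required to
be genuine hairpins *under the model in use*, exactly as real miRNA genes
are genuine hairpins under thermodynamic folding.  Mature arms, their
8-nt flanks and the ncRNA references are screened against the first 6 nt
of the 3' adapter so exact-prefix trimming is lossless on planted inserts.

**Read mixture.** Each read is background (default 10 %; uniform-random
15–35 nt, exercising both sides of the length filter), an ncRNA fragment
(default 15 %; 18–30 nt windows of random rRNA/tRNA/snoRNA references), or
a miRNA read from a gene drawn with log-normal weights (μ = 2, σ = 1 —
heavy-tailed counts spanning roughly two orders of magnitude across 20
genes).  miRNA reads pass through the isomiR mixture below.  Inserts are
ligated to the TruSeq-style 3' adapter `TGGAATTCTCGGGTGCCAAGG`, padded
with random bases and truncated to 50 nt; the 5' adapter is modeled as
already removed.  Base qualities are Q30–40; sequencing errors (default
0.005/base) substitute a base and mark it with a low quality (Q2–15).

**IsomiR mixture** (`IsomirRates`, probabilities summing to 1; defaults
0.55 canonical / 0.25 trim3 / 0.04 each for trim5, templated 3' extension,
non-templated 3' addition, 5' shift, substitution).  Choices that matter:

- 3' trim lengths are geometric (p = 0.5) capped at 3 nt and at the
  18-nt length-filter floor.  The cap matches the conserved matcher's
  ±3 nt end-offset tolerance: every generated variant is assignable to its
  miRNA, and 1–3 nt trims are what dominates real isomiR data anyway.
- 5' variants move the 5' end by exactly ±1 nt.  Deeper 5' trims would
  delete canonical seed positions, making the variant unassignable by a
  seed-covering matcher (and biologically they are rare because the 5' end
  defines target specificity).
- Templated extensions copy genomic flank bases; non-templated additions
  append an A or U chosen to differ from the flank base, so the
  templated/non-templated distinction is decidable from sequence.
- Substitutions change one uniformly chosen position to a different base.

The truth table records, per read: source, isomiR class (canonical / iso5 /
iso3 / internal), the generative edit, signed end offsets, substituted
positions, the templated flag and the emitted insert.

**What the generator does not emulate:** quality-by-cycle decay, PCR
duplicates, ligation bias, multi-tissue expression structure, genuine
ncRNA secondary structure, sequence composition bias, and miRNA gene
families with near-identical matures.  Passing tests therefore show the
*algorithms* are correct and self-consistent at realistic scale — not that
their thresholds are well-calibrated for any real organism's library.

## Preprocessing

Quality rule: mean Phred ≥ 20 and no N (the classic pipelines only say
"low-quality reads"; this is a concrete, documented stand-in).  Adapter
trimming is leftmost exact-prefix search (≥ 6 nt of adapter, or the full
adapter); mismatch-tolerant trimming is deliberately not the default so
the stage stays an oracle-checkable string operation.  Length bounds 18
and 30 are inclusive.  Collapsing normalizes T→U and orders tags by
(count desc, sequence), making tag ids order-invariant.

## Annotation

Reference matching is ungapped containment with ≤ 1 substitution (ncRNA)
— exact and deterministic at toy scale, standing in for heuristic BLAST
matching.  Conserved-miRNA matching allows ≤ 2 substitutions and ±3 nt
end offsets but requires the overlap to cover reference seed positions
2–8; best hit by (mismatches, |5' offset|, reference order).  Genome
mapping reports *all* ungapped hits with ≤ 1 substitution on both strands
(vectorized sliding-window comparison; verified against exhaustive scan),
and is only consulted for tags that match no reference.  Precedence
conserved miRNA > rRNA > tRNA > snoRNA > other ncRNA reflects that
conserved-miRNA assignment is reported separately from structural-RNA
removal; it is configurable in spirit (the matcher parameters are keyword
arguments).

## Hairpin discovery

Clusters merge same-strand alignments within 10 nt; the anchor (putative
mature) is the highest-count tag.  Two windows are excised per cluster —
anchor as 5p arm (20 nt proximal / 150 nt distal flank) and anchor as 3p
arm — reverse-complemented for minus-strand clusters so the mature always
reads 5'→3'.

Folding is weighted Nussinov (G-C = 3, A-U = 2, G-U = 1, min loop 3,
deterministic traceback preferring pairing over bifurcation).  Two
numerical conventions make a max-pairing folder usable as a hairpin
judge:

1. **Precursor search.** A 170-nt window of mostly random flank folds, under
   a maximizing DP, into heavily branched structure; the evaluator
   therefore folds a grid of precursor-sized subwindows anchored at the
   mature read (extensions 20–52 nt in 4-nt steps, 3 nt proximal pad) and
   keeps the best-scoring one that passes the structural criteria — the
   same precursor-search idea MIREAP applies with a thermodynamic folder.
2. **Short-helix filtering.** Maximum-weight folds decorate loops with
   thermodynamically implausible 1–2-pair helices.  Topology criteria are
   judged after removing helices shorter than 3 stacked pairs (the
   counterpart of the no-lone-pair convention); the raw fold and score are
   reported unmodified.

Acceptance requires all four flags: *unbranched* (no internal multiloop
and exactly one hairpin loop — a single stem-loop), *mature on one arm*
(all partners of mature bases on one side, no mature base inside the
terminal loop), *pairing* (≥ 60 % of mature bases paired), and *support*
(≥ 2 distinct tags starting within ±3 nt of the mature or star 5' end;
the star is derived from the pair list with the canonical 2-nt 3'
overhang).  Only the ≥ 2-distinct-reads rule is inherited from practice
verbatim; 60 % and ±3 nt are package choices, exposed in
`HairpinThresholds`.

Because a hairpin's star arm is near-complementary to its mature, the same
reads align antisense at the same locus and produce a mirror candidate;
overlapping accepted precursors are collapsed to the better-supported one.
Candidates are named Novel-N by descending total support, with letter
suffixes (a = most supported) when identical matures arise from distinct
loci.

The negative control dinucleotide-shuffles windows (Altschul–Erickson
Eulerian-path shuffle, preserving dinucleotide counts and both terminal
bases) and re-evaluates them with the same support; on the default
library the acceptance rate is ~2–4 % against ≥ 90 % (empirically 100 %)
recovery of planted loci.

## IsomiR classification

Anchoring scans 5' offsets in ±5 nt (the 3' offset follows from the length
difference) and minimizes substitutions, ties to the smallest |5' offset|;
an alignment needing > 2 substitutions raises an assignment error.  Offsets
beyond ±5 would make assignment to a canonical miRNA dubious.  Classes:
iso5 / iso3 / internal for single-component edits, mixed when edits
co-occur at both ends or with substitutions (needed for a total
classification).  Extensions are templated iff the added bases equal the
genomic flank.  Substitutions are recorded in canonical coordinates with
an in-seed flag (positions 2–8).  Summaries are read-weighted (fractions
of reads, the convention in which isomiR percentages are usually quoted),
with tag-weighted fractions also emitted; per-miRNA distinct-isomiR counts
are split by arm when ids carry -5p/-3p suffixes.

On a noise-free library the classifier recovers the generative mixture
exactly (per-read labels 100 %, class fractions within sampling error).
With sequencing errors on, errors inside canonical reads surface as
internal/mixed calls — visible in the worked example — which is faithful
behavior, not misclassification: an error is indistinguishable from an
internal variant at the single-read level.

## Target scanning

Seed sites: WC-only complement of miRNA positions 2–7 (6mer), upgraded by
an m8 match and/or an A opposite position 1.  The duplex alignment is a
global affine Gotoh DP on complementarity (+5 WC, +2 G:U, −3 mismatch,
−8 open / −2 extend), with scores at seed positions 2–8 scaled ×4 in the
miRanda tradition — this is what makes the 140-score retention threshold
meaningful (a perfect 22-mer duplex scores ≈ 215, a bare 6mer far less).
Energies sum Turner-2004 WC nearest-neighbor stacks (embedded as data)
over consecutive pair columns; stacks involving G:U use a single
approximate −1.2 kcal/mol term; interruptions cost +4 kcal/mol and duplex
initiation +4.1.  This ranks toy duplexes sensibly but is not a partition
function; retained sites need score ≥ 140 and energy ≤ −14 kcal/mol.

## Reporting

Percentages are Decimal-exact, rounded half-up to 2 decimals; the
denominator for category percentages is the high-quality read total (the
convention under which the classic read-statistics tables are internally
consistent).  Length-distribution modes break ties toward the shorter
length.  The top-novel table ranks by most-expressed-sequence count,
descending by default with an ascending option.  qPCR fold changes use
$2^{-\Delta\Delta C_t}$ with each replicate's ΔCt referenced to the
calibrator tissue's mean ΔCt (calibrator defaults to brain); dispersion is
SE by default, switchable to SD.

## Numerical and degenerate-input conventions

- All tie-breaks are documented and deterministic (folding traceback,
  collapse ordering, hit sorting, naming).
- Empty inputs: empty FASTQ → empty tag set; no seed sites → no target
  sites; no pairs → duplex energy 0; `summarize_isomirs([])` raises.
- Genomes too small to hold all loci raise a sizing error before any
  output; truncated excision windows are flagged rather than dropped.
- Offsets/coordinates: 0-based half-open internally; GFF3 output 1-based
  inclusive; tag/alignment positions in error messages 1-based.

## Problem sizes

Tests and the acceptance script use 50,000-read libraries on a 50-kb
genome with 20 loci — large enough for tight binomial checks on mixture
recovery (n ≈ 37,000 miRNA reads) and for every planted locus to attract
several distinct tags, while the whole suite stays in the minutes range.
Oracle comparisons use 200 folding cases (≤ 14 nt, where enumeration is
exact), 1,000 mapping/containment cases, and 500 target-scanning pairs.

## Known limitations

- The Nussinov weight model has no entropy, dangles or coaxial stacking; a
  thermodynamic folder can be substituted via the `fold_fn` hook and the
  evaluation criteria reused unchanged.
- Multi-mapping tags are all retained and clustered everywhere they hit;
  there is no probabilistic read assignment.
- The conserved matcher is containment-based and cannot distinguish
  paralogs closer than its mismatch cap.
- The energy model's G:U stack term is a single constant; absolute
  energies are approximate, rankings are the intended use.
- qPCR summaries propagate no Ct-level error model beyond replicate
  spread.
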