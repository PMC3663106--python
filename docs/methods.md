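# Methods

## The model

`asmlik` scores a genome assembly by the probability that it would have
produced an observed set of paired-end reads.  Reads are modelled as
generated independently: for each pair a fragment length `l` is drawn from a
distribution `p_F`, a start site `s` uniformly over every position (on
every contig, either strand) where a length-`l` fragment fits, and the two
ends are read from the fragment's 5' ends on opposite strands through a
sequencing-error process `p_E`.  The per-pair probability is

    p(r) = sum_l p_F(l) * sum_s p_S(s | l) * 1/2 * sum_e p_E(r | a[s..s+l), e)

where the inner sum ranges over ways `e` of obtaining the read from the
assembly subsequence, and the total score is `sum_i log p(r_i)`.  Summing
over every site is intractable, so the sum is restricted to the placements
a report-all mapper finds with at most `max_edits` differences (default 5
per pair); placements with more differences contribute negligibly.  On
toy genomes the package's exhaustive enumerator makes this approximation
testable exactly: with an indel-free error model, the mapping-based value
equals the brute-force triple sum truncated at the same edit budget to
within floating-point error (`asmlik.oracle`).

The score is reference-free.  It rewards coverage (every read must be
explained), accuracy (mismatching placements pay substitution rates), and
parsimony of total length: `p_S(s|l) = 1 / valid_sites(l)` shrinks when
unsupported sequence is added, so inflating an assembly with junk strictly
lowers the likelihood.  A reference genome can be scored by the same
pipeline for comparison.

### Strand factor

A fragment may be sequenced from either strand; strand is modelled as a
fair coin, contributing an explicit factor 1/2 per placement.  The factor
is constant across assemblies with the same orientation structure, so
rankings are unaffected; it is kept explicit so that toy-scale sums
normalize exactly.

## Learned distributions

All parameters are learned from pairs with exactly one reported mapping.

**Fragment lengths.** `p_F` is the empirical distribution of observed
fragment lengths (outermost aligned base to outermost aligned base),
Laplace-smoothed with pseudocount α = 1 over the observed [min, max]
window.  Smoothing prevents zero-probability fragments at the window edges
without inventing mass outside the observed range; insert-size
distributions are shaped by library size selection and are deliberately
not fit parametrically.  `p_F` is renormalized once at learning time only.

**Error model.** For every machine cycle `j` (position within the read as
sequenced, not assembly position — ends aligned to the reverse strand are
flipped back into machine coordinates before counting) the model keeps a
substitution rate for each ordered (reference base, read base) pair, an
insertion-opening rate, a deletion-opening rate, and pmfs over indel
lengths.  Estimates are Laplace-smoothed counts:

    sub(j, b, b') = (n_sub + α) / (n_b-at-j + 4α)
    ins(j)        = (n_ins + α) / (coverage_j + 2α)      (del analogous)

with α = 1 by default; α > 0 is required, otherwise an unseen event would
zero out an entire mapping's probability.  Indel-length pmfs are smoothed
counts over lengths 1..max observed (minimum support {1}).  Base-quality
strings are ignored: rates come from the data.

At each read position exactly one event occurs — match, substitution,
insertion opening, or deletion opening — so the four event probabilities
sum to one at every (position, reference base).  A deletion is indexed by
the read position immediately following the deleted reference bases and
consumes that position's slot (the read base there copies the reference);
the event grammar is the minimal composition that makes `p_E` a proper
distribution over (read, edit list) pairs.  Deletion mass at cycle 0 is
unobservable (it would only shift the fragment start) and is folded into
match during simulation.  Columns in which the reference or read base is N
contribute a fixed uninformative factor 1/4, which keeps `p_E` defined
across scaffold gaps.  Two guards exist for pathological inputs: positions
with no observations fall back to pure pseudocount rates (with a warning),
and if smoothed event mass at a position would reach 1 it is rescaled to
0.95 (never triggered at realistic coverage).

## Rescue of unmapped reads

Mappers leave a fraction of pairs unplaced; assigning them probabilities
analytically (as if generated from anywhere) tends to make unmapped reads
look *more* probable than mapped ones, which is anomalous — the engine
emits a warning if that happens.  Instead, a random subsample (default
500, in line with sampling a few hundred to a thousand reads) of the
non-mapped pairs is aligned directly: an infix edit-distance scan (edlib)
shortlists one window per contig and strand, and exact affine-gap
Smith–Waterman (match 1, mismatch −1, gap open −2, gap extend −1; one
mismatch preferred over two gaps) scores the window.  If the two best end
alignments co-place compatibly and the implied fragment length is inside
the learned support, the pair is scored exactly like a single mapping;
otherwise each end contributes its `p_E` and the placement term is bounded
by the modal fragment probability.  Read positions outside the local
alignment, and alignments the learned model assigns zero probability
(e.g. indel lengths never observed in mapped data), fall back to the
uninformative 1/4-per-base floor.  The arithmetic mean of the sampled
pairs' log probabilities — a geometric-mean imputation, robust to a single
near-zero sample — is assigned to every non-sampled non-mapped pair.
Cross-scaffold pairs are routed through the same rescue path rather than
given a bespoke chimera model.  Everything is deterministic given (seed,
sample size); thread count affects wall time only.

## Conversion and routing

`convert` ingests report-all SAM (CIGAR M/=/X/I/D; the reference sequence
is taken from the assembly, so no MD tag is needed) and emits one mapping
record per proper co-placement: both ends on one contig, opposite strands,
forward-reverse orientation by default (reverse-forward available for
mate-pair libraries), total edits ≤ `max_edits`.  Fragment length is the
outermost-coordinate span, so indels in either end shift it.  Hard- or
soft-clipped alignments are treated as if that end were unmapped, since
clipping hides bases the model must explain.  Pairs whose ends map only to
different contigs — or only in improper configurations — are routed to the
cross-scaffold category.  The four categories partition the input pairs.
Scaffolds can be split into contigs at runs of ≥ 25 N before evaluation.
No mapping-quality filter is applied to the mapper's output.

## The simulator

The validation instrument draws fragment lengths from a rounded Gaussian
(default mean 200, sd 20) truncated to [read length, longest contig],
start sites uniformly over valid positions, strands fairly, and pushes
each end through the error-model event grammar (defaults: substitution
0.01 per cycle split evenly over the three alternatives; insertion and
deletion opening 5 × 10⁻⁴; indel lengths 1–3 with pmf 0.9/0.09/0.01).
These defaults emulate a 35 bp short-insert Illumina library.  The "true"
fragment distribution used for true-parameter likelihoods is the
discretized truncated Gaussian (mass of Normal(μ, σ) on [l−0.5, l+0.5],
renormalized over the truncation window; lengths beyond 8σ carry no
representable mass and are omitted).  Emitted FASTQ carries placeholder
qualities; a tab-separated truth log records every placement and injected
edit, and reads are exactly reconstructable from it.

What the simulator does *not* emulate: coverage and GC bias,
sequence-context-dependent errors, quality-score structure, chimeric
fragments, and adapter artifacts.  Passing tests therefore demonstrate
correctness of the inference machinery under the stated generative model,
not robustness to every artifact of real libraries.

## Built-in mappers

The package's contract is to consume external report-all SAM, but it
ships two mappers so that every experiment is self-contained: an
exhaustive enumerator (toy genomes; the oracle's placement source) and a
k-mer seed-and-extend mapper (k = 11, three spaced seeds per end, so any
placement with ≤ 2 edits is found by pigeonhole; candidates failing
gapless verification are re-aligned with a banded edit-distance search so
indel-containing reads are still placed, as indel-capable external
mappers would).  Ends with more than 3 edits may be missed and flow to
rescue, mirroring the behaviour of heuristic production mappers.

## Numerical choices

Natural logarithms throughout; per-pair sums use log-sum-exp; totals are
exact sums (`math.fsum`) where cheap.  Zero-probability mappings (fragment
length outside the learned support) are dropped from the per-pair sum
rather than floored — a pair losing all its mappings is re-routed through
rescue, so no probability mass is double-counted.  Smith–Waterman
tie-breaks are deterministic: smallest target start, then smallest read
start; traceback prefers diagonal moves.  Alignment candidate ties across
contigs resolve to the lowest contig index, "+" strand first.

## Scale of the shipped experiments

The validation experiments in the test suite and acceptance script run on
100 kb synthetic genomes with up to 50,000 pairs, 3,000-pair read sets for
the discrimination checks, and toy genomes (≤ 200 bp) for exact oracle
comparisons — sizes chosen so the full battery reruns from scratch in a
few minutes on one core while leaving every statistical margin (3σ bounds,
sub-0.5% agreement targets) intact.  At these sizes the true-parameter vs
learned-parameter disagreement is ≈ 0.08% at 50,000 pairs and shrinks with
depth, consistent with parameter-estimation noise decaying as n^(-1/2).

## Known limitations

* Multireads are handled by summing over reported placements; no
  expectation-maximization reassignment is attempted.
* The uniform start-site model ignores coverage bias; likelihood
  differences between assemblies therefore partly reflect bias the model
  cannot explain.
* Rescued pairs are scored by their single best co-placement, not a sum
  over alternatives, so rescue is slightly conservative by construction.
* The seeded mapper is a validation instrument, not a production mapper;
  real analyses should feed the converter output from an indel-capable
  report-all mapper.
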