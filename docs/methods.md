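# Methods

`cd5switch` asks a single scientific question at desk scale: when a chronic
lymphocytic leukemia (CLL) clone is split by surface CD5 level into a
CD5-high bulk and a CD5-low minority, are the two fractions the same clone
mixing freely between states (common/continuous switching), or does the
CD5-low fraction descend from one or a few switch events (rare switching)?
The package implements the full inference chain — amplicon read processing,
sequence-network clonality detection, single-cell clonotype matching, two
bespoke statistics, and lineage reconstruction — driven by a synthetic
repertoire generator with a known switching regime, so every stage is
testable without patient data.

## The synthetic repertoire

**Model.** A clone of `clone_cells` B cells descends from one central
ancestor BCR sequence of length `sequence_length` (default 300 nt). The
central sequence is a packaged *synthetic* V-like reference segment
(`data/vref_synthetic.fa`, randomly generated — not a germline gene)
extended by a random junction region, so clone sequences pass an
immunoglobulin-similarity screen while the polyclonal background (uniform
random sequences) does not. A fraction `central_fraction` (default 0.85) of
clone cells carry the unmutated central sequence, emulating the observed
dominance of the central BCR in CLL clones. The remaining cells form
variant *subclones*: groups of cells sharing one variant sequence.

**Lineage growth.** Subclones arise sequentially. Each new subclone attaches
to the central ancestor with probability `root_attachment` or to a
uniformly chosen existing subclone, and differs from its parent by exactly
one fresh substitution (position uniform among unmutated sites, base
uniform among the three alternatives; distinct subclones are kept sequence
distinct). Consequences that matter downstream:

- mutations nest along lineages, so a founder cell's descendant sub-lineage
  is sequence-coherent — the property rare-switch detection relies on;
- every variant is one substitution from its parent, so the whole clone is
  a single connected component under the Hamming-distance-1 edge rule and
  error-free runs recover it exactly;
- the variant's distance from the central sequence equals its subclone
  depth, with mean `1/root_attachment`. By default `root_attachment` is
  derived as `1/mean` from `distance_distribution = ("geometric", 1.5)`,
  giving star-like trees with mean variant distance ≈ 1.5 nt.

Subclone cell counts follow `abundance_distribution = ("geometric", 3.0)`.
Multi-cell subclones are essential: they are what allows one variant
sequence to be observed in both CD5 gates under common switching, which is
the signal the overlap test measures. These defaults are a deliberately
scaled-down analogue of a patient repertoire (10^3 cells rather than 10^5);
the qualitative regimes (dominant cluster ≫ 85% of reads, star-like
diversification) are preserved.

**Switching scenarios.** `A`: all cells CD5-high except the complete
descendant subtrees of `switch_rate` founder cells (an integer count,
default 1), which are low — a unidirectional switch fixed after the event.
`B`: the mirror image. `C`: every cell is low independently with
probability `switch_rate` (default 0.15), regardless of lineage. Default
founders for A/B are the variant cells whose descendant sub-lineages carry
the most distinct sequences: a rare *early* switch whose progeny expanded —
the only rare-switch history that would leave a detectable sorted CD5-low
population to study. An explicit `founder_cells` argument overrides this.

**Reads.** Each cell yields `reads_per_cell` read pairs from the template
`primer_fwd + BCR + primer_rev`; the mates share an identical overlap of
`overlap_length` bp by construction, then acquire independent substitution
errors at `error_rate` (default 10^-3/base, a typical post-filter MiSeq
rate). Qualities are Phred+33: normal pairs draw per-base scores uniform in
[30, 40] with median forced ≥ 33; a `low_quality_fraction` of pairs draws
[20, 32], guaranteeing failure of the median filter. Single-cell plates
model dropout (empty well), doublets (two distinct sequences, flagged
multiple-signal) and uniform sampling from the gated population.

**What the generator does not model:** V(D)J recombination and germline
gene choice, indels, PCR amplification bias and chimeras, quality-value
correlation along reads, biologically realistic background diversity.
Passing tests therefore demonstrate correctness of the *analysis* under a
substitution-only star-like clone, not robustness to indel-rich or
biased real libraries.

## Read processing

Stages run in a fixed order — quality, merge, Ig similarity, primer trim +
length — each conserving reads (input = retained + discarded, recorded in a
`FilterReport`). All thresholds are strict inequalities:

- **quality**: both mates need median base quality > 32. The median of an
  even-length vector is the lower middle value, making the strict
  comparison unambiguous on integers.
- **merge**: the longest suffix of the forward read equal to a prefix of
  the reverse-complemented reverse read; merged only if that identical
  overlap exceeds 65 bp. Identity, not consensus: one mismatch inside the
  overlap discards the pair.
- **Ig similarity**: best local alignment (match +1, mismatch −1, gap −2)
  against the packaged V-like segments must reach
  `IG_SIMILARITY_MIN_SCORE = 100`. Clone-derived amplicons share a ~250-bp
  reference-derived segment and score near 250; uniform random sequences
  score ~10–20 (the logarithmic Karlin–Altschul regime), so the constant
  sits far from both distributions. This screen replaces a
  BLAST-against-database E-value cutoff with a self-contained equivalent.
- **trim/length**: the forward primer must match near the 5' end and the
  reverse primer (in either orientation) near the 3' end, each within
  `max_primer_mismatch` substitutions (default 0); both are trimmed and the
  result is kept only if longer than 240 bp.

## Network and clone

Unique sequences are vertices (read counts kept per sample); edges join
equal-length sequences at Hamming distance exactly 1 (indels never create
edges); clusters are connected components. Edge construction uses
masked-position hashing (two sequences are Hamming-1 neighbours iff they
share a one-position-wildcarded key), O(n·L) versus the O(n²) definition it
is tested against. The clone is the cluster with the most reads (ties:
more vertices, then lexicographically smallest central sequence); its
central sequence is the member with the highest read count (ties:
lexicographic). Cluster size is reported both as read fraction (the
headline number) and vertex fraction.

## Single-cell matching

A single-cell sequence is *clonal-identical* if it equals any clone member,
*clonal-near* if it is equal-length and within 3 substitutions of the
central sequence; the headline clonal fraction uses the union over
single-signal wells only. Both criteria are reported separately because
they answer slightly different questions (membership of the sequenced bulk
versus proximity to the dominant clonotype). Unequal lengths are never
rescued by alignment, consistent with the non-indel network rule.

## Switching statistics

**Variant overlap.** For the clone's central sequence of length *l*, a
variant at Hamming distance *d* is one of C(l, d)·3^d possible mutants.
For each distance class d ≥ 1 present in either gate, with K_d and n_d
unique variants in the high and low gates and k_d shared, the per-class
p-value is the exact hypergeometric upper tail P(X ≥ k_d) over universe
N_d = C(l, d)·3^d, computed by big-integer tail summation (exact for
universes far beyond floating-point range; classes with k_d = 0 contribute
p = 1). The central sequence is excluded from both sets — the shared
ancestor is the given of the test. Classes are pooled with Fisher's method;
the per-class table is always reported so any alternative pooling can be
recomputed. The full combinatorial universe makes observed overlaps
astronomically unlikely under independent mutation — sharing even a handful
of variants drives the pooled p far below 10^-10, which is the signature of
a clone whose members move between CD5 states.

**Co-clustering ratio.** mean within-gate pairwise Hamming distance (high
pairs and low pairs pooled) divided by mean between-gate distance, over
unique sequences unweighted by abundance (tree-tip semantics). Pairs of the
*same* sequence string never count — a sequence observed in both gates is
one sequence, not a zero-distance pair — so identical gates give ratio
exactly 1. The null distribution permutes gate labels over the pooled
sequences preserving group sizes (n_boot = 1000 by default), subsampling
each pseudo-group to at most 200 sequences purely as a size cap (groups at
desk scale are kept whole, so the procedure is a plain permutation test).
One-sided, small ratio = distinct clusters; p = (1 + #{null ≤ observed}) /
(n_boot + 1), which cannot return 0. A rare founder switch confines the low
gate to one sequence-coherent sub-lineage, giving a small ratio and small
p; common switching mixes the gates and leaves p non-significant.

**Subclonal frequency regression.** Ordinary least squares of low-gate on
high-gate per-variant frequencies over variants observed in both gates
(≥ 3 required); private variants are listed, never imputed as zero. Under
common switching both gates sample the same subclonal structure and R²
approaches 1.

## Lineage

The clone lineage is the minimum spanning tree of the complete
Hamming-distance graph over unique clone sequences, rooted at the central
sequence — a parsimony approximation that attains the maximum-parsimony
length on star-like data (verified against a brute-force Fitch
small-parsimony oracle on ≤ 6 taxa in tests) and upper-bounds it in
general. Kruskal's algorithm with tie-break (weight, then lexicographic
endpoint order) makes the tree input-order invariant. Tips are classified
high-only / low-only / both from gate membership; the rare-switch
signature is all low-only tips lying in a single proper subtree. No
ancestral-state reconstruction is attempted: the inference argues from tip
interleaving alone. Trees contain unique sequences, not
abundance-duplicated tips.

## Numerical and design choices

- Strict thresholds (> 32, > 65, > 240, E-value-like screen) follow the
  processing conventions the pipeline reproduces; all are configurable.
- Per-distance-class hypergeometric tests with Fisher pooling: the class
  structure keeps the universe well-defined per d; reporting every class
  keeps the pooling auditable.
- The permutation (rather than resample-with-replacement) null matches the
  hypothesis actually tested — label exchangeability between gates.
- One run seed fans out to per-stage RNG sub-streams
  (`SeedSequence(seed, spawn_key=(stage, salt))`), so stages can be rerun
  independently and everything is bit-reproducible; FASTQ, reports and
  trees are byte-identical across reruns of the same config.
- Degenerate inputs raise informative errors rather than guessing: gates
  with < 2 unique sequences (no within-distance), empty networks, tips in
  neither gate, < 3 shared variants for the regression.
- Problem sizes in tests and the acceptance script (clones of 150–4000
  cells, 20-seed replication, 200–1000 permutations) were chosen as the
  smallest sizes at which the three switching regimes separate cleanly.

## Known limitations

- The MST lineage can misroute a tip when positional homoplasy creates
  distance ties across lineages; on star-like clones this is rare but not
  impossible.
- The overlap test's universe assumes every mutant is equally likely
  (no hotspots); real somatic hypermutation is biased, which would shrink
  the effective universe and weaken the p-value's extremity.
- The co-clustering test conditions on the observed unique-sequence sets;
  sequencing-error singletons inflate both gates' private variant counts
  and dilute (never inflate) the overlap signal.
- Scenario A/B power depends on the founder lineage's sequence diversity;
  with very small switched lineages the within-gate distance is undefined
  and the test correctly refuses to run.
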