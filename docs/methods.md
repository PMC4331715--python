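# Methods

## Overview

`ispasm` reconstructs full-length transcript isoforms from spliced
RNA-seq alignments of F samples jointly.  Rather than assembling each
sample separately and merging the results, it builds one weighted
*multiple-sample connectivity graph* (MSCG) per gene locus from the
pooled evidence and repeatedly extracts the best source-to-sink path —
each path one isoform — by linear programming with an integer-program
fallback.  Paired-end fragments and an across-sample co-expression
test contribute rewards that steer the path towards read-consistent
isoforms.

## Segmentation

Alignments are clustered into loci by genomic footprint: two
alignments share a locus when the gap between their outermost
reference coordinates (introns included) is below `max_gap`
(default 200 bp).  Using footprints rather than covered bases lets a
spliced read hold a multi-exon gene together across uncovered introns.

Within a locus the boundary set is the union of every junction donor
and acceptor observed in any sample, plus annotated exon edges when an
annotation is supplied.  *Expressed segments* are the covered
intervals between consecutive boundaries; uncovered stretches are
dropped.  A junction whose coordinates match no known boundary creates
a new one — this is deliberate: shifted-alignment noise thereby enters
the graph, where downstream weighting and filtering must absorb it,
mirroring what happens with real mapper output.  Each alignment is
reduced to its *segment vector*, the ordered list of segment indices
it touches; alignments whose splice sites do not coincide exactly with
segment edges (possible only when boundaries are restricted to
annotation) are dropped and counted.

## The connectivity graph and its weights

Vertices are the M segments plus a source s and sink t; an internal
edge (i, j), i < j, exists when at least one read from any sample
joins segments i and j consecutively.  All weights use natural logs;
only relative magnitudes matter.

* **Vertex reward.**  `w[i,i] = -log(d_i + 1)` with
  `d_i = Σ_k C_i^k / (l_i - L + 1)`, the read density of segment i
  pooled over samples (C_i^k reads of sample k touching the segment,
  l_i segment length, L read length).  Segments shorter than a read
  use the overlap window `l_i + L - 1` instead: the contained-read
  window does not exist for them, and normalizing a handful of stray
  reads by a clamped window of 1 would hand 1 bp junction-debris
  slivers absurdly large rewards.
* **Edge cost.**  `w[i,j] = -log((d_ij/Σ_h d_ih) · (d_ij/Σ_h d_hj))`
  with `d_ij = Σ_k C_ij^k/(L-1)`: the probability that this junction,
  among the competing junctions at both endpoints, belongs to an
  isoform.  Rare junctions next to heavily used ones are expensive.
  The competing sums run over internal edges only.
* **Terminal edges.**  `(s, i)` is inactivated (set to a large finite
  sentinel, 1e9) when segment i can be reached from another segment,
  and `(i, t)` when i has an outgoing internal edge: isoforms may not
  begin or end in the middle of observed splicing.  The sentinel keeps
  the LP bounded; an optimal path crossing a sentinel edge means no
  admissible path remains.

**Junction consensus filter.**  Two spliced junctions whose donors and
acceptors each lie within 5 bp are competing versions of the same
splice event — alignment slippage shifts a site by a few bases, never
to a different exon.  Only the densest junction of such a positional
cluster is kept, and fragments aligned across a removed junction are
excluded from the reward pool as misalignments.  A genuinely
alternative junction (different donor or acceptor exon) is never in
any cluster and survives at any depth; the price is that sub-5 bp
alternative splice sites (NAGNAG-style) collapse onto their major
form.

Per-sample depth is assumed equal (the simulator guarantees it); for
real data the optional `depth_normalize` flag rescales each sample's
counts to the mean depth first.

## Paired-end rewards

A fragment p = (b, b′) implies an inclusion set IS_p (all segments
either mate touches) and an exclusion set ES_p (segments strictly
inside a mate's span that the mate skips); the gap between mates is
unconstrained.  A path P is compatible with p iff IS_p ⊆ P and
ES_p ∩ P = ∅.  Fragments with |IS_p| = 1 carry no information and are
dropped; identical (IS, ES) patterns collapse into one pattern whose
reward is `alpha_real` times the multiplicity.  Single-end reads
spanning two or more segments participate identically.

## Jensen-Shannon co-expression test

Alternative ("uncertain") segments — those some edge can skip, where
neither lies inside the other's minimal flanking edge — may combine
into several isoform sets the edges cannot distinguish.  For each
uncertain pair the JS metric, the square root of the Jensen-Shannon
divergence between the two segments' across-sample expression
distributions, is compared against an empirical null built by
permuting every segment's per-sample densities across sample labels
(1000 permutations, one randomly chosen segment pair scored per
permutation).  Base-2 entropies keep the metric in [0, 1].

At FDR β% (default 5), a pair in the lowest β% of the null is
*co-expressed* and injects a pseudo fragment with IS = {i, j}; a pair
in the highest β% is *exclusively expressed* and injects IS = {i},
ES = {j} in both directions, so that either exclusive isoform earns
the reward.  Pseudo fragments carry reward `alpha_pseudo`
(default 2 = 2×`alpha_real`, as they encode locus-level rather than
single-molecule evidence).  β = 0, a single sample, or a degenerate
(zero-density) profile disables injection.  The permutation unit —
densities permuted per segment, pooled null across pairs — is one of
several defensible readings of a permutation background; it is fixed
here and seeded for reproducibility.  Uncertain pairs are capped at
50 per locus by descending minimum density.

## Path extraction

Indicators f(i,j) over vertices and edges and q_p per pattern maximize

    Σ_{(i,j)∈P} −w[i,j] f(i,j) + Σ_p α_p q_p

subject to unit flow out of s, in-flow = f(i,i) = out-flow at each
internal vertex, and q_p ≤ f(i,i) for i ∈ IS_p, q_p ≤ 1 − f(i,i) for
i ∈ ES_p.  Finding the optimum is NP-hard in general, so the [0, 1]
relaxation is solved first (HiGHS via `scipy.optimize.milp`); if any
variable is off {0, 1} by more than 1e-6 the binary program is solved
instead.  In practice almost all solves are integral LPs.  The
returned objective is recomputed from the reconstructed path and
asserted equal to the solver's.  Variable order is fixed (sorted
(i, j)), making a given backend reproducible.

## The iterative loop

Each iteration emits the current optimal path as an isoform (merging
genomically contiguous segments into exons), then makes the graph less
attractive along it: vertex rewards are multiplied by `gamma` and used
internal edges penalized by `delta`, and every pattern the isoform
explains is removed from the pool.  Both decay knobs default to the
most forgetful setting (`gamma = 0`, `delta = 0`): later isoforms must
justify themselves through still-unexplained patterns or unused
segments.  Two softer settings were tried and rejected: retaining a
fraction of consumed vertex rewards lets superset paths outscore
genuine alternatives, and penalizing shared edges pushes later
iterations onto rare spurious junctions that run parallel to a heavily
used true junction.  The loop stops when the best path's objective
falls below `theta_stop` (default 0 — no net reward left), when it
re-proposes an emitted path, or after `max_iter` (default 20) rounds.

### Emission guards

Maximizing leftover rewards is greedy and, after the dominant isoform
is removed, the remaining rewards of *different* isoforms' deviations
can add up along a single chimeric path.  Because the objective cannot
see molecule identity, three guards act at emission time; rejected
candidates are excluded by linear cuts (edge-pair bans or exact-path
no-good cuts) and the solve repeats:

* **Molecule co-occurrence (from the second isoform on).**  Novel
  transitions — consecutive path pairs absent from every emitted
  isoform — must be linked by sequenced molecules.  Novel transitions
  in different novel blocks (deviations reconnecting through emitted
  structure) must be pairwise witnessed by a single fragment whose
  mates cross both, at any distance.  Consecutive spliced junctions
  along the candidate with at least one novel member must be witnessed
  when they lie within `witness_span` (default 350 bp, a generous
  upper bound on fragment spans for standard short-insert libraries);
  more distant pairs are unknowable from short fragments and pass.  A
  true secondary isoform shares these junction pairs with its chimeric
  lookalike, so the same witness decides both consistently.
* **Exon density uniformity.**  Segments merged into one predicted
  exon must agree in density within a factor of 10
  (`min_exon_uniformity = 0.1`): a real exon is covered by the same
  molecules throughout, whereas read-through and nested intron-blob
  calls stitch a genuine exon to stray intronic coverage one to two
  orders of magnitude shallower.  Genuine intron retention expressed
  at a sizeable fraction of its flanks still passes.
* **Single-exon floor.**  Single-exon calls require pooled density of
  at least `min_single_exon_density` (default 2 contained-read windows
  per base): isolated intronic coverage islands are isolated vertices
  with small positive rewards that would otherwise surface as spurious
  single-exon transcripts once real isoforms are exhausted.

## Simulator

The generator plants loci of 1–4 isoforms: a full exon chain
(exons 100–300 bp, introns 150–400 bp) plus variants each skipping a
distinct internal exon — the cassette-exon structure that dominates
real alternative splicing and keeps all planted isoforms
distinguishable under the matching rule.  Isoform abundances are drawn
i.i.d. log-normal per sample (meanlog 1, sdlog 1; heavy-tailed like
real transcript abundances); `exclusive` and `coexpressed` modes
instead impose anti-correlated or identical abundances for the
co-expression scenarios.  Fragment starts are uniform along the
transcript, insert lengths normal (250 ± 25), and clean reads are
emitted as perfect spliced alignments, isolating the assembler from
mapper behaviour.  A chosen fraction of fragments is replaced by
noise: shifted-junction copies of real junction fragments (each splice
coordinate moved ±1–3 bp) or single-end reads placed uniformly inside
introns.  Replacement keeps totals fixed, so the noisy fraction equals
the configured error rate exactly in expectation.

What the simulator does not model: sequencing errors and mapper
behaviour (alignments are exact), positional/GC bias, unequal sample
depths, genuinely novel junction structures such as alternative
splice sites within a few bp, intron retention as a *true* isoform,
and isoforms with sample-specific transcription starts.  Passing the
synthetic suite therefore demonstrates correct handling of junction
and intronic noise under the stated geometry, not performance on any
particular real library.

## Evaluation

Two transcripts match when their exon chains are identical except for
the start of the first exon and the end of the last; single-exon
transcripts match on any overlap (the rule is vacuous for them; an
exact variant is available).  Matching is one-to-one and greedy in
genomic order with ties broken by exonic overlap, so duplicate
predictions cannot double-credit one reference.  With K matches among
N reference and M predicted transcripts, sensitivity = K/N and
precision = K/M.

## Problem sizes and determinism

The bundled acceptance checks run 50-locus ensembles (1–4 isoforms
per locus, 800 fragments per sample per locus, 10% noise) at F = 1, 4
and 6, and 200 random small graphs (M ≤ 8) against exhaustive path
enumeration.  All randomness flows through seeded NumPy generators —
per-locus substreams are derived from the global seed — so every
dataset, permutation background, and therefore every assembly is
bit-reproducible; the LP backend is deterministic for a fixed variable
order.

## Known limitations

* Precision is bought with conservatism: isoform structures whose
  defining junction combinations no fragment can witness (deviations
  farther apart than the insert size) are never emitted after the
  first isoform of a locus.  Single-end libraries carry much less
  linkage information and recover fewer secondary isoforms.
* Expression levels are not estimated; the output is structural, with
  per-call compatible-read support as a rough proxy.
* Strand is carried through but loci are not split by strand;
  overlapping antisense genes will be co-clustered.
* Sub-5 bp alternative donors/acceptors collapse onto the major form
  by the junction consensus filter.
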