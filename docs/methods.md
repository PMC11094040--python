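# Methods

## The classification model

Every analysis is anchored to a *reference piRNA annotation*: a set of
piRNA species, each with a transposon (TE) id, a strand relative to the
TE, the 1-based TE coordinate of its 5′ nucleotide, and its 23–32 nt
sequence. The central assumption is that a piRNA species is identified by
its 5′ end: reads of different lengths sharing a 5′ anchor are the same
species at different stages of 3′ maturation. Consequently

* per-species counting uses **5′-anchor matching** — a read counts toward
  a reference piRNA when its best alignment places its 5′ nucleotide at
  the annotated `(te, strand, pos)`, regardless of read length; and
* the **ping-pong partner** of a species is a coordinate, not a specific
  annotated sequence: for a plus-strand 5′ at `p` the partner 5′ is at
  `p + 9` on the minus strand (minus-strand: `p − 9` on plus), so the two
  10-nt 5′ prefixes occupy the same ten TE positions as reverse
  complements. Partner abundance pools all 23–32 nt reads at that
  coordinate; the partner need not be in the annotation.

PIWI calls compare RPM between the two IP libraries, each normalized by
its total reference-matched read count (so IP RPMs are compositional over
the reference set). A call is made only when one RPM strictly exceeds the
other *and* at least one library shows more than `low_count_threshold`
(default 1) raw reads; otherwise the species is undetermined. Applying the
low-count rule to the raw-count pair jointly (rather than per library)
reads "no more than 1 read" as a statement about the evidence available
for the comparison; the threshold is configurable.

The class of a reference piRNA is `partner→own`. Exclusion precedence is
rRNA-TE > undetermined > ambiguous; the precedence affects only how an
excluded piRNA is labelled, never the membership of the three classes.
BmAgo3→BmAgo3 configurations are excluded as ambiguous by default — a
BmAgo3-bound piRNA whose complementary partner is also BmAgo3-bound means
BmAgo3 is abundant on both strands at that locus, which the heterotypic /
homotypic-Siwi model does not interpret; `report_a_to_a=True` reports
them as a fourth class instead. Note one symmetry consequence: feeding
the IP libraries swapped turns every S call into an A call, so A→S and
S→A exchange exactly while homotypic S–S configurations become homotypic
A–A (the homotypic *category* is preserved, not the S→S label).

A geometric remark: for an annotation whose 23–32 nt body lies fully
inside its TE, the partner 5′ (9 nt into the body) is always in bounds;
the out-of-bounds partner branch exists for truncated or edge-case
annotations and reports the partner as absent (undetermined).

## Preprocessing

The read layout inverted here is
`[4-nt UMI][insert][4-nt UMI][3′-adapter core]…`. Stages run in pipeline
order: adapter trimming → exact-duplicate collapsing → UMI stripping →
23–32 nt gating. Collapsing happens *before* UMI removal, so "identical"
means identical including UMIs: equal inserts from distinct molecules
survive, PCR copies do not. The surviving count is therefore a molecule
count. Two molecules of the same species collapse spuriously only when
both 4-nt UMI pairs coincide (probability 4⁻⁸ ≈ 1.5 × 10⁻⁵ per pair);
at the depths used in the tests this produces no merges, but at ~10³
molecules per species birthday collisions become measurable (≈ 0.7 % of
molecules) — an intrinsic property of 8 nt of UMI, not of the
implementation.

Adapter search policy (the adapter trimmer named by small-RNA protocols
leaves these unstated, so they are package decisions): leftmost window,
ungapped, minimum 6-nt overlap at the read's 3′ end, allowed mismatches
⌊overlap × max_error_rate⌋ with max_error_rate 0.1; no indels. Reads with
no detectable adapter are discarded as adapter-dimer/garbage rather than
kept untrimmed, since the library design guarantees an adapter on real
inserts. An adapter at position 0 (empty insert) is likewise discarded at
this stage. The "longer than 12 nt" core gate is strict: a 12-nt core is
discarded, a 13-nt core kept. Quality strings are carried but never used.

The search is implemented with pigeonhole seeding (a full-length window
with ≤ a mismatches contains one of a+1 disjoint adapter fragments
exactly) and verified by Hamming comparison; the test suite checks it
against a brute-force sliding-window search.

## Mapping

End-to-end ungapped alignment under Hamming distance ≤ 1, both strands,
best stratum only (exact hits suppress 1-mismatch hits) — deliberately
minimal so that an exhaustive-scan oracle can verify it exactly. The
index stores every 6-mer position of the panel; any ≥ 13 nt query aligned
with ≤ 1 mismatch matches one of its two leading disjoint 6-mers exactly.
TE-level counting takes one placement per read (`best_single`, tie-break:
fewest mismatches, then te_id, then lowest start, then + before −);
per-piRNA anchor matching uses all best-stratum hits with 1/k fractional
assignment, which conserves totals without a heuristic primary-hit
choice. A `strict_anchor` switch additionally requires the 5′-anchor
nucleotide itself to match (default off: the single-mismatch budget may
fall anywhere).

Normalization denominators: `genome_mapped` (reads with any best-stratum
panel hit — the panel plus its decoy content stands in for a genome at
desk scale) for control/KD libraries; `reference_matched` for IP
libraries. The denominator mode is recorded and enforced downstream.

## Expression change and grouping

M = log₂((KD + c) / (ctrl + c)), A = ½(log₂(KD + c) + log₂(ctrl + c)) on
RPM with pseudocount c = 1 RPM (the conventional MA offset; configurable).
piRNAs from rRNA TEs are removed, then an optional `min_rpm` filter on
max(ctrl, KD) applies (default 0 — the selection of the plotted subset in
the original analyses is not fully specified, so the filter is exposed as
a knob). Grouping into increased/unchanged/decreased is by rank tertile
on M (ties broken lexicographically for determinism) with the
outer-extra remainder rule: n = 3k+1 puts the extra in "increased",
n = 3k+2 in both outer groups — the rule that yields 825/824/825 at
n = 2474. This rank-tertile reading is a reconstruction from the
near-equal published group sizes; fold-change thresholds that happen to
give near-equal groups cannot be distinguished from it at desk scale.

1U/10A classification is a character test at 1-based positions 1 and 10
of the mature sequence (position 10 pairs with position 1 of the partner
across the 10-nt overlap); the four classes are exhaustive and disjoint
for any sequence of length ≥ 10.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:
random-sequence TEs (8 × 800 nt plus one rRNA-flagged TE by default)
carrying planted pairs with exact 10-nt 5′ overlaps; Siwi on the
antisense strand and BmAgo3 on the sense strand (Siwi on both for
homotypic pairs); 30 pairs per class; 6 annotated rRNA-TE piRNAs; 10 % of
pairs forced to low IP counts (planted undetermined); log-normal base
abundances (σ = 0.75); 8-fold IP enrichment of the cognate PIWI
(cognate-only in the `inf` limit); knockdown folds 0.3 / 0.7 / 2.5 for
A→S / S→A / S→S (the published analyses report directions, not
magnitudes — these folds are generator choices with the right signs and
comfortably resolvable sizes); depth 2 × 10⁵ molecules per library;
negative-binomial counts (dispersion 0.05; Poisson switch); geometric PCR
duplication (mean 1.5) applied *before* substitution errors (rate 10⁻³)
so duplicates can disagree at error sites; 4-nt UMIs drawn uniformly.

Because the 10-nt prefixes of a pair are complementary, the S-side 1U and
the A-side 10A are the *same TE base*: heterotypic pairs draw that shared
base once (probability max(bias_1U, bias_10A), both 0.9 by default, so
the coupling is invisible at defaults), and homotypic S–S pairs draw both
shared bases with bias_1U — which is why S–S pairs come out 1U10A, the
hallmark of homotypic amplification. An `n_offsize` handful of 20 / 35 nt
background species exercises the length gate.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: ligation sequence bias, quality
profiles, indels, genomic multi-mapping beyond the panel (TE sequences
are i.i.d. random, so 23-mers are effectively unique), 3′-maturation
length heterogeneity within a species (each species has one length),
phased/trailing piRNA production, and annotation error in the reference
set. Recovery of 100 % at defaults reflects the planted 8-fold IP
enrichment and clean anchors; real IP libraries have cross-contamination
and shared anchors that this model idealizes.

## Problem sizes and numerics

The default synthetic study (4 libraries × 2 × 10⁵ molecules, ≈ 1.2 M
reads after duplication) runs the full FASTQ-to-classification path in
under half a minute on one CPU; the test suite and the acceptance script
both use it directly, plus a 5 × 10⁴-depth noiseless run and small
fixtures. Determinism: all randomness flows from `numpy.random.default_rng`
seeded from a single seed (the generator uses seed, seed+1, seed+2 for
panel, counts, reads); collapse output is sorted lexicographically;
tie-breaks are total orders; reruns produce byte-identical tables.
Degenerate inputs are errors, not silent defaults: empty panels or
libraries, zero denominators, mismatched annotation sequences, lo > hi
length gates, and non-reference-matched IP inputs to the PIWI assignment
all raise.

## Known limitations

* The aligner is deliberately O(candidates) per read with a 6-mer seed
  table — fine for TE panels (≤ a few Mb), not for genomes.
* `genome_mapped` normalization uses the panel as the genome stand-in;
  with a real genome the denominator should come from a genome mapper.
* The ambiguity exclusion (A–A configurations) and the joint low-count
  rule are reconstructions of under-specified published bookkeeping;
  both are switches (`report_a_to_a`, `low_count_threshold`).
* Fractional 1/k multi-anchor assignment is one defensible weighting;
  unique-only or rescue-style weightings are not implemented.
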