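# Methods

## The model

An open reading frame (ORF) of `k` codons (start and terminal stop
included; `3k` nucleotides) requires an ATG at its beginning, a stop codon
at its end, and no stop codon in between.  Treating codon positions as
independent draws from a composition measure, the stationary probability
that a locus is an ORF is

    P_ORF(k) = P_ATG · P_stop · (1 − P_stop)^(k−2).

An ORF antisense to an annotated coding ORF overlaps it in one of three
reading frames.  With `s` the start coordinate of any sense codon and `x`
the leftmost plus-strand position paired with the antisense codon, the
frame is `d = (s − x) mod 3`: frame 0 is exact antiparallel codon overlap;
frames 1 and 2 shift the antisense codon one or two nucleotides toward
the sense 5' end, so each antisense codon is determined by two
consecutive sense codons (a dicodon).

Because the sense ORF interior is stop-free, the dicodons available to an
antisense codon are constrained.  Exhaustive enumeration over all 4096
6-mers shows that 192 dicodons (3·4³) overlap an antisense stop codon in
each shifted frame; in frame 1 (window = dicodon positions 3–5, 1-based)
64 of them contain a sense stop, leaving 128, while in frame 2 (positions
2–4) all 192 survive.  Frame 1 is therefore the only frame whose stop
probability is reduced by the overlap; frames 0 and 2 behave exactly like
intergenic DNA of the same composition.

### Composition measures and the normalization convention

Two composition models supply all codon/dicodon/trimer probabilities:

* **GC model** — independent sites with `p(G)=p(C)=g/2`,
  `p(A)=p(T)=(1−g)/2`.  Frame-specific stop probabilities are the
  **unnormalized** product-measure mass of the allowed stop trimers or
  dicodons, *not* renormalized by the probability that the sense reading
  is stop-free.  This convention is forced by the requirement that frames
  0 and 2 equal intergenic DNA exactly (renormalizing by `(1−P_stop)²`
  would break the equality) and it reproduces the existence crossover
  lengths below.
* **Oligomer model** — empirical tables: sliding-window trimers from
  intergenic DNA, non-overlapping codons (every third position) and
  dicodons (every sixth position) from annotated ORFs with the terminal
  stop excluded.  Codon and dicodon tables are stop-free by construction,
  so the empirical mode is intrinsically conditioned on the sense
  constraint; the two modes intentionally differ.

With the GC model, the smallest `k` at which the frame-1 existence
probability exceeds the intergenic one is 17, 21, 27 and 39 codons at GC
contents 30, 40, 50 and 60% (`crossover_length`, smallest integer with
ratio > 1).  Over the whole grid `k = 10..300`, GC 30–60%, the frame-1
probability never drops below ~74.6% of the intergenic value
(`scripts/acceptance.py` recomputes both).

The start-codon probability is deliberately frame-independent (codon-table
ATG frequency; product measure under the GC model), ignoring the effect
of the overlap.  The exact antisense start probability can be computed by
summing the dicodon measure over 6-mers whose frame window reads CAT; at
40% GC it is +6.7% (frame 1) and −15.7% (frame 2) relative to the
approximation, and exact in frame 0 (the test suite computes these).
This matters for expected-count comparisons (below).

## Mutation model and selection

Substitutions occur independently per site at rate `u = 1.7e-10` per
nucleotide per generation (budding-yeast estimate), weighted by six
strand-symmetric base-pair substitution classes
(A:T→T:A 0.063, A:T→G:C 0.144, A:T→C:G 0.110, G:C→A:T 0.349,
G:C→T:A 0.182, G:C→C:G 0.152).  The rate of a specific change is
`m(a→b) = u · bias[class(a→b)]` with no per-source renormalization; all
headline quantities are ratios of O(u) expressions and are invariant to
the overall scale (verified by a linearity test).

Purifying selection on the sense gene limits which sense codon changes
are available to the antisense reading:

* `none` — any sense mutation except a nonsense mutation;
* `weak` — synonymous changes, or substitutions between chemically
  similar amino acids (symmetric similarity sets derived from
  MHC-peptide-binding covariance; C, G, N, Q have no partners);
* `strong` — synonymous changes only.

Per-feature event probabilities are computed by exhaustive enumeration of
the codon (intergenic, frame 0) or dicodon (frames 1, 2) state space and
single-nucleotide neighborhoods.  Gain sums over source states that lack
the frame's stop reading and contain no sense stop (sense interiors are
stop-free), weighting tolerated mutations into the allowed stop set; loss
is conditional on membership of the stop set.  Start-codon events are
computed on the plain 3-mer measure with no selection filter, consistent
with the frame-independent start probability.  One mutation per event;
multi-hit paths are ignored.

ORF-level transitions for a `k`-codon locus:

    P_gain(k) = P_ATG-gain · P_stop-stay · B^(k−2)
              + P_ATG-stay · P_stop-gain · B^(k−2)
              + P_ATG-stay · P_stop-stay · P_stop · P_stop-loss · (k−2) · B^(k−3)

    P_loss(k) = P_ATG-loss + P_stop-loss + (k−2) · P_stop-gain / (1 − P_stop)

with `B = 1 − P_stop − P_stop-gain` and `stay = exists · (1 − loss)`.

**Third-term switch.**  The third gain path (one internal stop lost) is
sometimes written without the `P_stop` existence factor.  Both readings
are available through `orf_gain_probability(..., internal_stop_term=
"joint"|"literal")`; the default is `"joint"`, which is the consistent
first-order term — the probability that an internal position *has* a stop
and loses it — and the one the forward-mutation simulation validates.
Under the literal reading the gain crossovers below move to 22/39 codons,
far from the values the joint reading reproduces.

**Crossover readout.**  The gain curves of two frame contexts cross
between integer lengths; `gain_crossover_length` locates the zero of the
interpolated log-ratio and reports its integer part (lengths strictly
greater favor the antisense frame).  With this readout the frame-1 versus
intergenic gain crossovers are 26 codons (40% GC, no selection) and 46
codons (60% GC, no selection).  The stationary `crossover_length` keeps
the plain smallest-`k`-with-exceedance convention, which is the one that
yields 17/21/27/39; the two readouts are deliberate, per-quantity
conventions.

**Strong-selection threshold.**  At 60% GC the frame-1 gain crossover is
124 codons under the synonymous-only (`strong`) filter and 108 codons
under the similarity-tolerant (`weak`) filter — computed by
`gain_crossover_length`, and frozen in the test suite.  The package
implements the filters exactly as defined above; users comparing against
externally reported strong-selection thresholds near 108 should note that
such values coincide with the similarity-tolerant filter here, while the
synonymous-only filter is markedly stricter.  Selection ordering is
monotone throughout: gain(strong) ≤ gain(weak) ≤ gain(none).

## Expected counts over annotated regions

For an antisense-overlap region of `l_A` nt, the number of loci where a
`k`-codon ORF could sit in one frame is `(l_A − 3k + 1)/3` (kept as a
real number, no flooring); an intergenic region admits every offset,
`l_I − 3k + 1`.  Expected ORF numbers sum `P_ORF(f, k) · nLoci` over
regions and `k ≥ 10` with `3k < l` (strict).  Composition can be supplied
globally (one oligomer table set) or per locus (a GC model from each
region's own sequence); the report table carries total loci, expected and
observed counts (with and without sub-ORFs) and their frequencies.  The
model treats the three frames as independent and does not correct for
mutual exclusivity of overlapping ORFs.

## Genome scanning

Coordinates are 0-based half-open internally; GFF3 is converted at the
boundary.  ORFs are extracted per transcript reading frame as the longest
stretch from the most 5' in-frame ATG to each stop (one record per stop);
the minimum length of 30 nt *includes* the terminal stop, so 30 nt = 10
codons, matching the `k ≥ 10` bound of the expected counts.  Sub-ORFs —
shorter ORFs sharing the stop but starting at internal in-frame ATGs —
are added on request; expected counts correspond to observed counts
*including* sub-ORFs, since the model counts every (start, stop) locus.
An asORF is assigned a frame only when it overlaps exactly one
opposite-strand CDS at or above the overlap-fraction threshold (default
1.0, "wholly contained"; 0.5 reproduces the relaxed variant); records
overlapping several CDSs are reported separately and excluded from frame
counts.

## Synthetic data and the Monte-Carlo oracle

`generate_genome` emulates the pipeline's empirical inputs: a contig
alternating intergenic background (i.i.d. bases at the requested GC,
default 0.38, a budding-yeast-like value) with stop-free CDSs
(codon-conditioned draws, default 20 CDSs of 100–400 codons) on random
strands; antisense transcripts spanning a fraction of the CDSs (default
0.5); optional asORFs planted at requested frames, with an antisense stop
codon placed immediately 5' of the planted ATG so the scan recovers the
exact planted boundaries.  Output is deterministic given the seed, and
the generator does not emulate introns, UTRs, Kozak context, codon-usage
bias beyond the GC model, or locus-to-locus composition variation —
passing tests therefore demonstrate implementation correctness, not
fidelity to any real genome.

Two consistency experiments validate the analytics:

* **One-generation transitions.**  Loci are drawn from the stationary
  measure (i.i.d. bases for intergenic; stop-free sense codon chains read
  antisense for frame 1, with ORF loci sampled by exact conditioning plus
  rejection), mutated for one generation at an inflated rate, and the
  empirical gain/loss frequencies are compared with the analytic values
  within three binomial standard deviations.  The inflation keeps the
  per-codon double-hit probability below 1e-3 (per-site mutation
  probability 0.01 for gain, 0.003 for loss), preserving the
  single-mutation regime; sample sizes are 1e6 loci (gain) and 1e5 (loss)
  at 40% GC and k = 10.  For frame 1 the reference uses the exact
  conditioned oligomer tables the generator implies, which is the measure
  the simulated loci actually follow.
* **Expected versus observed counts.**  200 unplanted replicates (one
  50–110-codon CDS with a spanning antisense transcript plus flanking
  intergenic stretches, 40% GC) are scanned with sub-ORFs; per-frame
  totals are compared with the expected-count sums within three standard
  deviations estimated across replicates.  At this problem size the
  sampling band (~±20%) bounds implementation error while remaining wider
  than the model's own start-codon approximation error per frame (the
  +6.7%/−15.7% figures above); a much larger experiment would resolve
  that approximation as a systematic deviation in frame 2 — a property of
  the model, documented here deliberately.

## Numerical and degenerate-input choices

* Frequency tables must sum to 1 within 1e-9; stop-containing codon or
  dicodon keys must carry zero mass.
* Trimer counting does not cross record boundaries; windows or codons
  containing ambiguity codes are skipped (logged), never fatal unless no
  countable unit remains.
* Fisher tests round the (possibly fractional) per-frame loci counts to
  integers; one-tailed directions are explicit in every result object.
* "FDR" is Benjamini–Hochberg step-up throughout.
* Empty region sets yield zero expected counts with a warning; zero-mass
  stop sets yield zero loss.
* The crossover scanners return None when no crossing occurs in range
  (e.g. frame 2 under the GC model, where the ratio is identically 1).

## Known limitations

* Adjacent antisense codons share sense codons; the analytics treat
  internal positions as independent, and the pair-level correlations this
  ignores are at the few-percent level in the synthetic benchmark.
* The frame-independent start probability is exact for frame 0 but biased
  for frames 1 and 2 (figures above).
* Indels, multi-nucleotide mutation events, rate variation along the
  genome, and spliced (multi-exon) antisense overlaps are out of scope;
  asORFs spanning several sense genes are reported but not frame-counted.
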