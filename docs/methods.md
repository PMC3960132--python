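# Methods

`middenid` reimplements, as a tested pipeline, a multi-evidence
species-identification workflow for subfossil ungulate dung preserved in
arid-land cave deposits: who left the pellets, and when.  Five largely
independent components contribute evidence; each is described below with
its model, parameters, numerical choices, and the limits of what the
synthetic tests demonstrate.

## Pellet morphometrics

Dung producers are discriminated with fixed published rules, not a
fitted classifier.  For a pellet with long axis *L* (mm), short axis *W*
(mm) and optional weight *w* (g), the decision order is:

1. *w* > 0.5 g → `LARGE_UNGULATE` (wapiti, shrub-ox and other
   large-bodied taxa; weight dominates every shape rule);
2. *W/L* > 1.1 → `PRONGHORN_LIKE`;
3. 0.5 ≤ *W/L* ≤ 0.9 → `OVIS_LIKE` (the cuboid bighorn/domestic-sheep
   form);
4. otherwise `AMBIGUOUS`.

The ratio is implemented exactly as width∶length.  The published phrase
pairing "longer pellet" with a width∶length ratio *greater* than 1.1 is
geometrically odd (a longer pellet has a *smaller* width∶length ratio),
but the rule set is self-consistent with its own worked identification
(10.1/15.5 ≈ 0.65 falls in the Ovis interval), so the printed form is
kept.  Interval endpoints 0.5 and 0.9 are inclusive ("between 0.9 to
0.5" read as a closed interval); 1.1 is exclusive on the gap side.
Pellets in overlap zones are flagged (`WEIGHT_MISSING`,
`WEIGHT_OVERLAP_ZONE` for 0.3 g < *w* ≤ 0.5 g, `RATIO_GAP_ZONE` for
0.9 < *W/L* ≤ 1.1) rather than reclassified.  Mountain-goat pellets are
described only as "distinctly smaller" than Ovis with no numeric cutoff,
so no small-taxon class is emitted; the overlap surfaces through flags
only.  A sample's modal class is the most frequent decisive label, with
ties reported as `AMBIGUOUS`.

## Replicate consensus calling

Ancient DNA is degraded, so each mitochondrial fragment is amplified in
several independent PCR replicates, sequenced in both directions.  The
module reverse-complements reverse reads, picks the longest read as an
alignment anchor (ties broken by replicate id), pairwise-aligns every
other read to it, and merges them into a site-by-replicate matrix.  The
unaligned overhang at a shorter read's ends is encoded `N` (no data);
interior absences are `-` and vote for a deletion.  Reads that fail to
align to the anchor with positive score are dropped with a warning as
possible contaminants.

Each column is resolved by majority among its non-`N` cells.  A unique
plurality winner is called (in practice a strict majority; the plurality
extension covers rare three-way splits).  Exact ties between bases yield
the IUPAC ambiguity code; ties between a base and a gap next to a run of
that base resolve to the gap — polymerase slippage lengthens homopolymer
runs more often than it shortens them, and a published replicate set
left a 3-vs-4 repeat conflict unresolved, so the shorter run is a
declared package decision, not a published rule.  Other gap ties give
`N`.  Columns with fewer than `min_coverage` (default 2) covering
replicates are called `N`; a fragment must ultimately rest on at least
three PCRs, but individual sites near fragment ends may be covered by
fewer reads.  Per-column support (agreeing/covering) is reported at
alignment length; the consensus base string drops deletion columns.

## Haplotype comparison

Fragments are compared against reference panels by global
Needleman–Wunsch alignment (match +1, mismatch −1, gap −2, linear;
traceback ties broken diagonal > up > left so results are bitwise
reproducible) followed by column-wise counting: substitutions between
determinate bases, one difference per gap column (an L-bp indel counts L
— the same column-wise convention the parsimony analysis uses), `N`
columns skipped, overlapping ambiguity pairs compared-but-equal, and
disjoint pairs involving an ambiguity code skipped as unresolvable.
Exact-match search restricts each comparison to the aligned extent of
the query, so a short ancient fragment matches any longer published
haplotype identical over the sequenced span — the situation in which two
published desert-bighorn haplotypes, distinguished only outside the
sequenced fragments, both match the ancient sequence.

One caveat of pairing a *global* aligner with span restriction: when the
query's terminal base can equally pair with a repeat of that base in the
reference flank, the tie-break may spread the end gap, inflating the
count by the stray base.  Reference panels whose flanks differ from the
fragment ends (the usual case) are unaffected.

## Parsimony with gaps as a fifth state

Alignments of a few dozen sites cannot support model-based likelihood
inference, and treating indels as missing data discards most of their
signal.  The engine therefore scores trees by Fitch parsimony over the
five-state alphabet {A, C, G, T, gap}: each matrix cell is a state set
(`-` → {gap}; `N` → {A,C,G,T}, because an unread base was still a base;
IUPAC codes → their base sets), and a column's cost is the number of
empty-intersection events in a post-order pass, summed over columns
(duplicate columns are collapsed with weights).  The count is invariant
to the rooting used for the pass.

Search: `n_starts` (default 1000, the published setting) random taxon
addition sequences from a seeded generator; stepwise insertion on the
edge minimizing tree length with ties broken by a deterministic edge
ordering; then branch swapping to a local optimum — SPR with
first-improvement and deterministic move ordering by default.  The
published analysis used PAUP* without stating its swap setting; SPR is
chosen as a reproducible middle ground (NNI is weak, TBR costlier), and
NNI remains available in config.  All local optima are pooled; the
co-optimal set is the distinct topologies (canonical split-set identity)
attaining the minimum, summarized by a strict majority-rule consensus
(splits in > 0.5 of the co-optimal trees, support fractions attached)
and optionally rooted on an outgroup's pendant edge.  A same-seed run is
bitwise reproducible.  An exhaustive enumerator (≤ 9 taxa) provides the
exact oracle used throughout the tests.

Note the heuristic's co-optimal set contains only topologies that are
local optima of some start; degenerate flat regions of tree space can in
principle hold additional co-optimal trees that no start terminates in.

## Radiocarbon calibration

A conventional age y ± σ is calibrated against a knot table
(cal BP, μ, σ_c) by evaluating, on a fixed calendar grid (default 1 yr)
over the curve's range,

    p(θ) ∝ exp(−(y − μ(θ))² / 2(σ² + σ_c(θ)²)) / √(σ² + σ_c(θ)²),

with μ and σ_c linearly interpolated.  Curve and measurement error
combine in quadrature; the 1/√ factor honors varying curve precision.
The posterior is normalized on the grid; reported summaries are the
median (midpoint-interpolated CDF, exact for symmetric posteriors and
stable under grid refinement), the mode, and highest-posterior-density
intervals at 68.2% and 95.4% built by descending-density accumulation,
which makes the 95.4% set automatically enclose the 68.2% set.  Because
a published "mean age" range is ambiguous among summaries, all of them
are emitted.  Mass outside the curve is truncated with a warning; a date
whose ±5σ window misses the curve entirely is an error.

## Synthetic data

The generator produces every input the pipeline consumes, with truth
records as test oracles.  Defaults are the study conditions:

* **Panel**: root sequence uniform over {A,C,G,T}, length 60; exactly 5
  substitutions per branch at distinct live sites (exact counts, not
  Poisson, so parsimony scores have controlled expectations); optional
  deletion events (Poisson rate per branch, geometric length), off by
  default.  Indels are realized as deletions so the true alignment is
  simply the root coordinate system with `-` at deleted sites.
* **Replicates**: 7 forward + 5 reverse (the published 12S replication),
  miscall 0.01/base, N dropout 0.02/base, homopolymer slippage 0.05/run
  (runs ≥ 3 lengthened or shortened by one).  End truncation is
  available (`trunc_max`) but defaults to 0; with truncation on, the
  consensus legitimately reports low-coverage `N` ends rather than the
  full haplotype.
* **Pellets**: per-class normals — Ovis 15.5 ± 2 × 10.1 ± 1.5 mm
  (means are the single published measurement; spreads are synthetic),
  weight 0.2 ± 0.05 g; pronghorn 10 ± 1.5 × 12.5 ± 2 mm (ratio centered
  1.25), weight 0.2 ± 0.05 g; large ungulate 20 ± 3 × 15 ± 2 mm, weight
  0.7 ± 0.1 g.  Draws land inside the class's defining region with
  probability 0.9; the remaining 0.1 are unconstrained, giving
  deliberate inter-class overlap, so per-class recall is expected near
  but not at 1.
* **Calibration**: analytically invertible linear curves (and an
  identity curve) plus normal measurement noise, so closed-form
  posteriors are available as oracles.

Sub-generators draw from independent seeded streams, so adding pellets
never perturbs the sequence simulation.  What the generator does *not*
emulate: cytosine deamination damage patterns, chimeric amplicons,
base-quality scores, realistic chromatograms, and IntCal-scale curve
wiggles.  Passing tests therefore demonstrate the correctness of the
algorithms under the stated noise model, not robustness to every
artifact of real ancient-DNA data.

## Problem sizes in the reported results

`scripts/acceptance.py` regenerates everything from scratch at: 1000
pellets per class; 50 replicate-set seeds; 50 random 6–7-taxon
30-column matrices for the heuristic-vs-exhaustive comparison (10
random-addition starts each, against full enumeration); 10 twelve-taxon
panels at 100 starts for topology recovery; 100 calibration simulations;
and 5 full end-to-end pipeline runs at 100 starts.  These sizes give
stable percentages from a few seconds of computation each; the
pipeline's own default remains 1000 starts.

## Known limitations

* The morphometric rules are fixed thresholds; no uncertainty or
  discriminant fitting is attempted (deliberately — the source rules are
  categorical).
* The progressive star alignment is adequate for near-identical
  replicate reads and short homologous fragments; it is not a general
  multiple-sequence aligner.
* Heuristic co-optimal counts can depend on swap strategy and tie
  ordering, as they do between implementations of any parsimony
  heuristic; the best score is the robust quantity.
* Calibration covers single independent dates; no multi-date phase
  modeling or reservoir correction.
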