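# Methods

`omsv` implements a desk-scale, fully synthetic analog of nick-label
optical genome mapping: simulated long molecules are assembled de novo
into consensus genome maps and large structural variants (SVs) are
called from the consensus-to-reference alignment geometry.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## The measurement model

A nicking endonuclease cuts one DNA strand at its recognition motif;
fluorescent labeling of the nicks turns each motif occurrence into a
landmark on the imaged molecule backbone.  A *map* is therefore an
ordered list of label positions in bp.  References can be built by
in-silico digestion of sequence (IUPAC motifs, both strands by default)
or, for sequence-free experiments, by homogeneous Poisson placement of
labels with a configurable mean spacing (default 6,000 bp, a realistic
density for the usual single-cutter enzymes on human DNA).

Molecules are windows of a haplotype observed under a parametric error
model:

| parameter | default | meaning |
|---|---|---|
| `sizing_sd0` | 400 bp | baseline SD of each inter-label interval |
| `sizing_sd_scale` | 20 | interval variance grows as `sd0^2 + 20 * L` |
| `label_miss_rate` | 0.10 | probability a true nick goes unlabeled |
| `false_label_rate` | 0.8 / 100 kb | spurious labels (Poisson) |
| `resolution_limit` | 1,500 bp | nearby labels fuse into one |
| `fragile_break_prob` | 0.5 | break at close opposite-strand nick pairs |
| `chimera_rate` | 0.01 | molecule is a join of two unrelated fragments |

Molecule lengths are log-normal with mean 500 kb (sigma of the log
0.40), truncated below at 200 kb.  The platform images
megabase-scale DNA, and the assembly problem changes qualitatively with
molecule length: at a mean of 500 kb a molecule carries ~80 labels and
every pairwise overlap decision is statistically comfortable, which is
what makes a desk-scale de novo assembly reliable.  Raw coverage is
drawn against the haploid genome size; *effective coverage* follows the
platform convention: total bases / genome size x molecule-to-reference
map rate.

## Alignment and its empirical P-value

One dynamic-programming kernel aligns any label map to any other
(molecule-molecule, molecule-consensus, consensus-reference), searching
both orientations.  A transition from matched pair (i',j') to (i,j)
scores

    match_bonus - (dq - dt)^2 / (2 (sd0^2 + scale * dt))
      - miss_penalty * m(j',j) - false_penalty * (i - i' - 1)

with free end gaps on both sides, at most `max_skip` (5) skipped labels
per side per transition, and a hard residual gate at |z| > 5 (a
transition with a larger sizing discrepancy is simply not available —
this is what forces a real SV junction to split the alignment rather
than be absorbed).  `m(j',j)` counts skipped target labels *excluding*
those within the optical resolution of a flanking matched label: such
labels are almost certainly fused into the query's observed label and
are not evidence of labeling failure.  Without this resolution
forgiveness, alignments systematically break wherever Poisson label
clumps fuse.  The skip penalties default to 2.3 per label, the
likelihood-consistent value (-ln of a 10% event rate); with weaker
penalties, spurious chains through unrelated maps have a branching
factor above one and the overlap graph fills with false edges.

Significance is empirical: interval-shuffled synthetic queries of
varying label counts are aligned to the reference, and a Gumbel tail is
fitted per query-size bucket; location is shifted by `scale * ln(T/T0)`
for targets of other sizes (extreme-value scaling of the number of
candidate placements).  The staged cutoffs quoted in configuration
(1e-11 for refinement and extension, 1e-15 for merging, 1e-12 for
consensus-to-reference alignment, 3e-3 for the indel outlier test) are
conventions of the original platform's internal score scale, which is
much steeper than this empirical tail.  A single calibration exponent
maps a configured cutoff onto the empirical scale as
`cutoff ** (1/pvalue_scale)` with `pvalue_scale = 2.0`, chosen by a
design calculation (a typical molecule's full-length alignment must
clear the strictest molecule-level cutoff with margin) and exposed in
configuration.  `alignment_pvalue` itself always returns the raw
empirical tail probability.

## Assembly

Overlap-Layout-Consensus with the staged schedule: all-vs-all pairwise
overlap graph; layout and initial consensus; refinement (best-match
molecules only, chimeric-join removal); five extension-and-merge rounds
with extend-and-split inside each round; final refinement with
haplotype conversion.  Design choices that proved load-bearing:

* **Edges.** An overlap edge requires the empirical P-value below the
  pairwise cutoff, at least 9 matched pairs, and at least 50 kb matched
  span on both molecules.
* **Junction molecules.** A molecule whose overlap matched-ranges all
  terminate at one interior position from one side and start there from
  the other spans an allele junction (heterozygous SV, chimeric join).
  Such molecules are set aside before layout — they would otherwise
  stitch incompatible frames together — and re-enter through
  refinement and the extend-and-split pools.
* **Layout by accretion.** Components are traversed in BFS order over a
  maximum-weight spanning tree, but placement comes from aligning each
  molecule to the *growing consensus* (pinned interpolation through its
  matched anchors), so offsets never accumulate drift.  The target is
  the confirmed two-molecule core plus provisional single-molecule
  clusters beyond the core ends, which lets the frontier advance
  without extrapolation scatter.  Acceptance needs either a decisive
  P-value or agreement with the spanning-tree position prior.
* **Consensus building.** Projected member labels are clustered at the
  point-scatter scale (half the resolution limit); member labels outside
  the matched range are dropped when they project into the map interior
  (they belong to another allele or a chimeric partner) and kept when
  they extend past the ends.  Projection uses windowed local offsets
  (averaged over 11 anchors) so positions are re-estimated from the
  molecules' own geometry instead of being pinned to the previous
  consensus.
* **Merging.** Map pairs merge below the merge cutoff only if the
  alignment is a proper dovetail or containment: unaligned overhangs on
  the same side of the matched region mean two alleles sharing a flank,
  and such pairs must never merge.
* **Splitting.** Coverage-cliff (mis-join) splitting runs only after
  refinement has re-admitted molecules the layout left out; earlier the
  dips are artifacts.  Maps are also split at internal label gaps above
  40 kb: no molecule can span a label-free gap, so the two sides are
  independently anchored frames glued at an arbitrary distance — glue
  that can land reference-consistently and silently hide a real
  deletion.  Extend-and-split pools molecules whose unaligned ends
  exceed 30 kb, but only when their break positions cluster at one
  locus (a real junction) and the molecule does not re-align end-to-end
  under a widened skip allowance (a broken chain, not an allele), and
  never when the break sits at a map end (extension material).
* **Assignment caching.** Between stages each molecule is realigned
  against a banded window of its previously assigned map; cache entries
  of pooled molecules are invalidated so newly created allele maps can
  claim them, and only full-length fits (at least 80% of labels
  matched) may skip the remaining map screens.
* **Pair pruning.** Before the all-vs-all comparison, molecules receive
  approximate placements on a guide map; pairs whose bounding boxes
  cannot overlap are skipped.  A pruned pair could never satisfy the
  edge criteria, so the overlap graph is unchanged and assembly itself
  remains reference-free; re-assemblies per extension round are capped
  at the eight largest pools.
* **Haplotype conversion.** Per map, molecules are clustered by the
  signed residual between their span and the consensus span between
  well-supported flanking labels; a locus with two clusters separated
  by more than 3x the within-cluster spread (and at least 4 kb, below
  the 50 kb internal-gap threshold, minor cluster at least 25%)
  converts the map into two haplotype maps, each rebuilt from its own
  molecules by a depth-1 re-assembly.

Assembly is deterministic given its inputs; all simulation randomness
is seeded, with per-molecule substreams independent of batch size.

## SV calling

Consensus maps align to the reference; a map that does not align
contiguously is split into segments by (a) change points in the
per-pair offset series (a step residual coinciding with a sustained
shift of the offset plateau — a chain of marginal residuals can
otherwise "bridge" a junction), (b) recursive realignment of unaligned
prefixes, suffixes, and internal stretches, (c) removal of
stepping-stone islands (pieces under 8 pairs) and offset excursions
(a segment contradicting two agreeing neighbors), and (d) boundary
repair: edge pairs are re-anchored to the segment's own offset plateau,
trimmed when they fit the neighboring segment's frame better (near an
inversion junction the mirrored coordinates satisfy both frames), and
greedily re-extended toward the junction under frame arbitration.

Classification follows the platform's rules: span discrepancies between
adjacent matched labels are insertions (gain) or deletions (loss) under
a two-sided normal outlier test at 3e-3 — computed over windows of one
to twelve adjacent matched pairs, because a bridged junction spreads its
discrepancy over several intervals while the cumulative span arithmetic
remains exact; adjacent opposite-orientation segments on one contig are
inversion breakpoints (paired into one event when they bracket a middle
segment); segments on different contigs are inter-chromosomal
translocations; same-contig segments more than 5 Mbp apart are
intra-chromosomal ones.  The outlier test deliberately uses the
single-molecule sizing variance rather than the consensus-averaged one:
conservative by roughly the square root of coverage, which keeps the
3e-3 threshold quiet on consensus jitter while any cohort-scale event
sits at more than ten sigma.

Junction sizes are the median over short-baseline anchor pairs (k-th
matched pair from each side, k = 1..6): assembled maps can carry ~1%
residual scale error, which a long baseline would transfer into the
size.  Indel sizes are then refined against the supporting molecules:
each junction-spanning molecule contributes the span between its
anchors nearest the junction minus the (unfused) reference span, with a
ladder of up to eight anchor pairs per side, a per-molecule
ladder-consistency filter, and the requirement that the two flank
placements use disjoint, correctly ordered parts of the molecule.  The
median of the size-consistent estimates replaces the consensus-level
value when at least five molecules agree — the molecule evidence is
immune to the map-scale artifacts (duplication-locus stretch,
mixed-haplotype dilution) that bias consensus spans.  Breakpoint-uncertainty intervals are bounded by the matched
reference labels flanking the event; the reported uncertainty is the
interval half-width around the midpoint estimate.  With exponential
6-kb spacing, the interval containing a breakpoint is length-biased
(Gamma(2)), giving single-enzyme half-width medians around 5 kb.  Calls
from two independent enzyme channels pair by type and 50% reciprocal
overlap; merged intervals are the per-side intersections, which is
where the second enzyme's resolution gain comes from.

An orientation flip carries both inversion breakpoints at once: the
inverted block's low end maps adjacent to the far flank, so the
junction-adjacent labels of the flip's two segments bound the left and
right breakpoints respectively, and any flip spanning under 200 kb is
an assembly-edge artifact and is dropped.  Because flip anchors can
only drift outward past a junction, duplicate inversion records keep
the smallest span, and disagreeing dual-channel intervals resolve to
the inward bound per side.

For gain calls the refinement first re-localizes the junction: inserted
material blocks any single alignment transition, so carrier molecules
break there, and the densest cluster of their outermost matched
reference labels pinpoints the junction far better than the
consensus-level intervals (which can be off by tens of kb near a
garbled duplication locus).

Zygosity uses ploidy metadata: ploidy 1 makes calls hemizygous; at
ploidy 2 a covering non-supporting map — or, for deletions, any
non-supporting map aligning across at least 70% of the deleted
interval's interior, which only the reference allele can do — marks the
call heterozygous.  Molecule evidence refines this further: a cluster
of junction-spanning molecules with no span change is the reference
allele (heterozygous); its absence with many size-consistent molecules
is homozygosity.  Without metadata the state is reported unknown.

## Detection floor and known limitations

* The smallest emitted indel defaults to 11 kb.  At the default error
  model, consensus maps occasionally carry internal offset seams of
  3–10 kb (merge boundaries, locally thin support) that would otherwise
  surface as small spurious calls; an event whose query region rides
  low-support consensus labels is likewise suppressed.  The smallest
  event in the validation scenarios is 12,857 bp.  At zero noise the
  pipeline is exact down to the configured floor.
* Size precision for ~13 kb tandem duplications is about 4–7% at the
  default error model even after molecule-level refinement: every
  estimate shares the handful of reference anchors nearest the
  junction, whose fusion-displaced positions set a common-error floor
  of several hundred bp that more molecules cannot average away.
* The smallest deletion scenario (45,839 bp) sits at an awkward scale:
  large enough to break alignment chains, small enough that assembly
  occasionally fragments exactly at its junction, leaving no surviving
  map that carries the junction.  Across seeds the eleven-sample cohort
  typically scores ten or eleven concordant samples.
* Assembled maps may remain fragmented into several overlapping
  consensus maps per region; calls from different maps covering the
  same event are deduplicated by type and 50% reciprocal overlap,
  keeping the estimate with the sharpest evidence window.
* A very large gain of material (more than ~6 labels of inserted
  sequence) can split into adjacent gain calls, because the inserted
  query stretch is realigned as its own segment; all gain events in the
  validation scenarios are ~13 kb and unaffected.
* Chimeric molecules whose fragments both map near other maps' ends are
  indistinguishable from genuine bridging molecules and are retained;
  support thresholds dilute their effect.
* Mid-size inversions whose inverted interior is comparable to the
  flanks can in principle be pseudo-crossed by the aligner at small
  per-step cost; the 5.1 Mb scale of the validation inversion makes
  crossing prohibitively expensive, which is the regime the method is
  designed for.

## What the synthetic cohort shows

The bundled cohort reproduces the structure of a published
dystrophinopathy validation series: eight hemizygous probands and three
mothers, with deletions of 45,839–250,092 bp, a 12,968/12,857 bp
duplication-insertion pair, one heterozygous deletion carrier, one
confirmed non-carrier, and one 5.1 Mbp inversion mapped with two enzyme
channels.  Regions are restricted to 3 Mb per family (8 Mb for the
inversion family) and coverage to 40x per channel so the whole cohort
runs on one CPU at desk scale; positions are seeded random, sizes are
exact.  Passing the cohort demonstrates end-to-end recovery of type,
size, zygosity, and breakpoint localization *under this generative
model*.  Real data differ in ways the simulator does not emulate:
sequence-dependent nick density and fragile-site clustering, non-human
contamination, instrument-specific sizing nonlinearity, and
reference-assembly errors.  Conclusions about absolute clinical
sensitivity do not transfer; the demonstration is of the method's
internal consistency and of the geometry of what nick-density-limited
maps can and cannot resolve.
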