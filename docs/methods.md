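# Methods

## Coordinate and signal conventions

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on read and back on write, so round trips are
bijections. Signal tracks are sorted, non-overlapping weighted intervals
with coverage semantics: the value applies to every base, and a region's
raw signal is the per-base integral over it. Overlapping bedGraph
intervals are rejected rather than summed, which keeps the integral
unambiguous; zero-value gaps are implicit.

RPM normalization divides the raw integral by the track's `total_mass`
times 10⁻⁶. A bedGraph cannot know the library size its values came from,
so callers may supply `total_mass` explicitly (e.g. mapped-read count);
otherwise the track's own integral is used. Within one track this choice
only rescales signals, and the super-enhancer cutoff is scale-invariant.

## Distality and stitching

A peak is distal when its boundary is more than `boundary_min` (1.5 kb)
from every TSS **or** its center is more than `center_min` (3 kb) from
every TSS; the two rules are alternatives, strand is ignored, and a peak
containing or touching a TSS has boundary distance 0. Stitching merges
same-chromosome peaks whose end-to-start gap is strictly less than the
12.5-kb threshold; merging is transitive (single linkage), so a chain of
close peaks can form a region far longer than the gap. Both primitives
are verified against brute-force oracles (all-pairs transitive closure;
exhaustive threshold scans).

## The slope-1 tangent cutoff

On the ascending scaled curve (rank/(n−1) vs signal/max), the tangent-of-
slope-1 point is realized as the maximizer of vertical distance below the
diagonal y = x. For a convex curve this is exactly the tangency point; as
implemented it is total — defined for any curve. Ties take the largest
index (the conservative choice: fewest super-enhancers), so a perfectly
linear curve yields zero supers. "Above the cutoff" is strict: the cutoff
region itself is typical. Control-track subtraction is available but off
by default (negative residues clamp to zero); replicate tracks should be
pooled by summation before calling.

## Gene linking and expression clusters

"Adjacent" defaults to the single gene whose TSS is nearest the enhancer
midpoint, with a window mode (default 50 kb from the enhancer span) for
sensitivity analysis; ties break on lexicographic gene id. Expression
change uses the ratio of condition-mean FPKM with pseudocount 2⁻⁵ (the
same offset used for log-scale expression displays) and a default fold-
change threshold of 1.5 — both configurable, since no canonical values
exist for these boundaries. The four-way variant splits unchanged genes
at 1.0 mean FPKM into flat-low/flat-high. The classification is exactly
antisymmetric under swapping condition labels.

## PTM arithmetic and testing

Relative abundance is computed within one peptide and one sample
(percent of summed area over all forms), so percentages sum to 100 by
construction. Single-mark abundance sums the forms carrying the mark;
marks co-occurring on different peptides are never combined, because
short proteolytic peptides cannot witness long-distance co-occurrence.
Condition comparison is a plain two-sided equal-variance t-test with
df = n_a + n_b − 2; zero pooled variance is handled explicitly (p = 1
for equal means, a p = 0 sentinel with warning otherwise). No multiple-
testing correction is applied by default, matching the plain p < 0.05
convention of the source analyses; a Benjamini–Hochberg flag exists for
users who want it. Marks detected in only one condition are flagged and
excluded from the volcano fold-change axis rather than mapped to ±∞.

## Synthetic-data generator

The generator emulates the statistical structure of a two-condition
tissue study: clustered distal acetylation peaks with a heavy-tailed
ranked-signal curve, a co-localized H4K8ac track with tunable per-region
correlation, intergenic H3K4me3 over a subset of high-H3K27ac regions,
FPKM tables in which super-enhancer-adjacent genes are tumor-boosted, and
3+3 replicate peptidoform areas with planted differential marks.

Layout: one element per 50-kb slot (gene, typical cluster, super cluster,
or H3K4me3 region), shuffled across chromosomes. The spacing guarantees
that every planted cluster is distal to all TSSs and farther than the
stitch gap from its neighbours, so each planted cluster maps to exactly
one stitched region and ground truth is unambiguous.

Signal model: each cluster has a planted region-level H3K27ac mass —
class base (typical ≈ 3,000 value·bp; super = base × `se_signal_ratio`,
default 20) times a log-normal factor with σ = 0.1 whose z-scores are
truncated at ±2. Region-level dispersion is kept modest and bounded so
the planted classes are separable and the ground truth well defined;
heavy-tailed behaviour lives at the per-peak level, where heights follow
a log-normal with σ = 0.3 renormalized to preserve the region mass.
H4K8ac region masses are a log-scale ρ-correlated copy of H3K27ac (at
ρ = 1 the two tracks are exactly proportional). High-signal H3K4me3
domains span their cluster hulls; a configured fraction sit on
conventional super clusters and the rest on high-H3K27ac regions that
carry no H3K27ac peak call — regions the peak-based caller cannot see,
as intergenic-H3K4me3 enhancers missed by one antibody would be.

Expression: per-gene mean FPKM ~ Gamma(1.5, 8); replicates ~ Gamma(3,
mean/3); tumor means of super-adjacent genes multiplied by the boost
(default 4). Peptidoform areas are log-normal (σ = 0.25) around per-form
means; tumor multiplies areas of forms carrying a designated mark by that
mark's effect (defaults: H3K27ac 2.5×, H4K8ac 2×, H3K4me3 2.5×,
H3K36me3 0.4×), mirroring the acetylation-up/H3K36me3-down pattern of
transformed tissue.

Every output is a pure function of the configuration: each stage draws
from its own stream derived from (seed, stage id), and all writers format
floats deterministically, so reruns are byte-identical.

What the generator does **not** model: read-level noise, fragment-size
and GC bias, background signal between peaks, copy-number variation,
promoter-proximal signal competition, or compositional coupling between
marks beyond the closure inherent in relative abundances. Passing the
planted-truth tests therefore demonstrates correctness of the pipeline's
arithmetic and decision rules under clean class structure — not
robustness to the full messiness of real ChIP-seq.

## Problem sizes and numerical choices

Default study conditions: 2 chromosomes, 120 genes, 60 typical + 5 super
clusters, 30 low- and 6 high-signal H3K4me3 regions, 3+3 replicates —
small enough to simulate in milliseconds, large enough that the ranked
curve has a well-formed elbow. Oracle comparisons run on 1,000 random
curves (n ≤ 1,000) and 500 random stitching instances (≤ 200 peaks);
calibration uses 10,000 null replicates at n = 3+3; recovery statistics
aggregate 20 independent seeds. Conservation identities (percent sums,
partition additivity, bin mass) are exact to 1e-9 or better. Zero-
variance vectors yield NaN correlations rather than silent zeros; all
sort ties (ranking, gene assignment) break deterministically on genomic
position or identifier.

## Known limitations

- The stitched-region signal uses coverage integrals, not read counts;
  with user data the RPM denominator is only as meaningful as the
  supplied `total_mass`.
- Enhancer-gene assignment by adjacency is a heuristic; no contact data
  is consulted.
- The H3K4me3-variant and conventional calls share the H3K27ac track, so
  their super sets are not independent observations.
- `compare_conditions` at n = 3 has the usual fragility of tiny-sample
  t-tests; the calibration guarantee is for normal data.
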