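# Methods

This note documents the model implemented by `mitonet`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## Segmentation

Confocal images are segmented by: median smoothing (disk radius 2 px) →
contrast enhancement → intersection of a local and a global threshold →
neighbour-count erosion. Contrast enhancement clips the intensity tails
(0.4 % of pixels saturated, split between the two tails), rescales to
[0, 1] and equalizes the histogram; the order of these sub-steps is one
consistent reading of common practice and is fixed here. The local
threshold compares each pixel with the median of a (2·10+1)² window —
10 px being on the order of a mitochondrion's apparent width — and the
global threshold is either a manual value (the recommended practice,
chosen per image) or the triangle method as an automatic default.
Erosion removes a foreground pixel when ≥ 4 of its 8 neighbours are
background, once; this deletes residual single-pixel noise without
shortening tubules. All window operations use reflect padding.
Synthetic images contain no background structure and are segmented with
a single global threshold.

## Skeleton and structural elements

The binary mask is reduced to a 1-px centreline with topology-preserving
thinning (Zhang's algorithm as implemented in scikit-image). Each
skeleton pixel is typed by its number of 8-connected skeleton
neighbours: 1 → end, 2 → tubule, ≥3 → junction. Connected same-type
pixels merge into structural elements; tubule elements carry their
ordered pixel path. Two pixel-level artifacts are normalized after
merging: a single degree-2 pixel wedged between two pixels of one
junction component (a rasterized sharp corner) is absorbed into that
junction, and any junction element left with only two attachments is a
certain pass-through and is dissolved into its two tubules. Degenerate
components of one or two pixels (no tubule/junction pixel at all) are
represented as one tubule plus two zero-pixel ends, so every unbranched
mitochondrion counts exactly three elements. Closed loops without
junctions are single ring tubules with no ends; they are reported
separately and exempt from the element-count identities.

Junctions with four or more attachments are interpreted as two
mitochondria crossing, not as one four-way branch point. Their branches
are paired by maximal collinearity: each branch direction is estimated
by a principal-axis fit over the first five tubule pixels leaving the
junction, and the perfect matching minimizing the summed angular
deviation from straight continuation wins. Odd degrees ≥ 5 are paired
greedily until three branches remain as a residual 3-way junction (with
a warning). On every non-ring cluster the handshake identity
2·T = E + Σ<sub>j</sub> degree(j) then holds exactly and is asserted in
the test suite.

Clusters are connected components of the element graph. A cluster is
excluded from analysis when the foreground fraction of its bounding box,
padded by 10 px (about one apparent mitochondrion width), exceeds 0.6 —
skeletons are unreliable in such dense regions. The padding matters:
the *unpadded* box of a thin straight cluster is trivially ~100 %
foreground, which would absurdly exclude every isolated horizontal
mitochondrion.

### Connectivity metrics

Per image (over kept clusters): counts and percentage shares of ends,
tubules and junctions; elements per cluster *E*<sub>C</sub> (mean; 3 for
an isolated unbranched mitochondrion, growing with connectivity);
junction/end ratio *J/E* (0 for fully fragmented networks; undefined and
reported as missing for pure-ring images); tubule/end ratio; summed
junction degree per μm of skeleton. Shape classes follow their
operational definitions: a **donut** is a degree-3 junction attached
twice to the same tubule with its third attachment leading to an end; a
**blob** is an isolated three-element cluster shorter than 1 μm;
three-element clusters of 1–2 μm are counted separately as short
isolated mitochondria.

## Probabilistic topology interpretation

Each degree-3 junction carries a configurable table of local connection
patterns, all equally likely. The shipped default has 8 patterns: all
three branches terminating (1), one pass-through pair with the third
branch terminating (3), one pass-through pair with the third branch
abutting but unconnected (3), and a true three-way fusion (1). The
abutting patterns resolve paths identically to the terminating ones but
describe a different physical scene and are kept distinct, which gives
pass-through configurations the larger prior weight two readings imply.
The table is a JSON data file (`mitonet/data/junction_patterns.json`,
regenerated by `scripts/generate_junction_table.py`) and is hashed into
every result, so alternative tables — including larger ones with
directional duplicates — can be dropped in without code changes.

An interpretation chooses one pattern per junction; linked branches
merge tubules into one mitochondrion (possibly branched, for the fusion
pattern), terminated branches end there. Under any table built from
pair/terminate/fuse patterns every joint choice is admissible — no
tubule can be claimed by two paths — so sampling draws patterns
independently and uniformly per junction from a single seeded generator.
Clusters whose interpretation tree has ≤ 10 000 leaves are enumerated
exhaustively instead of sampled; junction-free clusters have exactly one
interpretation and zero uncertainty.

Path lengths are Euclidean sums over the ordered tubule pixels (1 or √2
per step, avoiding the pixel-count overestimate), plus small junction
terms: a traversed junction contributes the straight-line distance
between the two attachment pixels; a fused junction the distances from
each attachment to the junction centroid; a terminating branch half the
junction extent (pixel-set diameter + 1). End elements contribute their
own pixels and the connecting step. Within each cluster, per-sample
length histograms (default 0.5 μm bins, half-open, overflow clamped at
25 μm) are normalized and averaged; the per-bin SD across interpretations
is the confidence band. Image distributions weight each cluster by its
expected mitochondrion count, renormalize, and combine SDs as the
count-weighted root-mean-square (clusters are independent).

Two deterministic extremes bracket the probabilistic answer: the
branch-to-branch decomposition (every tubule its own mitochondrion) and
the greedy longest-path decomposition (repeatedly extract the longest
admissible path; ties break on the lexicographically smallest element-id
sequence). Mean length under branch-to-branch ≤ probabilistic mean
(total length / expected count) ≤ mean under longest-path, to within the
small junction-term wobble; the tests assert this with 5 % slack.

## Earth mover's distance and the replicate protocol

On a shared binning, EMD = Σ<sub>bins</sub> |CDF₁ − CDF₂| · bin width —
the exact 1-D transport cost for mass placed on the bin grid, verified
in the tests against a transportation linear program and SciPy's
Wasserstein distance. Values are in the units of the bin axis
(EMD<sub>μm</sub> on micrometre bins; pixel-bin EMD values are not
comparable to them and results are labelled accordingly). Note one
consequence of the grid convention: splitting every bin in two can move
the value by up to half a bin width, because refinement relocates the
atoms; the tests bound this rather than asserting exact invariance.

The replicate protocol compares, for each of two conditions, every
replicate distribution against its own condition's average (experimental
variability) and against the other condition's average (treatment
effect). Averages are per-bin arithmetic means of the replicate masses,
renormalized afterwards. Statistical testing of the resulting EMD values
is deliberately left to external tools; the report is a tidy CSV.
Small image sections can be pooled into one analysis unit before
interpretation to give each section statistical weight. For two-channel
comparisons (outer-membrane vs matrix marker), the per-parameter ratios
*E*<sub>C</sub>(outer)/*E*<sub>C</sub>(inner) and the same for *J/E* are
reported — near 1 for matching network structure. The per-cell
phenotype scatter plots *J/E* (connectivity) against 1/(mass in the
1 μm bin) (a length proxy that grows with elongation), both normalized
to the control-cell means, with control ±SD bands.

## Synthetic benchmark

The generator emulates the validation conditions the pipeline is
benchmarked under: 500×500 px images at 15 px/μm containing 10–500
mitochondria (more for density sweeps). Each centreline is a bounded-turn
random walk of unit-pixel steps whose step count matches a length drawn
from the configured model, truncated to 1–10 μm:

| parameter | default | rationale |
| --- | --- | --- |
| D1 | Normal(3 μm, 0.75 μm) | fragmented-like simple Gaussian; the mean is the benchmark condition, the SD a package choice |
| D2 | ½N(2.5, 0.5) + ½N(5, 0.5) μm | bimodal test case; centres are the benchmark condition |
| D3 | packaged table | fibroblast-like: truncated log-normal surrogate, mode ≈ 2 μm, editable data file (`d3_fibroblast_like.json`) |
| tortuosity | 5°/step heading SD | see below |
| profile σ | 2 px | Gaussian cross-section; half-max width 2σ√(2 ln 2) ≈ 4.7 px ≈ 0.31 μm, the physical diameter of a mitochondrial tubule |
| threshold | 0.5 × single-tubule peak | full-width-at-half-max segmentation |

Rendering deposits each walk point with bilinear sub-pixel weights
before Gaussian filtering, and the image is scaled so an isolated
straight tubule peaks at 1.0. Walks reflect at the image border.
The tortuosity default was set by a physical constraint: heading noise
much above ~5°/step makes the centreline wiggle at the pixel scale,
which Gaussian widening smooths away, so the recovered skeleton is
systematically ~10–18 % shorter than the truth even on sparse images —
violating the round-trip fidelity the benchmark requires. At 5°/step the
persistence length is a few hundred nm, filaments are visibly curved,
and sparse round-trip ratios sit at 1.03–1.08. Larger values remain
available through `SyntheticSpec`.

In no-overlap mode, placements keep 12 px of centreline clearance
(rejection sampling), guaranteeing that masks of distinct mitochondria
never touch — the regime where *E*<sub>C</sub> must be exactly 3.

### Accuracy scoring

`skeleton_accuracy` compares the recovered skeleton with the truth on
two axes. *Positional agreement* is the fraction of skeleton pixels
within 1 px (chessboard distance) of any ground-truth centreline pixel;
an image "agrees" at ≥ 0.95. The *length ratio* divides the true total
length by the Euclidean length of the recovered skeleton, where skeleton
length counts each 8-neighbour step once and drops diagonal steps whose
orthogonal detour exists (otherwise staircase rasterizations are
overcounted by ~7 %).

What the benchmark shows — and does not. The generator reproduces
densities, lengths, widths and curvature of confocal mitochondria but
not photon noise, point-spread anisotropy, uneven background, 3-D
projection overlap or labelling heterogeneity; passing it validates the
geometric/topological chain, not robustness to those factors. Two of
its published-behaviour properties deserve explicit caveats, both
computed afresh by `scripts/acceptance.py`:

* The length-fidelity degradation at high density is *upward*: merging
  makes the recovered skeleton shorter, so the true/recovered ratio
  rises above 1 smoothly with area fraction (≈1.07 at 16 %, ≈1.7 at
  66 %, ≈3.7 at 90 % in the packaged sweep). A criterion phrased as
  "ratio stays ≥ 0.9" is therefore met at every density the sweep
  reaches.
* Per-pixel positional agreement has a physical ceiling. Wherever two
  tubules overlap, the medial axis of the merged region lies between
  the two centrelines — 1–2 px from each — so the per-image match falls
  from ≈0.98 at 100 mitochondria to ≈0.93 at 500, and the fraction of
  images agreeing at the 0.95 cutoff over the 100–500 range is ≈57 %,
  not ≈97 %. No pixel-accurate skeleton can avoid this; a claim of
  near-universal positional agreement at these densities must rest on a
  coarser notion of "same place" than 1 px.

## Problem sizes and determinism

The default analysis uses 1000 interpretation samples per cluster
(exact enumeration below 10 000 tree leaves), 0.5 μm bins, and the
acceptance script runs 10 replicates per density over 100–2000
mitochondria for the sweep and 108 images for the agreement rate —
sizes chosen to keep a full rerun within a couple of minutes on one
CPU while leaving the Monte-Carlo error well below the tolerances
tested. Every stochastic step (generation, placement retries,
interpretation sampling) draws from one seeded NumPy generator; the
seed and the interpretation-table hash are recorded in summaries and
metadata, and identical seeds reproduce results bit-for-bit.

## Known limitations

* 2-D only: overlapping structures in z project onto crossings that the
  4-way split resolves statistically, not physically.
* The interpretation prior is uniform over the pattern table; no image
  evidence (intensity, width, curvature continuity) reweights patterns.
* The degree-3 pattern table is a defensible default, not a unique
  truth; results depend on it mildly through the pass-through prior.
* The greedy longest-path decomposition enumerates simple paths and is
  exponential in cluster size; it falls back to capped exploration on
  very large clusters and is intended for small-to-moderate clusters.
* The fibroblast-like D3 table is a shaped surrogate, not an empirical
  histogram; replace the data file for cell-type-specific work.
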