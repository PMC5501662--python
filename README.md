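# mitonet

Probabilistic quantification of mitochondrial network length and
connectivity from confocal fluorescence images.

## The problem

Mitochondria form a dynamic network that continuously fuses and
fragments. Its state — the distribution of individual mitochondrial
lengths and how connected the network is — reports on nutrient stress,
apoptosis and inner-membrane (cristae) remodelling. Measuring it from a
2-D confocal image is hard because overlapping and touching mitochondria
make the true topology ambiguous: where two tubules cross or meet, the
image alone cannot say whether they are one long organelle, two fused
ones, or independent mitochondria lying on top of each other.

Instead of committing to a single topology, `mitonet` enumerates (or
samples) the admissible topologies and reports the *expected* length
distribution with a confidence band that quantifies the topological
ambiguity itself.

## Method in brief

For a binary mitochondrial mask the pipeline:

1. **Skeletonizes** the mask to a 1-px, topology-preserving centreline.
2. **Classifies** each skeleton pixel by its 8-neighbour count — 1 →
   end (*E*), 2 → tubule (*T*), ≥3 → junction (*J*) — and merges
   adjacent same-type pixels into structural elements. Junctions of
   degree ≥ 4 are treated as two mitochondria crossing and are split
   into pass-through tubules by maximal collinearity.
3. **Clusters** connected elements; each cluster is a set of
   overlapping/connected mitochondria analysed as one unit. Clusters in
   regions with > 60 % mitochondrial area are excluded (skeletons are
   unreliable there). Connectivity metrics are compiled per image:
   element fractions, elements per cluster *E*<sub>C</sub> (3 for an
   isolated mitochondrion: one tubule + two ends), junction/end ratio
   *J/E* (0 for a fully fragmented network), donut and blob counts.
4. **Interprets** each cluster probabilistically: every degree-3
   junction carries a table of equally likely local connection patterns
   (branches pass through, terminate, or fuse into a true branch
   point). A joint choice of one pattern per junction resolves the
   cluster into individual mitochondrion paths with definite lengths.
   Small clusters are enumerated exhaustively; large ones are sampled
   (default 1000 interpretations). Per-cluster length histograms are
   averaged, weighted by expected mitochondrion count, and summed into
   the image distribution with a ±1 SD band.

Distributions are compared with the 1-D earth mover's distance
(EMD<sub>μm</sub> = Σ<sub>bins</sub> |CDF₁ − CDF₂| · bin width), using a
within-condition vs between-condition replicate protocol; two-channel
ratios (e.g. outer-membrane vs matrix markers) of *E*<sub>C</sub> and
*J/E* flag inner-membrane rearrangements.

A ground-truthed synthetic image generator (curved centrelines widened
by a Gaussian profile, 500×500 px at 15 px/μm, configurable length
models D1/D2/D3) validates the whole chain.

## Worked example

```python
import numpy as np
from mitonet import MitochondrialNetwork, SyntheticSpec, generate_image
from mitonet.synthetic import DEFAULT_SYNTHETIC_THRESHOLD

spec = SyntheticSpec(n_mitochondria=100, length_model="D1", seed=11)
gray, gt = generate_image(spec)                      # image + ground truth
net = MitochondrialNetwork.from_synthetic(gray, DEFAULT_SYNTHETIC_THRESHOLD)
res = net.fit(n_samples=300, seed=2)
print(res.summary())
```

prints

```
Mitochondrial network analysis
==============================================
image size: 500 x 500 px (0.0667 um/px)
clusters analysed: 66 (excluded dense: 0, 0.0%)
interpretation samples/cluster: 300 (seed=2, table=ac22ea47472a2850)
----------------------------------------------
ends / tubules / junctions: 162 / 126 / 30 (50.9% / 39.6% / 9.4%)
elements per cluster (E_C): 4.818
junctions/ends (J/E):       0.185
tubules/ends (T/E):         0.778
connections per um:         0.3408
total skeleton length:      264.09 um
donuts / blobs / 1-2um iso: 0 / 1 / 6
----------------------------------------------
expected mitochondria:      96.0
mean mitochondrial length:  2.95 um
```

The 100 simulated mitochondria were drawn from a Gaussian with mean
3 μm; the pipeline recovers 96 expected mitochondria with a mean length
of 2.95 μm (ground-truth sample mean: 3.02 μm). The 66 clusters show the
mild connectivity that random overlap produces at this density
(*E*<sub>C</sub> = 4.8, *J/E* = 0.19). `res.distribution` holds the
binned length distribution with its ±1 SD band (`res.plot()` draws it),
`res.cluster_table()` the per-cluster CSV-ready table.

The same pipeline is scriptable from the shell:

```bash
mitonet simulate --model D1 --n 300 --seed 7 --out sim/
mitonet analyze sim_masks/*.tif --n-samples 1000 --seed 1 --out analysis/
mitonet compare --condition ctrl c1.csv --condition ebss t1.csv ...
mitonet sweep --sweep 100:500:100 --model D3
```

## Layout

| module | contents |
| --- | --- |
| `mitonet.segmentation` | confocal + synthetic segmentation, area fractions |
| `mitonet.skeleton` | skeletonization, skeleton graph, length estimator |
| `mitonet.elements` | element classification, 4-way splitting, clusters, connectivity metrics, donuts/blobs |
| `mitonet.interpret` | interpretation tables, sampling, exact enumeration, length variants |
| `mitonet.distributions` | binned length distributions with uncertainty |
| `mitonet.stats` | EMD, replicate protocol, pooling, two-channel ratios, per-cell scatter |
| `mitonet.synthetic` | ground-truthed image generator, accuracy scoring, density sweeps |
| `mitonet.model` | `MitochondrialNetwork` / `NetworkFitResults` high-level interface |
| `mitonet.cli` | `mitonet` command-line tool |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
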