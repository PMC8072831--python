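# Methods

## Model

Chromatin is represented as an ordered chain of partially penetrable
spheres ("beads"), one per genomic bin of a symmetric, nonnegative Hi-C
contact-frequency matrix.  The model makes three structural assumptions:

1. **Block locality.**  The matrix is close to block-diagonal: TAD-like
   regions interact internally far more than externally, so each
   diagonal block's sub-chain can be estimated independently of the
   rest of the chromosome.
2. **Contacts, not distances.**  Contact frequencies are never converted
   to target distances (a transformation known to produce geometrically
   inconsistent distance sets); instead the data enter a score function
   that rewards contact-rich pairs for being near touching distance.
3. **Ensembles, not consensus.**  Hi-C counts average millions of cells,
   so the output is a family of conformations with similar scores, not
   a single optimum.

### Score function

A candidate configuration C of one sub-chain is scored by

    Xi(C) = Phi_HiC(C) + mu1 Phi_ChIP(C) + mu2 Phi_RNA(C) + lambda Psi(C)

interpreted as a negative log-posterior (lower is better).

**Data fit.**  `Phi_HiC = sum_{(i,j) in L} n_ij [d_ij - (r_i+r_j)]^2`,
where `n_ij` is the contact frequency, `d_ij` the centroid distance and
`r_i` the bead radii.  L contains the pairs whose frequency reaches a
per-block percentile (default 75th) of the nonzero upper-triangle
entries; the cut is inclusive, so blocks whose nonzero entries are all
equal (e.g. binary matrices) still have a nonempty data term.  At
`d_ij = 0` the term takes the finite value `n_ij (r_i+r_j)^2`; keeping
beads apart is delegated to the barrier.

**Repression (H3K27me3).**  For blocks flagged repressed,
`Phi_ChIP = [max d_ij - d_min]^2` over non-adjacent pairs: the whole
sub-chain is squeezed toward diameter `d_min`, raising its curvature.

**Expression (RNA-seq).**  For blocks flagged expressed,
`Phi_RNA = [min d_ij - d_max]^2` over non-consecutive pairs: every such
pair is pushed to at least `d_max`, lowering curvature.  Blocks carrying
both marks have both terms active; their opposing pulls largely cancel.

**Excluded volume.**  With `x = c (d_ij - (r_i + r_j))`,

    psi_ij = (r_i + r_j) / (2 d_ij) * [1 - x^b / (1 + |x|^b)]

summed over all pairs.  The bracket approaches 2 deep in overlap and
decays like `|x|^-b` outside, so psi behaves as `(r_i+r_j)/d_ij` toward
coincidence (where it diverges), equals `(r_i+r_j)/(2 d_ij)` at contact,
and vanishes rapidly at separation.  The odd exponent `b` sets how
abrupt these transitions are.  The grouping of the bracket was chosen as
the one whose three asymptotic regimes are exactly those just listed —
the alternative reading, a pure ratio `(1-x^b)/(1+|x|^b)`, decays only
like `1/d` and has no factor-2 distinction between the coincidence and
contact regimes.  Coincident centers (`d_ij = 0`) are a hard error; the
sampler rejects such proposals before scoring.

### Geometry

Bead-size bounds at working resolution RIS (kilobases) for a chromatin
fiber of diameter `d_c`:

    d_min = d_c RIS^(5/6) / (6 pi),    d_max = d_c RIS^(5/6) / (3 pi)

so `d_max / d_min = 2` identically.  At the defaults `d_c = 30 nm`,
`RIS = 5 kb`: `d_min ≈ 6.09 nm`, `d_max ≈ 12.17 nm`.  The 5/6 exponent
and the denominators are exposed in `GeometryParams` because the
resolution scaling is a modeling choice, not a measured constant; RIS is
taken in kb (bp would give micrometer-scale beads at 5 kb resolution,
inconsistent with a 30 nm fiber).

Within a block, raw bead size is `1/(k_i + 1)` with `k_i` the bead's
intra-block contact total (contact-rich fiber is more compact; the +1
keeps contact-free beads finite), rescaled so the mean diameter equals
the nominal diameter (default: midpoint of `[d_min, d_max]`).  Diameters
are then modulated by transcriptional state: ×1.1 in active bins, ×0.9
in repressed bins, unchanged where both or neither mark is present.
These ±10% factors encode the chromatin volume concentration contrast
between euchromatin (~20%) and heterochromatin (~40%); no separate
volume bookkeeping is done.

### Feature tracks

RNA-seq enters as a binary per-bin array: 1 iff the bin overlaps an
expressed-gene interval by at least 1 bp (0-based, half-open bins).
ChIP-seq signal at fine resolution (e.g. 20 bp) is summed into the
Hi-C bins and thresholded: 1 iff the aggregate strictly exceeds 300
(configurable).  CTCF loop calls become a binary symmetric pair matrix;
multiplied by a scalar (default: the 90th percentile of the block's
nonzero Hi-C entries, so a loop ranks among the strongest observed
contacts without dwarfing them) and added to the Hi-C matrix, they act
as proximity constraints.  A block is flagged expressed/repressed if any
of its bins carries the flag (an alternative fraction-of-bins rule is a
config option); a CTCF pair constrains geometry at the first resolution
level at which both anchors fall inside one block.

### Block detection

The boundary statistic is a moving average over sliding triangles: at
boundary position p, the mean of the entries `(i, j)` with
`p - w < i <= p < j <= p + w` — the cross-boundary wedge of half-width
`w` (default 5 bins).  Boundaries are strict local minima of this score
that fall below a relative cut (default 0.5 × the mean score, rejecting
shallow noise dips inside blocks; ties broken leftmost).  Boundaries
closer than `min_size` (default 4 bins) to each other or to the matrix
edges are merged, keeping the lower-scoring one; blocks longer than
`max_size` (default 40) are split at their deepest internal minimum.
The window should not exceed the expected block size: a wedge wider
than the blocks mixes intra-block entries into boundary scores and
lifts them above the relative cut (the test fixtures with 4–8-bin
blocks use `w = 3`).

Binning each block to one bin yields the next level's matrix; the
coarse diagonal stores each block's internal mass in the
upper-triangle-plus-diagonal sense, so total mass in that sense is
conserved across levels.  Detection and binning recurse until a single
block remains.

### Sampling

Metropolis annealing with geometric cooling.  Moves are quaternion
pivot rotations — a uniformly chosen interior bead anchors a rigid
rotation of one side of the chain about its center, with a random axis
and an angle uniform in (0, max_angle] — mixed (70/30) with Gaussian
single-bead jitter of scale 0.1 × mean radius.  Quaternions give
numerically stable composition of 3-D rotations without gimbal
artefacts.  Proposals bringing any two centers within 1e-6 nm are
rejected outright.

The initial temperature defaults to the standard deviation of Xi over
100 random initial configurations.  The cooling factor is 0.85 per
stage with 50 stages of 200 steps by default: the final temperature is
then ~3e-4 of the initial, which freezes the chain.  This matters — at
a cooling factor of 0.95 over 50 stages the final temperature is still
~8% of the initial, the sampler never leaves the fluctuation-dominated
regime, and the compaction/expansion responses to the epigenomic flags
become statistically invisible; 0.85 was therefore adopted as the
default.  The trace records, per stage, the temperature and the best
score found so far (a running minimum, monotone by construction).

Ensembles are built from independent runs with per-run seeds derived
from the master seed by a splitmix64-style mixing function (kept below
2^31), each run starting from its own random initial chain.

### Multilevel assembly

Per level, every block's ensemble is estimated, then each block
collapses to one bead whose radius is half the maximum pairwise
centroid distance plus the mean member radius, averaged over the
ensemble (a gyration-radius alternative is a config option).  The
coarsest matrix is estimated as a single chain, ensemble-wise: output
structure m uses its own top-level sample and, at every finer level,
the m-th ensemble member of each block.  Reassembly substitutes each
coarse bead with its sub-chain, rigidly translated so the sub-chain
centroid sits at the bead center and rotated so its end-to-end vector
follows the local coarse-chain direction (previous-to-next bead;
endpoints use their single neighbor).  "Orientation" has no defined
reference frame at the coarse level, so end-to-end alignment to the
local tangent is this package's concrete choice; sub-chain internal
geometry is preserved exactly.

### Evaluation

From an ensemble, the synthetic contact matrix counts, per pair, the
members in which `d_ij <= alpha (r_i + r_j)` (default alpha 1.2 — a 20%
tolerance mirroring the partial penetrability of the beads; the
construction of synthetic matrices from configurations is a forward
model this package defines, exposed in config).  Quality is the Pearson
correlation of upper triangles (diagonal excluded, self-contacts being
uninformative) between observed and synthetic matrices; per-block
reports give both the pooled-ensemble correlation and the mean
per-member correlation, the two natural ensemble summaries.

## Synthetic data

The fixtures module generates every input class the pipeline consumes:

* **Planted matrices** — Poisson counts at `intra_density` (default 10)
  inside planted blocks and `inter_density` (default 1) outside, with
  optional truncated-normal noise: the block-diagonal caricature of a
  Hi-C matrix with known boundaries.
* **Reference chains** — helix, seeded random walk, or hairpin (two
  antiparallel arms giving one long-range near-contact pair, a stand-in
  for a CTCF loop), with consecutive beads exactly touching.
* **Tracks** — binary expressed/repressed spans and CTCF pairs by bin
  index.

What these emulate — and what they do not: planted matrices have sharp,
noise-free block structure and independent Poisson entries, whereas
real Hi-C has genomic-distance decay, ICE-normalization artefacts and
correlated noise; reference chains yield nearly binary contact
matrices; tracks are exact, while real peak calls and expression
quantification carry their own error.  Passing tests therefore
establish internal consistency — the method recovers structure its own
forward model generated, detects planted boundaries, and responds to
constraints in the predicted direction — not reconstruction accuracy on
experimental data, where correlations per block are known to be far
lower.

## Problem sizes

The shipped tests and the acceptance script run desk-scale problems
chosen to exercise every code path with comfortable statistical
margins: 24-bead reconstruction with 20-member ensembles, 8–10-bead
blocks for the 100-pair feature and CTCF comparisons, 20 planted
fixtures of 2–4 blocks.  Chromosome-scale inputs (thousands of blocks)
use the same code but are cluster-scale jobs.

## Numerical choices and degenerate inputs

* Score weights default to `mu1 = mu2 = lambda = 1`, `b = 3`,
  `c = 1/(mean bead diameter)` (making `x` dimensionless at the chain's
  own scale), percentile 75 — none of these are measured constants;
  all sit in the config.
* Contact matrices must be symmetric to 1e-8 relative; smaller
  asymmetries are averaged away, larger ones are errors, as are
  negative or NaN entries.
* A matrix with fewer than `2 min_size` bins, or with no qualifying
  boundary minimum, is a single block; the pipeline then reduces to one
  annealing run and trivial reassembly.
* Chains need at least 2 beads; pivot rotations need 3, so 2-bead
  chains are sampled by jitter moves alone.
* Blocks flagged both expressed and repressed keep both score terms
  active; beads flagged both keep their unmodulated diameter.
* Percentile convention: linear interpolation, inclusive cut (see
  above).  Boundary ties in block detection: leftmost wins.

## Limitations

* Only intra-chromosomal (cis) contacts; no trans contacts, no
  normalization (matrices are taken as given).
* The annealer is a stochastic sampler, not an optimizer with
  guarantees; rates quoted by the acceptance script are paired-run
  frequencies under fixed seeds.
* Coarse-level "orientation" of sub-chains is identified with the
  end-to-end axis; sub-chains with near-zero end-to-end distance are
  placed by translation only.
* No nucleosome-level geometry; the 30 nm fiber diameter is a model
  constant, not a claim about fiber structure in vivo.
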