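# Methods

## Model

The tissue is a planar cell-adjacency structure evolved by cell
division only: no rearrangement, migration, or apoptosis. Each real
cell is represented combinatorially by the cyclic counterclockwise list
of its neighbors (a rotation system); the number of neighbors is the
cell's polygon class k. Boundary edges of the growing patch each border
one *fake* cell — a side-count-0 placeholder for the exterior that
never divides. Growth starts from a single cell (default 7-sided; the
final distributions are known to be insensitive to this choice) and
proceeds in discrete cycles in which every real cell divides exactly
once, so cycle n ends with 2^n cells.

A division of an i-sided mother chooses an edge for each endpoint of
the cleavage plane: side1, then side2 at counterclockwise offset
u ∈ {2, …, i−2} (adjacent edges are excluded, which precludes
tetravalent vertices and 3-sided cells). The mother is replaced by
daughters of u+2 and i−u+2 sides that share the new edge; a real cell
across a cut edge gains one side and becomes adjacent to both
daughters; a boundary cut edge is split into two boundary segments.
Total side count therefore grows by 4 + (number of real cells across
cut edges) ∈ {4, 5, 6} per division, which keeps the mean side count
below 6 + 1/n at all times.

## Strategy options

**side1.** `LaN`/`SmN` pick the neighbor with the most/fewest sides
(ties uniform); `RandN` picks an edge uniformly. The `Orth*` family
anchors side1 on the edge shared with the sister cell. When the sister
has already divided this cycle and its cleavage plane cut the shared
edge, the cell borders both nieces and a sub-rule selects between them:
current side counts (`OrthSmN` fewer / `OrthLaN` more), side counts at
the nieces' birth (`OrthBornSmN` / `OrthBornLaN`), a fair coin
(`OrthRandN`), or the fewer-sided niece with probability `smp`
(`OrthSmpN`). Side-count ties resolve toward the niece that retained
the mother's label for the `SmN`-flavored rules and away from it for
the `LaN`-flavored ones; under `OrthSmpN` a tie selects the
label-retaining niece with probability `smp`.

**side2.** All distributions are over u ∈ {2, …, i−2}: `evensplit`
(mass on the most even split; odd i ties broken ½/½), `random`
(uniform), `unevensplit` (½/½ on u = 2 and i−2), `Binomial`
(u−2 ~ Binomial(i−4, ½)), `Even-Binomial` (the exact mixture
(1−probB)·evensplit + probB·Binomial), and the rotation models. For
`rotNorm`/`rotTanNorm` the mother is modeled as a regular i-gon, the
plane is anchored at the midpoint of side1, and β = 0 is the ray
through the centroid (the perfectly even cut). Each edge's angular
interval is computed by exact coordinate geometry (the i−1 intervals
tile (−π/2, π/2) and are symmetric under u ↔ i−u); interval masses are
closed-form normal-CDF differences — Φ(b/σ) − Φ(a/σ) for `rotNorm`
(density truncated to (−π/2, π/2); the constant cancels), and
Φ(tan b/σ) − Φ(tan a/σ) for `rotTanNorm`. Mass falling on the two
adjacent edges is removed and the remainder renormalized; this is the
deterministic, resampling-free way to honor the non-adjacency rule
while keeping the rotation picture. As stdbeta → 0 both collapse onto
`evensplit` (for odd i the β = 0 ray hits the opposite vertex, giving
the ½/½ tie), and the two models agree in that limit since tan β ≈ β.

**Order.** `Random` draws a uniform permutation of the real cells each
cycle. `Strict` keeps each sister pair consecutive, sequences pairs by
their mothers' positions in the previous cycle's realized order, and
randomizes within pairs independently — the strongest possible
correlation between consecutive division times in a model with
discrete cycles.

## Parameters

| name | meaning | range | used by |
|---|---|---|---|
| `smp` | probability of picking the fewer-sided niece | [0, 1] | OrthSmpN |
| `probB` | weight of the Binomial component | [0, 1] | Even-Binomial |
| `stdbeta` | std. dev. of β (radians) or of tan β | > 0 | rotNorm / rotTanNorm |
| `initial_sides` | polygon class of the founding cell | ≥ 4 | all (default 7) |
| `cycles` | division cycles per experiment | ≥ 0 | all (default 12) |
| `batch_size` | experiments pooled per batch | ≥ 1 | all (default 100) |

Default snapshots are taken after cycles 9, 10, 11 and the final cycle.

## Design choices

- **Rotation system.** Only side counts and the adjacency matrix are
  strictly needed to *describe* the model, but selecting "the u-th edge
  counterclockwise" and partitioning neighbors between daughters
  requires a cyclic edge order, so cells store one; S and N are derived
  views. Daughter A — the arc from side1 counterclockwise to side2 —
  deterministically keeps the mother's id, which pins down the
  label-retention tie-breaks and makes runs replayable.
- **Fake cells.** One fake cell per boundary edge. When a boundary
  edge is cut, the existing fake id stays with daughter A's segment and
  a fresh fake id is minted for daughter B's, preserving the unique
  edge-per-neighbor representation for daughters with several boundary
  edges.
- **Fake neighbors in side1 rules.** `RandN` draws over all edges
  (boundary included); `LaN`/`SmN` compare real neighbors only, since a
  fake cell's side count of 0 is a sentinel, not a biological count
  (uniform fallback if every neighbor is fake; a flag
  `extremes_include_fake` exposes the other reading).
- **First cycle under Orth*.** The founding cell has no sister, so
  side1 is chosen uniformly; from cycle 2 on every cell has one.
- **Chi-square.** Computed on proportions over *all* real cells,
  restricted to (not renormalized over) k = 4..9; a `renormalize` flag
  provides the alternative. A zero-denominator term with zero numerator
  contributes 0; with positive numerator the statistic is flagged
  undefined (NaN), excluded from rankings, and warned about — ranking
  on sheet 2 sidesteps empirical zeros. Ties in rankings break
  lexicographically on the setting name.
- **Pooling.** Batch censuses are pooled counts; since every experiment
  ends with exactly 2^cycles cells this coincides with averaging
  per-experiment proportions.
- **RNG.** `SeedSequence(seed).spawn(batch_size)` gives each experiment
  an independent stream; within an experiment one stream is consumed in
  a fixed order (order draw, then per cell side1 then side2), so any
  run is bit-for-bit reproducible from (config, seed).

## Validation oracle

`oracle_simulate` maintains every cell as an explicit planar vertex
list: a division inserts two midpoint vertices and splits the mother's
list; a neighbor across a cut edge has the midpoint inserted into its
own list. Side counts are list lengths; adjacency is shared consecutive
vertex pairs. The oracle replays the main simulator's logged decision
stream (mother, side1 position, u, daughter ids), so the two
implementations share decisions but derive all *consequences*
independently. The test suite checks exact agreement of per-cell side
counts and real-real adjacency over 50 seeds for all 126 strategy
combinations at 5 cycles.

## What the simulations do and do not show

Simulated tissues reproduce the topological statistics of proliferating
epithelia (polygon-class proportions, hexagon dominance, sub-6 mean).
They carry no geometry: no cell areas, vertex positions, junction
lengths, mechanical stress, or rearrangement/apoptosis events, and
divisions are perfectly synchronous in discrete cycles. Agreement of a
strategy with an empirical distribution therefore supports topological
sufficiency for early, proliferation-dominated developmental stages
only; later stages where rearrangements matter are outside the model
class. Empirical organism tables are user-supplied input (the package
ships only a clearly labeled synthetic example), so goodness-of-fit to
any real organism is a workflow, not a packaged result.

## Problem sizes and numerics

Tests run experiments at the reference condition (12 cycles, 4096
cells; one 100-experiment batch pooling 409 600 cells) and validate
distributional laws by Monte Carlo at n = 10⁵ within 4σ binomial
bands; the oracle-equivalence sweep uses 5 cycles × 50 seeds per
combination. Angular intervals and normal-CDF masses are computed in
double precision with exact endpoint handling (±π/2 forced, tan(±π/2)
mapped to CDF 0/1); pmfs are renormalized once after assembly, and a
degenerate all-zero rotation mass (possible only far outside the
supported stdbeta range) falls back to the even split.
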