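# epitopo

A topological, division-only simulator of epithelial tissue development,
with a library API, a small CLI, and chi-square machinery for scoring
simulated polygon-class distributions against empirical references.

## The problem

The cross-section of a cell in a monolayer epithelium can be treated as
a k-sided polygon. Across evolutionarily distant organisms — fly wing
disc, *Hydra*, *Xenopus* tadpole epidermis, cucumber and pimpernel
epidermis — the observed distribution of k-sided cells is strikingly
similar: hexagon-dominated, with a mean just below six sides. A highly
parsimonious class of models reproduces this "standard polygonal
distribution" from cell division alone, tracking nothing but each
cell's side count and the neighbor relation.

`epitopo` implements such a model. A tissue grows from a single cell;
every real cell divides exactly once per cycle; a division passes a
cleavage plane through two non-adjacent edges of the mother, creating
two trivalent vertices and one new shared edge. An i-sided mother cut
at counterclockwise offset u (2 ≤ u ≤ i−2) yields daughters with
u+2 and i−u+2 sides, each real neighbor across a cut edge gains one
side, and no 3-sided cells or tetravalent vertices can ever form. The
model's degrees of freedom are:

- **side1 choice** — which edge holds the first endpoint of the
  cleavage plane: `LaN`, `SmN`, `RandN` (largest / smallest / random
  neighbor), or the `Orth*` family (`OrthSmN`, `OrthLaN`, `OrthRandN`,
  `OrthBornSmN`, `OrthBornLaN`, `OrthSmpN`) that anchors the plane on
  the edge shared with the sister cell or, once the sister has divided,
  with one of the two nieces;
- **side2 choice** — the distribution of the offset u: `evensplit`,
  `random`, `unevensplit`, `Binomial`, the `Even-Binomial` mixture, and
  the rotation models `rotNorm` / `rotTanNorm` in which the plane
  pivots about the midpoint of side1 by an angle β with β (or tan β)
  normally distributed with standard deviation `stdbeta`;
- **division order** — `Random` (uniform permutation each cycle) or
  `Strict` (sister pairs divide consecutively, pairs in their mothers'
  realized order).

Fit against an empirical reference is scored per organism by

    chi2 = sum_{k=4..9} (p_sim(k) − p_emp(k))^2 / d(k)

with denominators d(k) from the empirical proportions ("sheet 1") or
the simulated ones ("sheet 2"); rankings of parameter settings use
sheet 2. The package is aimed at quantitative/systems biologists who
want a division-only null model to compare richer mechanical or
geometric models against.

## Worked example

```sh
python examples/grow_tissue.py
```

```
cycle  9  (  512 cells)  k=4: 0.039, k=5: 0.291, k=6: 0.441, k=7: 0.188, k=8: 0.039, k=9: 0.002
cycle 10  ( 1024 cells)  k=4: 0.021, k=5: 0.316, k=6: 0.425, k=7: 0.189, k=8: 0.045, k=9: 0.003, k=10: 0.001
cycle 11  ( 2048 cells)  k=4: 0.032, k=5: 0.264, k=6: 0.465, k=7: 0.196, k=8: 0.038, k=9: 0.005
cycle 12  ( 4096 cells)  k=4: 0.031, k=5: 0.264, k=6: 0.450, k=7: 0.216, k=8: 0.037, k=9: 0.003
final mean side count: 5.9739 (< 6 by Euler bookkeeping)
```

One experiment doubles the cell count every cycle (2¹² = 4096 cells
after 12 cycles) and settles into the standard shape: hexagons most
frequent (~45%), then pentagons, then heptagons, mean side count just
below 6. `examples/compare_cleavage_strategies.py` prints the side2
distributions for an 8-sided mother (the rotation strategies are more
sharply peaked at the even split than `Even-Binomial`), and
`examples/rank_against_reference.py` runs the full score-and-rank
workflow against a synthetic reference table.

The same runs are available from the shell:

```sh
epitopo simulate --order Random --choice1 OrthSmpN --smp 0.55 \
    --choice2 rotNorm --stdbeta 0.05 --cycles 12 --batch 100 --seed 42 --out runs/
epitopo chi2 --results runs/ --empirical refs.csv --out chi2.csv
epitopo rank --chi2 chi2.csv --organism Drosophila
```

where `refs.csv` is a user-supplied table with columns
`organism,k,proportion` for k = 4..9 (see
`epitopo fixtures --kind reference-table` for a synthetic example).
Output folders are named `order-choice1-choice2-param1-param2`, e.g.
`Random-OrthSmpN-rotNorm-0.55-0.05`, with `*` for unused parameters.

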