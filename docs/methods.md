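# Methods

## The model

`clonemix` simulates the growth of a tumor cell population on a fixed
2D square lattice and the spread of a single mutant subclone within
it. Each lattice site holds at most one cell, labeled wild type (WT)
or mutant (MUT); the Moore neighborhood (8 surrounding sites) defines
adjacency. The simulation starts from one WT cell at the lattice
center and stops when the population reaches `final_size`.

Events are scheduled as an exact continuous-time (Gillespie) process.
Each WT cell attempts division at rate 1 (time is measured in units of
the WT division rate), each MUT cell at rate `fitness_ratio` ≥ 1; a
`fitness_ratio` of 1 is neutral evolution. When a cell divides, one
daughter stays in place and the other is placed uniformly at random in
an empty Moore neighbor. Two variants handle the crowded case:

- **Pushing** (default): if no neighbor is empty, one of the 8
  directions is chosen uniformly and the chain of cells along that ray
  is translated outward by one position up to the first empty site,
  opening a space next to the parent. Labels travel with their cells,
  so pushing conserves the clone-label multiset exactly, and no
  division is ever blocked. A consequence worth noting: the count
  dynamics (ignoring spatial positions) are then exactly a two-type
  Yule process, which makes the neutral case an exact martingale — the
  expected mutant frequency stays at its initial value — and gives
  clean analytic cross-checks for the tests.
- **Empty-only**: a cell with no empty neighbor simply fails to divide
  (the attempt consumes a waiting-time draw but changes nothing), and
  every cell additionally dies at a fixed rate δ (`death_rate`),
  freeing its site. Whole-population extinction is possible and is
  reported as a flagged outcome, not an error. δ is a free knob with
  default 0.1 — small relative to the division rate so growth remains
  strongly supercritical.

The mutant is introduced the first time the population reaches
`arise_size`: one occupied cell, chosen uniformly, is relabeled WT →
MUT. The initial mutant frequency is therefore `1/arise_size`
(`arise_size = 100` gives the canonical 0.01). An alternative
convention — introducing several cells at a late arising time to hold
the initial frequency at 0.01 — would change the early-drift variance;
we fix the single-cell convention because a point mutation arises in
one cell.

Lattice sizing: the side defaults to `ceil(3·sqrt(final_size))`, so a
tumor of `final_size` cells (disc radius ≈ `0.56·sqrt(final_size)`)
never approaches the boundary and push chains always terminate.
Reaching the border ring anyway raises a boundary-overflow error
rather than silently wrapping. There are no periodic boundaries; the
oversized open grid emulates growth into unbounded space. Under
empty-only mechanics with death rates near criticality the colony can
random-walk over long times, so a larger explicit `side` may be
needed there.

## The mixing score

Clone intermixing is quantified by overlaying a grid of square
quadrats (side `quadrat_side` positions) on the occupied bounding box
of a clone map and averaging the binary Shannon entropy of the local
mutant fraction:

    S = − Σ_i [ p_i log2 p_i + (1 − p_i) log2 (1 − p_i) ] / n

with `p_i` the mutant fraction among tumor positions in quadrat `i`,
`0·log 0 = 0`, and `n` counting only quadrats that contain at least
one tumor position (quadrats with no tumor are dropped, since `p_i` is
undefined there). S is 1 when every quadrat is half mutant / half wild
type (fully mixed) and 0 when every quadrat is pure (fully
segregated). The quadrat grid is anchored at the top-left corner of
the occupied bounding box and partial quadrats at the far edges are
kept — a deterministic convention that survives the label-swap
symmetry test (swapping WT↔MUT leaves S unchanged).

Quadrat sizing. For simulated tumors the default side is
`max(2, round(sqrt(final_size/100)))`, which makes the occupied
bounding box yield on the order of 100 quadrats — the same order as
quadrat counts typical of annotated whole sections (~96 per case) —
and it is held fixed along a trajectory so mixing scores at different
checkpoints are comparable. For image-derived maps with a known pixel
size, `QuadratSpec.from_physical` converts a physical quadrat size to
pixels; both an area convention (default 1300 µm², side ≈ 36 µm) and a
side-length convention are supported because published physical
quadrat sizes are ambiguous between the two. Neither is asserted as
correct; the choice is a flag.

The subclone proportion is the mutant pixel count divided by the total
tumor (mutant + wild-type) pixel count; non-tumor pixels are excluded.

## Synthetic clone maps

`clonemaps.generate` fabricates two-color lesion maps with an exact
mutant pixel count (realized frequency within ±0.02 of target, exact
up to rounding) and a controlled geometry:

- `BLOB`: one compact disc — the low-mixing end;
- `STRIPED` / `INTERDIGITATED`: alternating clone bands, plain or
  interlocking, with band width set by the `dispersion` knob —
  intermediate mixing;
- `SCATTERED`: the subclone fragmented into `dispersion²` patches; at
  the maximal dispersion (10) it degenerates to single pixels placed
  by error diffusion over 2×2 tiles, so every aligned quadrat sees the
  target fraction almost exactly — the fully-mixed limit;
- `FROM_SIM`: pass-through of a simulator snapshot.

These emulate the *geometry* of manually annotated lesion maps
(internally pure clone patches on a background), not their histology:
real sections have gland-scale granularity, annotation noise, holes
and section artifacts, none of which are modeled. Tests passing on
synthetic maps therefore demonstrate correctness of the statistics and
of the inference plumbing, not robustness to annotation quality.
Color-raster input (red = mutant, yellow = wild type, per-channel
tolerance default 60/255, everything else → non-tumor) covers the
digitized-annotation path; the tolerance is deliberately generous
because hand-filled annotations are near-pure but not exact.

## ABC inference

Given an observed (frequency, mixing) pair, `abc_rejection` draws
(`fitness_ratio`, `arise_size`) from independent priors: the fitness
ratio uniform on its interval (default [1, 10]), the arising size
log-uniform on its integer interval (default [10, 2000]). The
log-uniform choice is deliberate: the physically meaningful parameter
is the clone's arrival *time*, and under exponential growth a uniform
prior on arrival time is log-uniform in the population size at
arrival; it also matches the log-scale binning of the posterior mode,
so the modal bin is unbiased with respect to the prior. Each draw
simulates **one**
realization per draw to a fixed `final_size`, computes the same two
statistics with the same quadrat side, and accepts draws whose
Euclidean distance to the observation is **strictly below** ε
(default 0.05). No re-weighting of the two components is applied —
both already live on [0, 1]. Extinct realizations count as rejected
draws and are reported separately. The point estimate is the center of
the modal bin of a 10×10 histogram of accepted draws over the prior
support, with `arise_size` binned on a log scale (its prior spans two
decades); ties break toward the smaller fitness ratio, then the
smaller arising size — a deterministic, assumption-free alternative to
kernel density estimation. Estimates are labeled by the nearest of the
canonical fitness anchors 1 / 1.75 / 3.0 / 8.0 (neutral / weak /
intermediate / strong, ties toward the lower anchor) and as
early/late arising by the geometric midpoint of the arising-size
prior.

The default inference tumor size is 2500 cells: parameter recovery is
already reliable there and one 2000-draw inference completes in a few
minutes on one core. The prior ranges and inference size are package
defaults, recorded in every result file, and should be adapted to the
tissue at hand.

Reproducibility: every replicate or draw receives an independent child
stream spawned from the master seed (`numpy` `SeedSequence`), so
results are independent of evaluation order and replaying a prefix of
the draws reproduces those draws exactly.

## Numerical and implementation notes

- The engine keeps the grid as a flat `int8` array plus per-label
  position arrays with an index map, giving O(1) cell sampling and
  removal; push chains are resolved with vectorized slice shifts, so a
  10⁴-cell realization takes ~0.5 s on one core.
- Entropy uses `scipy.special.xlogy`, which handles the 0·log 0
  endpoints exactly (the fully-mixed and fully-separated maps score
  exactly 1.0 and 0.0 in floating point, not approximately).
- Degenerate inputs: maps with no tumor positions raise a domain
  error; an all-mutant or all-wild-type map has S = 0 by the formula
  (a pure population has no mixing).
- Problem sizes in the test suite are chosen to keep the full run in
  the tens of minutes on a single core: 500 replicates for the
  neutral-drift check, 100 replicates per fitness ratio for the
  selection sweep, 2000 draws at `final_size` 2500 for the recovery
  run, 10⁵ draws for the one-step transition oracle.

## Design choices on genuinely open points

- **Transient-mixing check.** The rise-then-fall of the mixing score
  along a sweep ("low right after arising, transient peak, low again
  after takeover") is asserted on strongly selected replicates
  conditioned on fixation (final frequency > 0.95). At
  `arise_size` 100 and `final_size` 10⁴, fixation is essentially
  impossible below a fitness ratio of ~8: the Yule-process argument
  gives a wild-type count of ≈ 99·(9500/W)^(1/s) when the mutant
  reaches 9500 cells (W an Exp(1) fluctuation), which stays far above
  500 for s = 3 but drops below it with probability ≈ 0.95 for s = 8.
  Fixation-fraction ordering is still checked across all four anchors.
- **Arising-time/mixing degeneracy.** At a fixed observed frequency,
  arising time and fitness are strongly confounded (later arising
  requires higher fitness to reach the same frequency), and the mixing
  score breaks the degeneracy only weakly. The direction of the effect
  in this model is worth stating explicitly because it runs against a
  first intuition: at fixed frequency, *lower* mixing points to a
  *later*-arising clone. A late clone is observed young, while its
  pushed boundary is still compact; an early clone's boundary has
  roughened over the whole growth history. (Measured on 500
  realizations at final size 10⁴: among runs ending at frequency
  0.35–0.65, Spearman correlation between mixing score and arising
  size is −0.27.) The posterior-contrast test asserts this measured
  direction.

## Known limitations

- 2D only; no nutrient or oxygen fields, no cell migration, no
  multiple concurrent drivers — one mutant lineage against one
  wild-type background.
- The pushing variant has no cell death, so it cannot represent
  homeostatic turnover; the empty-only variant has surface-limited
  growth, so its time scale is not comparable to the pushing variant.
- ABC uses plain rejection with a single realization per draw; for
  low acceptance rates the posterior is noisy and the modal-bin
  estimate coarse (bin width ~0.9 in fitness, ~0.23 decades in
  arising size at the default 10 bins).
- Joint identifiability is weak at small inference sizes: at a fixed
  observed frequency, (fitness, arising size) trade off along a ridge
  whose summary differences are smaller than single-realization
  summary noise (frequency std ≈ 0.14, mixing std ≈ 0.11 at 2500
  cells). The accepted set reliably brackets the generating
  parameters, but the modal bin wanders along the ridge between
  repeat inferences; trusting the full accepted set (or pooling
  several inference seeds) is sounder than the point estimate.
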