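# Methods

## Model and procedure

The analysis treats extinction as independent Bernoulli events per species:
species *i* goes extinct within the horizon with probability `p_i`, obtained
by mapping its IUCN Red List category through a fixed transformation. The
shipped preset (`phyloprior/data/iucn50.json`) is the widely used 50-year
transformation — LC 0.00005, NT 0.004, VU 0.05, EN 0.42, CR 0.97 — and is
data, not code: any strictly increasing LC < NT < VU < EN < CR mapping can
be supplied instead. Data-deficient species carry no probability and are
excluded from the probabilistic indices (Expected PD-loss, HEDGE) but kept
for the purely spatial BED; extinct, regionally extinct and not-applicable
species are excluded everywhere.

Every metric is a branch sum over a materialized branch × tip incidence
table. Probability products are evaluated as exponentiated sums of logs
with explicit zero counting, so `p = 0` is exact and tiny probabilities
cannot underflow; with 12-tip enumeration oracles the implementation agrees
to < 1e-10 absolute.

**Rooting of per-cell Expected PD-loss.** A cell's loss is summed over all
branches from the cell's species up to the *regional* root, because the
quantity of interest is the loss of regional evolutionary history
represented in that cell. The alternative, summing only below the
assemblage's own MRCA, is available (`rooting="subset_mrca"`); for single
species assemblages it reduces to zero, which is why it is not the default.

**BED weighting.** The default divides each branch by the size of the union
of its descendants' ranges. The original fair-proportion-style variant,
which partitions each branch among descendants proportionally to their own
occurrence counts, is kept as `variant="occurrence_sum"`; the two differ
whenever clade members' ranges overlap. The union reading is the default
because it expresses the intended complementarity — a deep branch is
range-restricted only if *all* its descendants are confined to the same
small area.

**Polytomy grafting.** Species absent from a source phylogeny are attached
to the subtree of their congeners: at the genus MRCA with a terminal length
equal to the mean tip depth below that node (which preserves
ultrametricity on dated trees), or — for the sensitivity analysis — at a
uniformly drawn node of the genus subtree. When the attachment point is a
tip (single-member genus), the terminal edge is split at its midpoint and
the new species becomes that tip's sister.

## Null models and selection

* Risk shuffle: permute the probability vector across the scored species,
  cell composition fixed; recompute per-cell Expected PD-loss per replicate.
  An exhaustive mode enumerates all permutations on tiny pools for testing.
* Identity shuffle: for a cell of richness *k*, draw *k* distinct species
  uniformly from the regional scored pool and sum their scores,
  independently across cells and replicates.

F-values use a strict `>` ("observed higher than simulated"), so fully tied
nulls give F = 0 — e.g. when all species share one probability. Default
replicate count is 1000. Cells are ranked by F, ties broken by the raw
score, residual ties by cell id; the Aïchi rule takes the top
`round_half_up(0.17 · N)` cells (81 of 477, 253 of 1489). The rounding rule
is a package choice; the protocol source does not state one. The
alternative selection (above-mean raw value, or at least one top-decile
species, each with F ≥ 0.5) is size-free and may select more or fewer
cells than 17 %.

**Complementarity capture.** The combined hotspots' species pool is
evaluated with the same index and divided by the regional value, as a
percentage; the p-value counts equal-size random cell sets whose pooled
value is **greater than or equal to** the observed (ties favour the null,
unlike the strictly-greater F-values — the asymmetry is deliberate and
follows the protocol). Note that Expected PD-loss is *not* monotone in the
species pool: removing a safe widespread species removes its own branches
but *raises* the loss probability of deep branches it helped secure, so the
captured share can exceed 100 %. That is a property of "unique Expected
PD-loss of a species pool" itself, and worth remembering when reading
capture tables.

**Protection.** A cell is protected in the *minimum* scenario if it
intersects any protected area, in the *strong* scenario only if strictly
more than half its area is covered; both are computed for all protected
areas and for the I/II/IV management-category subset. F_PA compares the
protected proportion of hotspot cells against equal-size random sets
(strict `>`); efficiency classes are the half-open intervals
F_PA ≤ 0.25 (under-protected), 0.25 < F_PA ≤ 0.75 (as expected),
F_PA > 0.75 (over-protected). A fully tied null (e.g. complete coverage)
yields F_PA = 0 and is flagged `degenerate_ties` so it is not misread as
under-protection. Rasterizing protected-area polygons to per-cell fractions
is upstream of this package; the coverage CSV is the contract.

## Synthetic regions

The generator emulates the structural features the method is sensitive to:

* **Trees**: pure-birth (Yule), root at the first split, a final
  `Exp(λn)` stretch to the present; expected tip depth `Σ_{k=2..n} 1/(λk)`.
* **Ranges**: spreading dye — grow a 4-connected patch from a uniform seed
  cell to an exact target size (8-neighbour optional); sizes lognormal,
  clipped to the grid, median ≈ 5 % of cells — many narrow endemics, few
  widespread species.
* **Threat**: a latent severity mixes the normal scores of negative range
  size (loading `2·sin(π·ρ_target/6)`, the Gaussian-copula inverse of a
  target Spearman correlation) with a Brownian-motion trait on the tree
  (weight = the clustering parameter), then splits at fixed quantiles into
  LC/NT/VU/EN/CR (defaults: 0.55/0.14/0.12/0.11/0.08, ≈ 31 % threatened —
  deliberately Mediterranean-like). Realized threat–range correlation
  tracks the target within ±0.15 at n ≥ 100. An optional DD share is
  assigned at random.
* **Protection**: a Gaussian random field smoothed at a 2-cell scale,
  rank-uniformized and raised to `1/target − 1` so the mean coverage equals
  the target (default 0.15), with fractions below 0.005 zeroed — sparse,
  spatially clumped coverage.
* **Planted scenario** (ground truth): on a 10 × 10 grid, the first 17
  cells (a contiguous block) exclusively contain all 15 CR/EN members of a
  long-stemmed clade (crown simulated at 3× the background birth rate,
  stem extended so the joint tree is ultrametric at 1.5× the deeper crown
  depth), over 60 widespread LC background species. The Expected PD-loss
  pipeline must recover these cells; the acceptance suite requires ≥ 80 %
  recovery and observes 100 %.

All randomness flows from one root seed through named CRC-derived
substreams (`tree`, `ranges`, `categories`, `protection`, …), so each stage
is independently regenerable and whole runs are byte-identical under a
fixed seed.

What the generator does **not** emulate: real spatial autocorrelation of
assemblages beyond range contiguity, latitudinal/area gradients, coastline
and island geometry, observation error in range maps, non-independent
extinction (threats that hit whole clades or whole regions at once), and
the actual magnitudes of published capture percentages — those depend on
real phylogenies and range maps. Green tests therefore certify the
machinery (metrics, nulls, selection, overlays) and its statistical
contracts, not any empirical claim about a real region.

## Problem sizes and numerics

Default analysis sizes — 150 species on a 15 × 15 grid with 1000 replicates
for the region, 75 species on a 10 × 10 grid for the planted scenario —
were chosen so a full run completes in well under a minute on one core
while keeping ≥ 30 species per null-model pool; all statistics of interest
stabilize at these sizes. Replicate counts follow the protocol's 1000
throughout. Ties in top-species and smallest-range sets are broken by
species id, ranking ties by raw score then cell id, purely for determinism.
Zero-length branches are allowed and contribute zero to every metric; a
positive root edge is treated as a branch subtending all tips so that
PD(all tips) equals total tree length.

## Known limitations

* Extinction independence is assumed everywhere; correlated threats would
  require a joint extinction model outside this package's scope.
* GIS steps (projections, polygon rasterization, buffering of point-only
  protected areas) are out of scope; inputs are grid-level CSVs.
* The identity shuffle draws uniformly from the pool and so ignores
  range-size structure in the null, as the protocol prescribes; nulls
  conditioned on range size would be stricter.
* Capture percentages for Expected PD-loss are unbounded above (see
  complementarity note); interpret them jointly with the p-value.
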