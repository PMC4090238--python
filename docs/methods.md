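# Methods

## Model

Camper travel is represented as a first-order transition structure over
map cells.  Trip records are aggregated onto an equal-area grid
(Lambert azimuthal equal-area, spherical form, 15 km cells by default)
into a sparse travel-frequency matrix **M** with zero diagonal: trips
whose endpoints share a cell carry no between-cell dispersal and are
discarded.  Dispersal risk along a segment is taken to be linear in
trip frequency, *p_ij* = λ·*m_ij*.  λ is not identifiable from travel
data alone — only the requirement that every row of the transition
matrix sums below 1 matters for the relative ranking — so the package
sets λ = `safety` / (maximum row sum of **M**) with `safety` = 0.9.
This maximises signal subject to the constraint and leaves the
termination probability *p_i*_term = 1 − Σ_j *p_ij* ≥ 0.1 on the
busiest row.  Rows with no outgoing trips get *p_i*_term = 1: such a
cell is a destination only.

φ_ij is estimated by simulating, from each origin cell, `sims_per_origin`
independent absorbing walks.  M_ij counts walks that visit *j* at least
once (an indicator, not a visit multiplicity, which keeps φ within
[0, 1]); the origin itself never counts as visited and φ_ii is by
convention absent/0.  The per-origin normalisation M means φ rows are
comparable across origins regardless of how many origins are simulated.
Walks also carry a hard 10,000-step cap; with row sums ≤ 0.9 the
expected walk length is below 10 steps and the cap is unreachable in
practice, but it is counted and reported if a misconfigured model ever
hits it.

The Monte Carlo estimator has an exact counterpart: the probability
that a walk from *i* ever visits *j* solves
h(k) = p_k,j + Σ_{l≠j} p_kl·h(l), a sparse linear system that is
strictly diagonally dominant (row sums < 1) and therefore non-singular.
The implementation solves it with a sparse LU factorisation and uses it
as an independent oracle for the simulation in the test suite; the two
agree within binomial error across random networks.

### Random-number contract

Every origin draws from `numpy`'s PCG64 seeded with the pair
(seed, origin cell id), so per-origin results are independent of the
order in which origins are processed and identical inputs give
identical risk matrices.  The batch simulator advances all walks from
one origin in lockstep, resolving each step's draws with a single
searchsorted over a row-shifted cumulative-probability array; a
separate scalar path simulator exposes individual itineraries.

## Preprocessing choices

* **Seasonal window.** Flight seasons vary geographically, but the
  geographic estimation behind published season maps is not
  reproducible from available material.  The default season model is a
  single start date with a 10-week window applied everywhere, with a
  `start_fn` hook taking (lon, lat) for per-location start dates.  The
  window is half-open (inclusive start, exclusive start + 70 days) so
  adjacent windows compose without double counting.  A trip is kept
  only if its date is in season at both endpoints.
* **Low-frequency drop.** Pairs with fewer than 4 trips are dropped at
  the raw point-pair resolution before aggregation by default (that is
  where the computational pressure that motivates the filter arises); a
  `low_freq_level="cell"` switch applies it to aggregated cell pairs
  instead.
* **Return segments.** m_ji += 0.15·m_ij computed from the input
  weights only (no cascading), applied after aggregation.  Weights stay
  fractional: they feed probabilities, not counts.
* **Grid.** Row-major integer cell ids from the lower-left corner of a
  projected bounding rectangle.  The projection is spherical LAEA
  centred on the data extent; any equal-area choice preserves the
  cell-size semantics.

## Synthetic trip generator

The generator emulates the statistical structure of campground
reservation data rather than any real geography: population centers
from a Thomas-style cluster process with lognormal (σ = 1) trip
propensities; campgrounds part-clustered, part-uniform with lognormal
(σ = 1.5) popularity so a few sites dominate (max/median ratio well
above 10 at the default 200 sites); origins carry a few fixed
"postal-code" sub-points so raw coordinate pairs repeat across trips as
they do in reservation records.

The one-way trip-distance distribution is a lognormal kernel whose
(μ, σ) are solved in closed form from two quantile constraints,
P(D ≤ 100 km) = 0.5 and P(D ≤ 500 km) = 0.9, giving μ = ln 100 ≈ 4.605
and σ ≈ 1.256.  A trip draws its origin center weight-proportionally
and its campground with probability ∝ popularity × β(d), where the
per-distance-bin factors β (25 km bins) are calibrated by iterative
proportional fitting until the predicted marginal distance mass per bin
matches the kernel, renormalised to the distances the landscape
actually offers.  This is what ties the marginal distribution to the
kernel on a *discrete* landscape: evaluating the kernel density alone
would confound it with the geometry of available sites.  Distances are
great-circle; no road routing is attempted.

What the generator does *not* emulate: road-network travel times,
party-size variation (every record is one trip), multi-night
re-booking, or the true spatial layout of any state.  Tests passing on
synthetic data therefore demonstrate correctness of the pipeline and
its statistical calibration, not predictions about a real jurisdiction.

### Fixture scenarios

Three small bundles reproduce the qualitative origin-risk archetypes
seen at the jurisdiction level, on a fictional region with a target
"state", an adjacent origin block, and a distant urban hub ~1,100 km
away: `two_state_local` (≈90% of trip-generation weight adjacent →
origin-risk mass concentrated next door), `hub_and_spoke_distant`
(weight concentrated in the hub → the top-ranked origin cell is a
distant hotspot above the 10⁻⁴ class threshold), and `mixed`.  Default
size is 4,000 trips over ≤ ~60 network cells, which keeps a full
pipeline run under a second while leaving dozens of populated cells.

## Numerical choices

* Conservation p_i_term + Σ_j p_ij = 1 holds to 1e-12 by construction
  and is validated explicitly.
* Profile sorting breaks ties by ascending cell id, so outputs are
  deterministic.
* The hotspot label uses a strict inequality at the 10⁻⁴ threshold;
  zero-valued cells are absent rather than labelled.
* Jurisdiction summaries accumulate integer walk tallies before the
  single division by M, making the identity with summed reverse
  profiles exact rather than float-order-dependent.
* Risk-map CSV exports write `repr` floats, so a read-back reproduces
  values bit-for-bit.
* Cell membership in a polygon jurisdiction is decided by the cell
  *center*, so non-overlapping polygons induce a disjoint cell
  decomposition.

## Problem sizes

The test suite's oracle study uses 20 random networks of 10–50 nodes at
100,000 walks per origin; the calibration checks draw 100,000 trips;
fixture pipelines simulate 5,000 walks per origin.  These sizes give
binomial standard errors of ~1.6e-3 or better on individual φ values
while keeping the whole suite in the tens of seconds on one core.

## Known limitations

* λ is relative: φ ranks locations, it is not an absolute probability
  of pest transport, and no species-specific establishment model is
  included.
* The 0.15 return fraction rests on a single regional survey of
  unburned-firewood behaviour; it is exposed as a parameter.
* The equal-likelihood assumption (every camper equally likely to carry
  infested wood, in equal quantity) is inherited from the model
  formulation.
* Season starts in the default model do not vary geographically unless
  a lookup is supplied.
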