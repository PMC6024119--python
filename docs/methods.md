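# Methods

## Data model

The analysis operates on three plain-text tables: long-format presence
records (one `(species_id, unit_id)` pair per row), a planning-unit
table (stratum, land area in hectares, PA coverage fraction, optional
per-year coverage columns), and a species table (taxon group,
threatened / nationally-protected / endemic flags, region). Presence is
strictly binary — a record exists or it does not — and duplicated pairs
are collapsed with a logged count rather than rejected, because
herbarium-derived compilations routinely duplicate records. Every
species in an `IncidenceMatrix` occurs in at least one unit by
construction; species listed in the attribute table without presence
records are retained and flagged by `cross_validate`.

`pa_present` defaults to `pa_coverage > 0` but can be overridden by an
explicit column: PA registries record some areas only as points, which
establish presence without a mappable coverage. When a PA spans several
units without a published per-unit breakdown, `allocate_pa_area` splits
its area evenly across them; contributions of overlapping PAs add, and
the sum is capped at the unit's land area (coverage 1.0) with a warning
at coverage-computation time.

## Complementarity and greedy selection

The pairwise score is `C_jk = 1 − V_jk / S_jk` with
`S_jk = S_j + S_k − V_jk`: 0 for identical species sets, 1 for disjoint
ones, undefined (an error) when both sets are empty. During selection
the score of a candidate unit is computed against the **pooled** species
union of the current set, treating the set as one composite site; this
is the reading under which "add units until the set covers all species"
is meaningful. The pairwise-minimum alternative is not implemented.

Selection is staged: the seed is the unit of greatest richness within
the target universe; stage one covers the priority class (nationally
protected or threatened species), stage two the remainder. Stage scores
and coverage bookkeeping are restricted to the stage's species class,
but a selected unit's *other* universe species enter the covered ledger
immediately — a unit chosen for its threatened species also contributes
everything else it holds. Candidates contributing no uncovered species
of the current stage are ineligible: under the raw score a small,
fully-covered unit can outscore units that still add species
(1 − 1/|pool| approaches 1), and the loop would stall short of full
coverage.

Two selection modes are provided because the score-maximising rule and
the classic richness-gain greedy ("most species not yet covered")
describe the same procedure from different angles and genuinely differ
on some instances. The default is `complementarity_score`;
`new_species_count` is a config flag. Ties are broken by total species
richness (the unit's full species count), then lexicographic
`unit_id` — the last tie-break is invented solely to make runs
deterministic, and the trace is a pure function of inputs and config.

Greedy set cover is not optimal; an exhaustive minimum-cover search
exists in the test suite as an oracle (instances ≤ 12 units) but never
in the product path. No cost, connectivity or boundary-length terms are
modelled.

## Representation, gaps, and summaries

`I_E = a/(a+b) × 100` with `a = |CS ∩ S_P|`. Threshold comparison is
inclusive (coverage ≥ t). Percentages are computed on exact rational
counts and rounded half-up only at presentation (one decimal; integer
for the congruence count panels), so printed values are bit-exact
reproducible. `I_E` is non-increasing in the threshold, and the
presence-criterion value bounds all positive-threshold values.

Two uncovered-species definitions are provided and neither is
privileged: `rangewide` (default) lists universe species with zero
occurrences in any protected unit — "not covered by existing PAs" read
literally — while `cs_only` lists species whose occurrences within the
CS fall entirely in gap units. Neither set contains the other in
general: a species can be rescued range-wide by a protected non-CS unit
(`cs_only` only), or protected inside the CS yet absent from every
protected unit of some other region.

Congruence percentages use the union of the CS and the PA-present unit
set as denominator, in counts and in area. Coverage classes are
half-open `[lo, hi)` between the configured edges with a distinguished
exact-zero class (no PA at all) and a final class closed at 1; class
counts sum to |CS| and area percentages to 100.

Regional effectiveness counts a region's species as captured only when
it occurs in a CS unit located in that region (capture in situ, not by
proxy sites elsewhere); the mean and sample standard deviation (ddof 1)
are taken across the emitted region (× taxon group) cells. The time
series applies the single-year selection + index path per year; no
monotonicity is enforced, since PAs can be downsized or degazetted.

## Stratified bootstrap

Within each stratum of size n, `round-half-up(fraction × n)` units
(minimum 1) are drawn uniformly without replacement; the minimum keeps
every environmental stratum represented, and the rounding rule is a
package choice where convention is silent. Sampling is of planning
units, not of presence records. Species losing all occurrences in a
subset drop from that replicate's universe rather than failing it —
subsets necessarily lose narrow-range species, and a CS is still built
on what remains. A replicate with an empty universe is recorded as
failed and excluded from means.

Each (fraction, replicate) cell gets an independent RNG substream from
`SeedSequence(seed, spawn_key=(fraction_index, replicate_index))`, so
the replicate table is deterministic given the config and extending the
replicate count preserves earlier draws (a 200-replicate run is a prefix
of a 1000-replicate run). At fraction 1.0 the subset is the full data
and every overlap is exactly 1.

## Synthetic data

Defaults are a desk-scale emulation of a national six-taxon county
database: 240 units in 8 strata; species per group
`{woody_plant 416, fern 92, amphibian 16, reptile 18, bird 55,
mammal 24}` (group proportions of a realistic national checklist at
~1/25 scale; units at ~1/10); per-group threatened fractions patterned
on national red-list ratios (woody plants 0.143, ferns 0.064,
amphibians 0.433, reptiles 0.300, birds 0.107, mammals 0.264);
nationally-protected fraction 0.10 and endemic fraction 0.35 flat.

Occupancy is truncated log-series (p = 0.98, mean ≈ 12 units) by
default — CS behaviour is driven by rare species, so the heavy
narrow-range tail is the load-bearing feature — with a lognormal
alternative for sensitivity work. Each species has a home stratum
holding ~`range_cohesion` (default 0.8) of its range, always including
at least one home occurrence, the remainder uniform elsewhere; for
species whose range outgrows the home stratum the home share saturates
at the stratum size. Threatened, protected and endemic flags are drawn
without replacement with weights `occupancy^(−bias)`, rank-correlating
threat with narrow range at exact configured counts. PA coverage is
zero for 30% of units (the observed share of counties without PAs in
national registries of this kind) and Beta(1.1, 8) otherwise — mostly
below 10%, occasionally high. Unit areas are lognormal around
~3×10⁵ ha. Strata double as regions unless callers supply separate
assignments.

What the generator does **not** emulate: spatial contiguity and
coordinates, survey-effort gradients, taxonomic error, and
co-occurrence structure beyond shared strata. Passing tests on this
data therefore demonstrate algorithmic correctness and the qualitative
behaviour of the statistics, not calibrated national-scale values.

Planted fixtures build k blocks whose designated units each solely hold
one single-site endemic (threatened in the fixture's species table), so
the unique minimal cover is exactly the k designated units; decoy and
extra units carry only already-covered species. The manifest records
the ground truth for tests. The yearly-coverage generator produces
constant, monotone (zero until a random establishment year, then a
rising ramp ending at today's coverage) or degazettement regimes (each
yearly transition decreases with the configured rate).

## Numerical and scale choices

Problem sizes in the test suite and examples (≤ 240 units, ≤ 650
species, 500 random greedy instances at ≤ 12 units, bootstrap at 200
replicates on planted fixtures) were chosen so the whole suite runs in
seconds while every property is exercised at a size where brute-force
oracles are exact. Rounding of presented percentages is half-up via
decimal arithmetic on exact rationals. All randomness flows from
explicit seeds: `SimulationConfig.seed`, `BootstrapConfig.seed`, or the
RNG handed to `stratified_sample`.

## Known limitations

- Greedy covers are not minimum covers; reported CS sizes are upper
  bounds on the true minimal representative footprint.
- All PAs are treated as equally and fully effective; management
  quality, partial habitat overlap within a unit, and species-specific
  area requirements are out of scope, so representation is likely
  overestimated relative to ecological reality.
- "Location" is an attribute, not geometry: no spatial adjacency,
  connectivity, or map output.
- Point-only PAs contribute presence (via the `pa_present` override)
  but zero coverage.
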