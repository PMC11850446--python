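# Methods

## Scope and assumptions

`fwb` implements static mass-balance trophic modelling: every functional
group's production and consumption are balanced over a reference period
(one year, g/m² wet weight and g/m²/yr throughout).  The model assumes

* steady state up to explicit biomass accumulation (`BA`) and net migration
  (`NM`) terms — both default to 0 when absent;
* a closed diet bookkeeping: each consumer column of the diet matrix plus
  its diet-import fraction sums to 1;
* detritus is a donor pool, not a producer: it has no P/B, and its
  ecotrophic efficiency is *derived* as outflow (consumption of detritus)
  over inflow (unassimilated consumption + unutilized production + external
  import).  With several detritus pools, internal flows to detritus are
  split equally among them; external imports are per-pool.  A single pool
  is the canonical configuration.

## Solving the balance

For living groups the production balance is linear once each group carries
exactly one unknown among {B, EE}.  Rows with unknown biomass form a square
system solved with a dense LU factorization; the remaining rows then give
each unknown EE directly as (catch + predation + net migration +
accumulation) / production.  A producer with no mortality sinks gets
EE = 0; production 0 with positive sinks is reported as infinite EE.
Solver failures (a group with zero or two unknowns, a singular system, a
negative solved biomass) raise with the offending group names.  EE > 1 is
*not* an error: it is returned as-is and flagged by the diagnostics, because
the balancing workflow is inspect-then-adjust.

Consumer budgets follow from the energy balance: R = Q(1 − UC) − P,
GE = P/Q, RA = R/(Q(1 − UC)), PR = P/R (nan when R = 0).  Producer
respiration is an optional measured input (default 0).  The diagnostic
screen applies the classical plausibility rules — 0.1 < GE < 0.3,
GE < net efficiency, RA < 1, PR < 1 — to consumers only; a
producer-dominated system violates PR < 1 trivially, so producers are
exempt.  Negative respiration is flagged, not raised.

## Diet auto-adjustment

When prey *i* ends with EE > 1, every diet entry DC[i, j] > 0 is multiplied
by `1 − step·overshoot` with `overshoot = min(1, (EE−1)/EE)` and the freed
fraction is redistributed proportionally among predator *j*'s other prey
that are not themselves over-consumed (to detritus when there are none, and
to the diet import as a last resort).  Defaults: step 0.1, at most 100
iterations.  Two numerical points:

* the multiplicative update shrinks the excess (EE − 1) by roughly a factor
  (1 − step) per iteration, i.e. it approaches EE = 1 geometrically *from
  above* and cannot cross it in finite steps.  Convergence is therefore
  declared at EE ≤ 1 + `ee_tol` with `ee_tol = 1e-3`; from EE ≈ 3, 100
  iterations leave about 3·10⁻⁵ of excess, so the tolerance is comfortable.
* redistribution necessarily increases predation on the receiving prey, so
  no update rule of this family can guarantee that every EE is non-increasing;
  restricting the targets to non-over-consumed prey removes the pathological
  case of two over-consumed prey swapping weight through a shared predator,
  which otherwise stalls convergence.

## Trophic levels, omnivory, Lindeman spine

Fractional trophic levels solve TL_j = 1 + Σ_i DC_ij TL_i with producers
and detritus pinned at 1; diet imports contribute prey material at TL 1.
The linear system handles cycles and cannibalism; a diet with no external
anchor (a pure cannibal) is singular and raises.  The omnivory index is the
diet-weighted variance of prey TLs around TL_j − 1; the system omnivory
index averages OI over consumers weighted by log(Q), restricted to
consumers with Q > 1 so the log-weights stay positive.

The Lindeman spine apportions each consumer's intake over discrete levels
by diet path length: the fraction of group *g* acting at level k+1 is the
diet-weighted sum of its prey's fractions at level k, seeded by producers
and detritus at level I.  Producer-origin and detritus-origin chains run
through the same recursion separately (diet imports count as producer-origin
level-I material, which keeps the spine mass-conserving) and are also
reported combined.  The recursion is capped at 8 levels; consumption not
apportioned within the cap (possible only with deep cycles) is reported as
a remainder.  Within every level, inflow decomposes exactly into flow
upward (predation), export + catch (+ accumulation), respiration and flow
to detritus.  The unconsumed detritus surplus is booked as level-I
export/accumulation so level I balances; it is excluded from the level-I
transfer efficiency.

TE_k = 100 · (flow k→k+1 + export & catch at k) / inflow at k.  The *mean*
TE is the geometric mean over levels II–IV (configurable range, arithmetic
option available).  Undefined levels (no inflow) are excluded; so are
zero-TE levels, because a top level that simply has no predators would
otherwise pin the geometric mean of the whole chain at exactly 0 and erase
the signal of the levels that do transfer — published per-zone mean TEs
remain positive in systems whose level IV transfers nothing, which is only
consistent with excluding structural zeros.

## System indices

TST = consumption + exports + respiration + flows to detritus.  TPP sums
producer production; TB excludes detritus; ratios are computed from
unrounded values and formatted by precision class in the reporting layer
(flows as integers, TPP/TR to 2 decimals, TB/TST to 4, A/C to 1).

Cycling uses the compartment network *including* detritus pools (flows to
detritus are real transfers): G[i,j] = flow i→j over total inflow of j,
L = (I − G)⁻¹, cycled throughput per compartment = inflow·(L_ii − 1)/L_ii,
FCI = 100·Σ cycled / TST.  The "excluding detritus" variants delete
detritus nodes and their incident flows (flows formerly received from
detritus become boundary imports) and capture predator-mediated cycling
only; the predator cycling index is the FCI analogue on that reduced
network with TST recomputed without detritus flows.  FML = TST/(exports +
respiration); straight-through path lengths subtract the cycled throughput
from the numerator.  Connectance counts realized diet links of living
consumers (including detritivory) over N_living·(N_living − 1).  Shannon
diversity is computed on living-group biomass shares by default (flow-based
variant behind a flag).

Ascendency and capacity are computed on the extended flow network (boundary
compartments appended for imports, exports and respiration) in log2 units
("flowbits"): A = Σ T_ij log2(T_ij·T‥/(T_i·T_·j)), C = −Σ T_ij
log2(T_ij/T‥); zero flows contribute nothing.

## Trophic impacts and keystoneness

The direct impact of i on j is the prey share minus the predation share:
DC(prey = i, predator = j) − [predation by i on j] / [total predation on j].
Detritus as an "impacted consumer" uses its normalized inflows as a diet
column.  Total impacts are M = (I − q)⁻¹ − I; when the spectral radius of q
is below 1 this equals the Neumann path sum Σ_{n≥1} qⁿ, and the closed form
analytically extends it through the strongly-coupled case (isolated
predator–prey pairs sit exactly at radius 1); only a singular I − q raises.
Keystoneness follows the overall-effect formulation:
ε_i = √(Σ_{j≠i} m_ij²) over living impacted groups,
KS_i = log10(ε_i · (1 − p_i)) with p the living-biomass proportion
(detritus carries no biomass share), and the relative total impact is
ε normalized by its maximum.

## Uncertainty

The pedigree index is the unweighted mean of per-parameter confidence
scores over living groups.  The Monte Carlo resampler perturbs each scored
parameter (B, P/B, Q/B, Y, DC) with a normal relative error, truncated to
positive values by resampling (at most 100 draws, then clamped); diet
columns are clipped to [0, 1] and renormalized to their internal share.  A
run is accepted when the balance solves, every living EE ≤ 1 and the
physiological screen holds (each constraint can be switched off).  Of the
accepted runs, the `n_keep` with the smallest sum of squared standardized
deviations from the base inputs are kept — "best-fitting" is not further
specified in the tradition this follows, so closest-to-base is a documented
interpretation.  Defaults are 10,000 runs keeping 200.  Randomness flows
from one integer seed through per-run substreams derived from the run
index, so results are bit-reproducible and independent of evaluation order.
Note that constraint-based acceptance truncates the sampled distributions
asymmetrically (e.g. a prey near EE = 1 biases its predator's accepted Q/B
downward); unbiased coverage of generating parameters is only expected with
screening off.

## Synthetic webs

The generator emulates the structure of subtropical-river models: one
detritus pool; phytoplankton, periphyton and macrophytes as low-standing-
stock, high-turnover producers (e.g. phytoplankton B 1.5–4 g/m² with P/B
150–250/yr); invertebrate guilds (rotifers, copepods, gastropods, bivalves,
shrimp, annelids) and fish feeding guilds stacked over levels 2–4 with an
apex soft-shelled reptile.  Consumer biomass is dominated by level II
(25 g/m² by default) and declines by a 0.25 decay factor per level; diets
are Dirichlet draws over the guild's permitted (strictly lower-level) prey;
gross efficiencies are drawn inside (0.1, 0.3); unassimilated fractions are
0.4 for detritivores/herbivores and 0.2 for higher consumers.  Total demand
on every living prey is capped at 90% of its production, with the excess
diet rerouted to detritus — which both guarantees solvable webs with all
EE ≤ 0.9 *known in advance* and reproduces the dominance of detritivory
seen in disturbed lowland rivers.  The detritus pool receives an external
import only if detritivore demand would otherwise overdraw it.  Everything
is deterministic given the recipe seed.  Generated webs are acyclic among
living groups (cycles run only through detritus), have no fishery, no
migration, no seasonality and no age structure; tests passing on them show
the machinery is exact under those conditions, not that real webs satisfy
them.

Disturbance scenarios: *industrial* removes consumers with fractional
TL > 2 + intensity and multiplies detritivore biomass by (1 + 4·intensity);
*overfishing* adds catch Y = intensity·P to the top TL quartile; *invasion*
inserts a high-biomass exotic detritivore (biomass = intensity × total
consumer biomass, GE 0.2, UC 0.4) that nothing preys on.  A caveat worth
stating plainly: because a detritivore's unassimilated and unutilized
production returns to the detritus pool it feeds from, boosting or adding
detritivores *increases* Finn's cycling — the invasion scenario raises FCI
monotonically even as it lowers the mean transfer efficiency.  Observed
cross-site orderings in which degraded, detritivore-dominated reaches also
show the lowest FCI must therefore arise from differences these two
mechanisms do not capture (lost diversity, shorter webs, smaller consumer
stocks), and the package makes no claim that FCI falls under these
scenarios.

## Numerical choices and problem sizes

* Diet-column normalization: exact to 1e-6; columns off by ≤ 1e-3 are
  renormalized with a warning (hand-rounded field tables); worse is a
  validation error.
* Solver exactness is verified to residuals < 1e-9 of the largest
  production; ground-truth EE recovery on generated webs is tested to
  1e-12 relative over 20 seeds at 16 groups.
* Oracle equivalences (impact matrix vs Neumann sum, Leontief cycling vs
  power-series path enumeration) are tested to 1e-10 on 100 random webs of
  ≤ 8 groups whose impact spectral radius is below 0.95, so series
  truncation error stays well under the tolerance.
* Monte Carlo calibration uses 20,000 runs against a closed-form
  normal-tail acceptance probability (two binding bounds: prey EE ≤ 1 and
  predator GE > 0.1… < 0.3), asserted within 3 binomial standard errors.
* Unset values are `None`/empty-cell, never 0; serialization round-trips
  floats via `repr` (exact for IEEE doubles).
* Group order is canonical (file order); all indices are invariant to
  reordering, which is under test.

## Known limitations

* One currency (wet-weight energy proxy); no nutrient co-limitation or
  multi-currency balance.
* No temporal dynamics: scenarios are comparative statics on the balanced
  state.
* Solving is restricted to {B, EE} unknowns; P/B or Q/B estimation from
  regressions is out of scope.
* Keystoneness implements the overall-effect (Libralato-type) variant only.
* The "excluding detritus" cycling variants depend on how the reduced
  network's boundary is defined (documented above); published tables do not
  state their convention, so cross-implementation differences of a few
  percent are expected for those rows.
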