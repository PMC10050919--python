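# Methods

## The world

Agents live on a bounded `grid_rows × grid_cols` rectangle (default 20×20)
with Moore (8-cell) neighbourhoods, clipped at the boundary; any number of
agents may share a cell, and co-occupancy is the elementary social event.
Each of the `n_agents` (default 100) initial agents gets a uniform-random
cell, a uniform-random age from 0–100 time steps (ages are counted in steps,
not years; the spread prevents synchronized die-offs under the demographic
condition), a fair-coin phenotype (`hybrid_like` / `common_like`), and
non-tool-user status — except one seed agent, a hybrid-like tool user of age
25. Agents of developmental age (`min_acquisition_age` = 25 steps or
younger) can never be tool users; the threshold mirrors the multi-year
developmental window observed for the real skill.

Each time step, living agents act in a freshly randomized order (avoiding
id-order artefacts). An agent ages by one step, moves, then applies its
condition's rule; state changes take effect immediately, so an agent that
becomes a tool user mid-step can influence others from the next step on.
After all agents have acted, every unordered pair sharing a cell is appended
to the association log (a cell with *k* occupants contributes *k(k−1)/2*
records), and the stopping rule is checked: the run ends when tool users
reach `stop_fraction` (default 0.5) of the population. The denominator is
the **initial population size** by default (`stop_denominator="initial"`);
under the demographic condition the living population grows and shrinks, and
measuring against the fixed initial size is what lets runs terminate during
the growth phase, while the initial cohort still lives. The alternative
(`"living"`) is available; it makes demographic runs terminate only after
near-complete population turnover. `max_steps` (default 20 000) bounds
non-terminating parameterizations; hitting it is flagged in run metadata,
never raised.

Identical `SimConfig` values (including `rng_seed`) give bit-identical
association logs; all randomness flows through one `numpy` Generator.

## Transmission conditions

**Social learning.** A naive agent entering a cell with tool users
increments its encounter counter by the number of tool-using co-occupants,
then (if past the age gate) acquires with probability
`min(1, social_increment × encounters)` — 1 % per accumulated encounter by
default, a rate chosen to echo the years-long associative learning of the
real skill. Encounters accrue at any age; only the acquisition trial is
age-gated.

**Genetic inheritance.** Adds demography. Each step an agent first risks
death with probability `death_baseline + death_age_coeff × age`
(defaults 1e-4 and 1e-5; at the maximum initial age of 100 the per-step risk
is 0.0011, keeping death rare but age-structured). Reproduction triggers on
co-occupancy: a moving agent sharing a cell picks a random co-occupant and,
with probability `reproduction_p` (default 0.05), produces an age-0
offspring at the same cell — provided both parents are past the
developmental age (juveniles neither use tools nor breed) and the living
population is below `population_cap` (default `2 × n_agents`). Matching
parental phenotypes pass on unchanged; mixed pairs flip a fair coin. The
tool-use trait rides the phenotype: a hybrid-like offspring carries the
trait from birth but expresses it — and counts toward the stopping rule —
only after passing the developmental age; a common-like offspring never
carries it. An optional stricter rule (`inherit_requires_tool_parent`)
additionally demands a trait-carrying parent, confining the trait to the
seed's lineage; it is off by default because the lineage-restricted trait
behaves like a quasi-neutral allele seeded at 1 % — it usually drifts
extinct and the stopping rule rarely fires. Offspring record one parent
(chosen at random) as mother and, while young, preferentially step toward
her: with probability `1 − 2·age/100` (clamped to [0, 1] — certain at birth,
gone by age 50) they pick the neighbouring cell minimizing Euclidean
distance to the mother, ties broken uniformly.

**Asocial acquisition.** Every eligible naive adult independently acquires
with probability `asocial_p` (default 5 %) per step, so runs are short.
`n_attractors` fixed resource sites (1, 10 or 200 in the sweep design) are
placed uniformly at random; each step a tool user, with probability
`attractor_pull` (default 25 %), steps toward the nearest attractor
(choosing among its neighbours and its own cell the one minimizing distance)
instead of moving randomly. With one attractor, tool users drift together
and associate; with 200, attractors blanket half the grid and the spatial
signal dilutes.

### Demographic parameter rationale

The transmission rates, death rates, grid, population size, age gate and
stopping fraction are fixed study conditions. Reproduction probability and
the population cap are not externally specified; they were set once on
mechanism grounds: the cap at twice the initial population so a growth phase
exists at all (a cap equal to the initial size would let births occur only
after deaths, contradicting the design intent that death stays a minor
force), and `reproduction_p = 0.05`, which at observed co-occupancy rates
gives an adult roughly 4–5 offspring over a typical lifespan — ordinary
primate fecundity — and demographic runs of a few hundred steps, long
enough for offspring to mature and for ageing to matter, short enough that
much of the initial cohort survives to termination.

## Networks and metrics

Association records — simulator logs (`step, agent_a, agent_b`, unordered)
or observational focal-follow rows (`focal, partner[, count]`, directed from
the active forager to the individual within 1 m) — are collapsed to pair
counts and built into a `networkx` graph whose nodes carry the attribute
table (isolates included). Requesting a directed graph expands each
unordered simulator pair into both directions at the pair's count;
requesting an undirected graph sums opposite observational directions.

**EV-centrality** is the dominant eigenvector of the weighted adjacency,
computed by power iteration to a 1e-10 update tolerance and rescaled so the
maximum is 1. Directed input is symmetrized (sum of both directions) first:
eigenvector centrality on weakly connected digraphs is ill-conditioned, the
simulator's associations are inherently symmetric, and one score per
individual is wanted. A small diagonal shift (1 % of the largest row sum)
breaks the ±λ tie that would make plain power iteration oscillate on
bipartite components; the shift leaves eigenvectors unchanged. Disconnected
graphs are scored on the largest connected component, everyone else gets 0
with a warning; an edgeless graph scores all zeros.

**Strength to tool users** sums the weights of a node's edges whose other
endpoint is a tool user (self excluded by the no-self-loop construction).
Directed graphs are symmetrized first so each unordered relation counts
once, keeping simulator and observational inputs on one scale.

## The status model

One Bernoulli observation per individual with a logit link; four groups from
age class (developmental = at or below the acquisition threshold, or an
explicit maturity flag for observational data) × phenotype, each with an
intercept and slopes on centrality and strength: 12 parameters. Predictors
are rescaled to [0, 1] by dividing by the observed maximum — not z-scored,
because the positive (lognormal) slope priors encode "more connection can
only help" and signed standardized predictors would distort that
monotonicity at the low end. A zero-variance predictor is left unscaled with
a warning. Priors: Normal(0, 1) intercepts; LogNormal(0, 1) slopes,
implemented by sampling log-slopes with a Normal(0, 1) prior, which keeps
the parameter space unconstrained.

Sampling uses `emcee` with differential-evolution and snooker moves: the
default stretch move mixes poorly on this 12-dimensional correlated
posterior (integrated autocorrelation ≈ 200 steps vs ≈ 60). Because walkers
within an ensemble interact, convergence cannot be judged by treating
walkers as independent chains; `fit_model` therefore runs `chains` (default
4) fully independent 24-walker ensembles from distinct seeds, computes Rhat
across ensembles (walkers pooled within each) and effective sample size
across every walker's thinned path (default: 2000-step warmup, then 1000
kept draws per walker at thinning 4). Defaults reach ESS in the thousands
and Rhat ≈ 1.003 on typical simulator output; Rhat > 1.01 or ESS < 400 is
flagged in metadata and warned about, not raised. The ensemble sampler has
no divergence diagnostic; the mean acceptance fraction is reported instead.
Complete separation (e.g. no developmental tool users, the normal case) is
handled by the priors, which keep those intercepts finite and low.

Summaries report, per parameter, the posterior mean, sd, 5.5 % and 94.5 %
quantiles, ESS and Rhat, in a fixed 12-row table keyed like
`intercept (DA, common like)` … `strength (adult, hybrid)`. Posterior
predictive curves sweep one predictor over [0, 1] while holding the other at
its group mean, reporting the mean and 89 % band of the inverse-logit
response per grid point.

## Batch experiments

`run_condition_batch` runs `n_iterations` (design: 30) simulations with
seeds `base_seed + i`, builds each iteration's undirected network, and
summarizes class means among **living adult** agents — matching the
model's eligibility logic; all-ages and per-iteration variants of the
pooled statistics are available through flags. Cross-iteration statistics:

- `exceedance_fraction` — share of iterations where adult tool users' mean
  (strength or centrality) strictly exceeds adult non-tool users';
  iterations missing a class are excluded and counted.
- `phenotype_tool_rate` — pooled share of living adult agents of one
  phenotype holding tool-user status (pooled across iterations by default).
- `centrality_gap` — mean per-iteration difference of adult class means.
- `permuted_exceedance` — the same exceedance after shuffling tool-user
  labels among living adults and recomputing strength against the permuted
  labels; a label-permutation null that should sit near 0.5.

## Synthetic observational data

`generate_observational` emulates one focal-follow season: `n_individuals`
(69) with `n_mature` (42) mature animals, exact attribute counts (half the
mature are tool users; immatures are never tool users), and exactly
`n_scans` (5990) directed records. Each scan draws a uniform focal and a
partner from a categorical distribution in which a tool-using focal's odds
of picking a tool-using partner are multiplied by `exp(assortativity)`.
That log-odds tilt is deliberately minimal plumbing — it plants the
association signature that social transmission leaves in real data
(tool users bound to tool users) so the network and inference stages can be
validated end to end; it does not model behaviour, seasons, tides, bout
structure or individual identity, and a zero tilt gives exchangeable
partners (a built-in null).

## What the simulations do and do not show

Passing tests demonstrate that the three mechanisms leave distinguishable
signatures in *simulated* association networks under the stated rules —
grid-world movement, co-occupancy as association, a single seeded skill —
and that the statistical pipeline recovers parameters from data generated by
its own model. They do not validate the rules as descriptions of macaque
behaviour, and real observational data add measurement structure (focal
sampling effort, visibility, tides, kinship) that neither the simulator nor
the generator emulates. Cross-iteration percentages computed from 30
iterations carry binomial noise of roughly ±8 points; small differences
between such percentages are not meaningful at this design size.

## Numerical and degenerate-input choices

- Distance comparisons use exact integer squared Euclidean distances; ties
  among minimizing cells are broken uniformly at random.
- Directed movement candidate sets include the current cell, so an agent
  already at a target stays (keeping distance 0) rather than being forced
  off it.
- The power iteration starts from the uniform vector, runs at most 10 000
  iterations, and takes absolute values before max-normalizing.
- Empty networks, edgeless networks, missing classes in an iteration, and
  all-one-class outcomes are reported (warnings, NaNs with counts, or
  explicit errors) rather than silently dropped.
- Dead agents are removed from the grid immediately: they never move,
  reproduce, acquire, or appear in later association records; their final
  attributes stay in the exported table with `alive=False`.
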