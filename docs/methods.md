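# Model and methods

This note documents the model implemented in `nksocial`, the defaults it
ships with, the numerical and design choices that were genuinely open, and
what the desk-scale experiments do and do not show.

## Task environment

The task is search on an NK fitness landscape.  A solution is a binary
vector of length `N`; the landscape assigns each locus `i` a contribution
table `f_i` over the joint state of locus `i` and `K` other loci, drawn
i.i.d. uniform on [0, 1].  The raw payoff of a genotype is the mean of the N
contributions; raw payoffs are divided by the landscape maximum and raised
to the 8th power, which stretches the payoff distribution so that most
solutions are mediocre.  The transform is strictly monotone, so it changes
no ordering, only the reward profile of partial progress.

Two points deserve comment:

* **Conditioning arity.**  Each locus depends on itself plus `K` distinct
  other loci chosen uniformly at random, i.e. tables have `2^(K+1)` entries.
  This is the canonical NK construction; `K=0` then reduces exactly to a
  mean of independent per-locus contributions, and `K` counts
  *interdependencies* with other loci.
* **Full enumeration.**  All `2^N` payoffs are cached at construction
  (`N <= 20` enforced), reducing the inner simulation loop to array lookups
  keyed by the integer encoding of a genotype (bit `i` of the code is locus
  `i`).  At the default `N=15` a landscape costs ~30 ms to build.

Default environment parameters: `N=15` with `K=0` (smooth, generically
single-peaked) and `K=7` (rugged, hundreds of local optima).  The
implementation validates ruggedness directly: the number of strict local
optima is non-decreasing in `K`.

A fresh landscape is drawn for every repetition.  Averages over repetitions
therefore integrate over landscape realisations rather than conditioning all
conclusions on a single draw.

## Strategies

Every strategy is a composition of search, stopping and decision rules:

* sample `s` distinct contacts uniformly without replacement from the
  agent's network neighbourhood (`s=3` or `s=9` in the study grid);
* **best member**: candidate = highest-payoff sampled solution, payoff ties
  broken uniformly at random;
* **conformity**: candidate = unique modal sampled solution.  The stated
  fallback ("all solutions equally frequent → learn individually") is
  generalised to *any* tie for the top frequency (e.g. counts 4–4–1 with
  `s=9`): a tie yields no decision and routes to individual learning.  A
  random modal choice would inject an arbitrary bias the model description
  does not license.  The payoff compared is that of the modal genotype
  itself, evaluated on the landscape.
* **critical adoption**: a candidate is adopted only if its payoff strictly
  exceeds the agent's current payoff; otherwise the agent performs exactly
  one hill-climbing step (flip one uniformly chosen bit, keep on strict
  improvement).  Strict comparisons everywhere prevent neutral drift churn.
* **random copying**: observe one random neighbour, adopt if strictly
  better; no individual-learning fallback.  It can only redistribute
  solutions already present in the population.
* **individual learning**: one hill-climbing step per time step.

Populations are strategy-homogeneous; mixed populations and strategy
evolution are out of scope.

## Update scheme

Updates are synchronous: all agents observe the start-of-step population and
commit simultaneously.  Payoffs and unique-solution counts are recorded
after the commit, so step `t` reports the state after `t` full updates.  An
asynchronous mode (uniformly random agent order, immediate commit) is
available behind `SimulationConfig(update="asynchronous")` for sensitivity
analysis; it is implemented on the per-agent reference path and is slower.

The production stepper is vectorised over integer genotype codes; the
per-agent functions in `nksocial.strategies` define the reference semantics
and the two are cross-checked in the tests (exactly on tie-free
deterministic scenarios, statistically elsewhere).  Consequences of
vectorisation: random tie-breaking in best member is realised by randomising
sample order (exact, because distinct genotypes almost surely have distinct
payoffs), and hill-climb bit draws are made for all agents but applied only
to those that did not adopt socially.

## Networks

Ten undirected networks on `n=100` nodes with uniform degree `d=19` (the
complete graph has degree 99):

* **complete** graph;
* **ring lattice**: offsets ±1..±9 plus a perfect matching at offset 10
  arranged in alternating blocks of 10 nodes.  A circulant graph cannot
  realise odd degree, so "the 19 nearest neighbours" is implemented as: every
  node is tied to 19 of its 20 circularly nearest nodes.  The construction
  needs `n` divisible by 20 for odd `d`; it keeps the high-diameter local
  character that makes the lattice the canonical inefficient network.
* **eight extremised networks**: starting from a connected random 19-regular
  graph, degree-preserving double-edge swaps (rewire (a,b),(c,d) to
  (a,c),(b,d) or (a,d),(b,c)) are accepted only when the graph stays simple
  and connected and the mean of the target measure — closeness centrality,
  betweenness centrality, clustering coefficient, or Burt's constraint —
  strictly improves in the target direction (first-improvement hill climb;
  plateau moves rejected).

Measures are evaluated through igraph's C routines and agree with the
networkx implementations to 1e-10 on the test fixtures; "network constraint"
is Burt's structural constraint averaged over nodes.  For the clustering
objectives the climb uses an exact incremental update of the mean clustering
(a swap only affects triangles through the four touched edges, and degrees
are swap-invariant), which is ~100x cheaper per candidate than a full
evaluation.

**Rewiring budget.**  The reference procedure runs 10^6 iterations and 10^3
restarts per network — a convergence device, not part of the model.  The
package's desk-scale default spends comparable wall time on every objective
by scaling iterations inversely with evaluation cost: 800k (clustering),
80k (constraint), 50k (closeness), 20k (betweenness) candidate swaps, one
climb per network, ~3 minutes for the full ensemble.  `budget_scale` scales
these (multi-seed robustness checks in the tests use 0.2); paper-scale
budgets are reachable by passing explicit iteration counts.  At the default
budget the ensemble spans diameters 1–6 with the clustering-maximised
network reaching mean clustering ≈ 0.93.

**Efficiency classes.**  Networks are ranked by diameter and split at the
median (ties broken by name for determinism): the five low-diameter networks
are *efficient*, the five high-diameter ones *inefficient*.  The complete
graph is always efficient and the ring lattice always inefficient.  This
operationalises efficiency as speed of information spread, consistent with
analysing performance against diameter.

## Experiment grids and problem sizes

Defaults throughout: 100 agents, t=200 steps.  The desk-scale grids use
50 repetitions (smooth-environment grid), 200 (rugged-environment strategy
grid), and 100 per network (ensemble grid); the multi-seed sign checks use
30 repetitions at `budget_scale=0.2`.  Within a grid, all cells share the
same per-repetition landscape seeds (a paired design): landscape difficulty
is a large common variance component, and pairing removes it from every
between-cell contrast without biasing any single cell's mean.  Sampling and
initialisation streams are independent per cell, derived from the master
seed via hashed cell labels; all seeds stay below 2^31.

Analyses: final-step mean payoff per cell with its standard error of the
mean (sd/√reps across repetitions), efficiency-class means, and the sample
Pearson correlation between network diameter and final mean payoff
(undefined and rejected for constant diameters or fewer than three
networks).  Some diameters repeat across networks, so the correlation is
computed over an uneven diameter distribution.

## Known behaviour and limitations

* **Random copying cannot find the optimum.**  A pure copier can only
  spread initial solutions, so in the smooth environment its payoff
  plateaus at the best initial draw (transformed payoff ≈ 0.6 with 100
  agents on 2^15 solutions) even though the population still converges to a
  single solution.  Statements that *all* strategies reach the global
  optimum at K=0 hold only for the strategies with an individual-learning
  component.
* **Extreme clustering can favour best member.**  At the default budget the
  clustering-maximised network becomes near-cliquish (clustering ≈ 0.93).
  Inside tight cliques conformity converges each clique onto its own local
  optimum and cross-bridge minority solutions are never modal, so
  frequency-based copying cannot import them — payoff-biased copying can.
  In that one network best member can overtake conformity, unlike in the
  other nine.  Less extremised ensembles do not show this.
* Correlation magnitudes depend on the realised ensemble: at desk scale
  the diameter spread is narrower than under the reference rewiring budget,
  so the Pearson correlations vary by roughly ±0.1 across seeds; the signs
  are stable.
* The simulation assumes fixed networks, homogeneous strategies, and a
  static landscape; changing environments and empirically measured
  landscapes are out of scope.
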