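# Methods

## Problem setting

A comparative metagenomic experiment yields shotgun reads from samples of
two phenotype groups (e.g. obese vs lean gut microbiomes). Reads mapped to
metabolic reactions produce a reaction × sample count matrix; the global
metabolic network — compounds as nodes, reactions as (possibly reversible)
edges — supplies the topology. The goal is to find *connected* sets of
reactions ("subnetworks") that are coherently enriched or depleted in one
group, including sets that straddle the boundaries of curated pathway
definitions, where per-pathway aggregate tests dilute the signal and
per-reaction tests lose power.

## Per-reaction statistics

Counts are converted to per-sample relative abundances (column totals
normalize to 1; raw-count mode is available). Each reaction is tested with
Welch's t-statistic under a two-sided permutation null over group-label
assignments: with n₁ + n₂ samples all C(n₁+n₂, n₁) distinct assignments are
enumerated when there are at most 10,000 of them (252 for the default
5 vs 5 design), otherwise B random assignments are drawn and
p = (r+1)/(B+1) with r the count of |t| at least as extreme (ties count as
extreme). A t-distribution engine (Satterthwaite degrees of freedom) is
provided for speed. The p-value is clamped below at the permutation
resolution so the normal-quantile conversion stays finite.

Two-sided p-values become signed Z-scores

    z = sign(mean_G1 − mean_G2) · Φ⁻¹(1 − p/2),

positive when the reaction is more abundant in group 1. Degenerate rows
(all-zero, or constant with equal group means) get p = 1, z = 0.

Note the relative-abundance transform is compositional: strongly shifting a
few reactions necessarily shifts all others slightly in the opposite
direction. This is intrinsic to relative data, visible in tests as
opposite-signed near-significant background reactions when the planted
fraction is large.

## Subnetwork score and greedy search

The score of a subnetwork is the sum of its members' Z-scores; maximizing
it over connected subgraphs is NP-hard, so a deterministic greedy heuristic
is used. Two edges are adjacent when they share a compound. From every seed
edge (optionally only positive-weight seeds) the search repeatedly adds the
highest-weight frontier edge, recording the cumulative score, up to a size
cap (default 30); the result is the best-scoring prefix over all seeds, or
the prefix of exactly k edges in fixed-size mode. Tie-breaks are fully
deterministic (weight ties → lexicographically smallest reaction id;
candidate ties → higher score, then smaller size, then lexicographic).

Chain mode restricts growth to simple compound paths whose successive
reactions are direction-compatible (irreversible edges traversed
source→target only; self-loops never join chains). Two extension rules are
implemented: `both` extends at either end of the current path; `one`
extends only ahead of the last added edge — the classical rule for
reaction-chain growth. The simulation studies shipped with the package use
chain mode with one-ended extension, because the planted signal is a linear
reaction chain; arbitrary-subgraph mode is the general default.

An exhaustive oracle (`brute_force_search`, networks up to 16 edges)
enumerates all connected edge subsets or all simple direction-compatible
paths of a given size and anchors the correctness tests.

## Significance: p_abund and p_struct

Each candidate subnetwork receives two permutation p-values, both of the
form (r+1)/(B+1) with B = 1000 by default:

* **p_abund** permutes the sample-group labels, recomputes the member
  reactions' p/Z under each permutation with the same engine as the
  observed statistics (observed and null scores are computed identically,
  which makes them exchangeable), and counts permuted aggregate scores at
  least as large as observed. With the exhaustive inner engine this is
  computed analytically over the full assignment lattice and sampled; the
  identity assignment can be redrawn, so even an overwhelming signal sits
  slightly above the 1/(B+1) floor.
* **p_struct** permutes the edge weights across the current network and
  reruns the greedy search on each permutation, asking how easily the
  topology produces an equally good subnetwork from reshuffled weights.
  The classical null re-searches at the observed size k (`null_size=
  "matched"`). When the observed subnetwork came from a *free-size* search,
  that statistic is a maximum over sizes, and the size-matched null
  under-covers the selection, rejecting well above its nominal level on
  null data. The selection-matched alternative
  (`null_size="free"`) reruns the free-size search on every permutation,
  restoring exchangeability; the discovery loop uses it by default.

A degenerate but instructive case: in a very dense network the free-size
subgraph search simply collects (nearly) all positive weights, a quantity
invariant under weight permutation — p_struct is then 1 identically and the
statistic carries no information. The chain constraint (or any binding
topology) is what gives the topology null its discriminating power.

## Discovery loop

Iteratively: compute reaction statistics once; run the free-size greedy
search on the remaining network (first with observed weights for
G1-enriched sets, then with negated weights for G2-enriched sets — the
mirrored search); compute p_abund and, if it passes, p_struct; if the
subnetwork is significant (p_abund ≤ 0.05 AND p_struct ≤ 0.05 by default),
record it, delete its edges, and repeat until neither direction yields a
significant subnetwork. Results are ranked by p_abund (ties by p_struct,
then |score|). Each acceptance removes at least one edge, so the loop
terminates. p_struct permutes weights only among edges still present at
the current iteration, and permutations are redrawn per iteration.

## Synthetic studies

The generator emulates a two-group metagenomic comparison:

* **Network** — a connected random-attachment graph; compounds default to
  one per reaction (compound:reaction ≈ 1:1, the rough ratio of the global
  metabolic network); edge directions random, 50% reversible. A designated
  simple path of length L is embedded with its compounds inserted at
  uniformly random times of the attachment process, so planted-path
  degrees are exchangeable with the rest of the graph (inserting them
  first would make them hubs and confound planted status with topology).
* **Abundances** — reaction i draws all samples from N(μᵢ, (0.2·μᵢ)²)
  with μᵢ log-uniform on [10, 1000] (an explicit mean list can be
  supplied); draws are truncated at 0. Planted reactions draw group 1 from
  the shifted mean μᵢ′ = μᵢ + t_crit · σᵢ · √(2/n), placing the expected
  two-sample t at the two-sided critical boundary of the chosen effect
  level (0.05 or 0.01). Defaults: 5 subjects per group, L = 5.
* **Pathway blocks** — contiguous blocks of 20 reactions stand in for
  curated pathway definitions; the planted chain straddles a block
  boundary, the scenario where aggregate per-pathway testing dilutes the
  signal.

Baselines for the ROC comparison: (a) per-reaction 1 − p; (b) per-block
aggregate counts tested as a unit, every member reaction inheriting the
block's 1 − p. The subnetwork-aware ranking scores members of significant
subnetworks by 1 − p_abund of their subnetwork and all other reactions by
their own 1 − p. AUC uses mid-ranks for ties.

What the generator does *not* emulate: real mean profiles (means are
log-uniform, not taken from a real study), overdispersion and zero
inflation of count data, gene-length effects, correlated reactions within
operons/pathways, and more than one planted signal per dataset unless
constructed explicitly. Passing tests demonstrate correct statistical
behavior under the stated Gaussian design, not performance on real
metagenomes.

## Numerical choices

* Permutation p-values use the (r+1)/(B+1) estimator — never zero, so the
  Z conversion is finite; exhaustive enumeration includes the identity, so
  its p ≥ 1/S automatically.
* Tie counting uses a relative tolerance of 1e-9 so float noise cannot
  un-tie exact ties (which would be anticonservative).
* Score comparisons in the search use a 1e-9 absolute tolerance; all
  remaining ties resolve lexicographically, making every run bit-
  reproducible for a fixed seed.
* Null searches that cannot reach the required fixed size contribute −∞
  and can never look extreme.
* Exhaustive-permutation p-values live on a discrete lattice (126 atoms
  for 5 vs 5); calibration checks compare their empirical CDF to the exact
  discrete null at the attainable atoms — a continuous-CDF KS is biased by
  the lattice spacing regardless of calibration.
* The batched p_struct kernel (subgraph mode) is vectorized across seeds
  and permutations and reproduces the scalar greedy bit-for-bit (tested).

## Problem sizes in the shipped test suite

The statistical suites run scaled-down but adequate versions of the full
protocol: 200-reaction networks, B = 200 permutations for both subnetwork
p-values, 100 recovery / 200 null replicates, 500 dense-network replicates,
and 20 ROC replicates per configuration. The generator's own defaults
(500 reactions, B = 1000) are unchanged.

## Known limitations

* The greedy search carries no optimality guarantee; on small graphs it
  matches the exhaustive oracle in the large majority of instances (the
  test suite reports the observed fraction).
* The free-size best-prefix rule absorbs adjacent positive-weight noise
  edges, so recovered subnetworks typically carry a few extra members
  around a true signal; recovery is measured by Jaccard overlap for this
  reason.
* p_abund of a searched subnetwork is selection-biased by construction
  (the member set was chosen to score high); it must always be paired with
  p_struct, which is exactly what the joint significance rule does.
* Compositional coupling of relative abundances can hand the mirrored
  search a genuine opposite-signed signal when a large fraction of
  reactions is truly shifted.
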