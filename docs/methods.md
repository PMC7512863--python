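# Model and methods

This note documents the model implemented by `sympair`, the choices made
where the design was genuinely open, the defaults and why they are set
where they are, and what the shipped tests do and do not demonstrate.

## The model

A fixed amount of resource circulates between an environment and a
population of agents living on an undirected, connected node graph (default:
a 4×4 torus grid, so every node has four neighbours and no boundary
artefacts).  Agents see only their own node.  All state changes happen in a
fixed per-step phase order — upkeep, dispensing, pair aging, courtship,
reproduction, migration, deaths — with every random decision drawn from a
single seeded generator in a documented order, so a run is bit-reproducible
from its configuration and seed.

**Genotype and variation.**  Each agent carries ⟨x⃗, σ⃗⟩ with x⃗ ∈ ℝ² (male
displayed traits / female preferences) and per-coordinate mutation scales
σ⃗ > 0.  Offspring genotypes come from intermediate recombination (convex
per-coordinate mixtures with fresh uniform weights, applied independently to
x⃗ and σ⃗) with probability `rec_prob = 0.8`, otherwise a copy of one
parent; whole-genotype mutation follows with probability `mut_prob = 0.1`:
first the log-normal self-adaptive σ update with learning rates
τ₀ = 1/√(2n), τ = 1/√(2√n) (n = 2), then a Gaussian perturbation of x⃗ with
the new σ.  Offspring x⃗ is clamped to the landscape's domain box.

**Landscapes.**  Four 2-D minimization surfaces whose local minima act as
ecological niches: Michalewicz (m = 10, [0, π]²), Rastrigin ([−2.5, 2.5]²),
Schwefel ([−500, 500]²; the canonical form −Σ x_i·sin(√|x_i|)) and Waves
(x₁ ∈ [−0.9, 1.2], x₂ ∈ [−1.2, 1.2]).  The published typesetting of the
Waves formula is ambiguous about grouping; the single function `_waves`
implements the parenthesization
−(0.3·x₁)³ − x₂² − 4.5·x₂²·x₁·x₂ − 4.7·cos(3·x₁ − x₂²·(2+x₁))·sin(2.5·π·x₁)
and is the one place to change if a different reading is preferred.

**Resource economy (selection).**  The environment pool dispenses
`dispense_rate = 0.1` of its level per step, split equally across occupied
nodes and, within a node, by quality weights

    w_i ∝ exp(−sharpness · (f_i − min_j f_j) / R),

where R is the landscape's global value range (precomputed on a 201² grid)
and `sharpness = 10`.  The margin is taken above the *local* best and
normalized by the *global* range: agents well adapted to any decent niche
earn comparable shares (a niche two fitness units worse on Rastrigin keeps
≈ 70 % of the best share), while recombinants stranded on the barriers
between niches (tens of units worse) are starved.  Weights are translation
invariant, strictly positive, and uniform when all fitness values tie.
Every agent pays a flat upkeep of `upkeep = 0.01` nominal shares per step
(the nominal share is `total_resource / initial_population`), which is the
pump that keeps resource circulating; an agent at or below
`death_floor = 0.01` shares dies and its remainder returns to the pool.
Conservation of `pool + Σ holdings` is exact to rounding (measured drift
< 10⁻¹⁰ relative over 5000 steps).

**Courtship, pairs, search.**  An unpaired agent enters the mating market
when its resource first reaches `min_rep_res = 0.5` nominal shares, and
stays in the market — roaming to a random neighbouring node every step and
paying `mig_cost = 0.05` of its current resource — until it is accepted
into a pair or dies.  A searching female picks among the searching males of
her node with probabilities ∝ 1/(1+d) (d = Euclidean preference–trait
distance) and accepts the pick with probability exp(−½(d/s)²), where
s = 8 % of the domain diagonal; with sexual selection disabled the pick is
uniform and always accepted.  Search is therefore the model's main
mortality channel, and choosiness itself creates the female search cost.
An accepted couple forms a pair: it co-migrates (spontaneously with
probability `move_prob = 0.05` per step), reproduces whenever both members
are ready, and dissolves when its age exceeds `max_pair_age` or a member
dies.  With `max_pair_age = 0` a pair dissolves immediately after its first
brood, so every reproduction requires a fresh (and risky) search.

**Reproduction.**  A brood is two offspring, one female and one male by
default (keeping the sex ratio balanced; an independent fair coin is
available via `offspring_sex_rule="coin"`).  The parents transfer
`female_rep_cost = 0.4` and `male_rep_cost = 0.2` of their current resource,
split equally between the children — the asymmetry that makes females the
choosy sex.  Offspring start unpaired, sit and accumulate until ready, then
search.

## Analysis layer

**Species detection** operates on the genotype x-coordinates only (species
live in genetic space).  PAM (k-medoids, BUILD + best-improvement SWAP,
fully deterministic with lowest-index tie-breaks, vectorized over the
distance matrix) is run for k = 2..10; the k with the largest mean
silhouette width wins, and a single species is reported when the best
silhouette is ≤ 0.5.  The floor is set above the ~0.35–0.45 silhouette that
k-medoids assigns to *any* homogeneous Gaussian or uniform cloud, so a
noisy blob counts as one species while genuinely separated clusters
(silhouette ≳ 0.6) are detected; labels are canonicalized by cluster size
so they are invariant to input order.

**Diversity.**  Species abundances (cluster label frequencies) feed the
Hill numbers D_q = (Σ p_i^q)^{1/(1−q)} at q ∈ {0, 0.5, 1, 2}, with the
exp-Shannon limit at q = 1; centroid-distance diversity is the mean
Euclidean distance of genotypes from the population centroid.  These
satisfy the standard identities (S equal species give D_q = S; doubling;
monotone non-increase in q), which the test suite verifies against
independent arithmetic.

## Study designs and their scale

The replicated designs in `sympair.experiments` run at a reduced scale —
150 founders, 750 resource units (nominal share 5, as at full scale),
2000 steps, five replicates with fixed seeds — so a full suite finishes in
minutes.  Three patterns are asserted, always ordinally and by replicate
majority, never as point values:

* **Speciation:** with sexual selection and lifelong pairs on Rastrigin,
  the final snapshot contains ≥ 2 detected species in ≥ 4/5 replicates.
* **Pair persistence:** final-epoch centroid diversity is higher with
  lifelong pairs than with dissolve-after-brood pairs in ≥ 4/5 seed sets.
* **Homogenization control:** with both mechanisms off, the population
  concentrates into a single detected cluster in the majority of
  replicates.  Homogenization is the slow process in this system, so this
  control runs the full 5000-step reference horizon rather than the scaled
  2000 (measured: centroid diversity 0.4–0.65 at step 2000, ~0.02 with one
  cluster by steps 3000–4000).

## What passing tests do and do not show

The synthetic populations reproduce the qualitative mechanism: an initially
uniform cloud condenses into distinct clusters at fitness minima within a
few hundred steps when females are choosy, ephemeral pairs erode diversity
through repeated search mortality, and unselective random mating
homogenizes the population.  Two honest limitations:

* **Species are metastable, not permanent.**  At this scale, a detected
  species persists for roughly 1000–3000 steps before competitive exclusion
  or drift removes it; the reference behaviour of species lasting the full
  5000 steps is not reproduced.  Consequently the two mechanism-contrast
  patterns above hold reliably under the shipped replicate seeds but are
  marginal properties across arbitrary seed sets (per-replicate frequencies
  of roughly 0.4–0.8 in wider probes).  `scripts/acceptance.py` recomputes
  the same quantities under seeds derived from its `--seed` argument and
  reports whatever it measures.
* **No real data.**  All populations are self-generated; nothing here
  validates the model against biological observations — the claims are
  about the model's internal dynamics only.

Other numerical choices: landscape value ranges from a 201² grid scan;
readiness thresholds are inclusive; iteration orders are sorted and the RNG
is consumed in a fixed documented order, making snapshot and diversity CSVs
byte-identical across replays; empty populations yield zeroed diversity
reports; a single agent is one species.
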