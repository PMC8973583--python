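# Methods

## The three-classifier experiment

A dataset of molecules with binary activity labels is treated as a sample
`(X_i, y_i) ~ P`. After a stratified 90/10 held-out split, the remaining 90%
is split into two stratified halves (per-class counts equal within one
molecule). Three random-forest classifiers are trained on ECFP features:
`C_opt` and `C_mc` on Split 1 with different random seeds, `C_dc` on
Split 2. All three share one architecture and one feature representation,
so score differences on the same molecule isolate two effects:

* `S_opt − S_mc` — seed-level (model-specific) underspecification: how much
  the training randomness alone moves the score;
* `S_opt − S_dc` — split-level (data-specific) underspecification: how much
  an equally sized, equally distributed but disjoint training sample moves
  the score.

Scores are the fraction of trees voting "active", so they are quantized to
multiples of `1/n_trees` and bounded in [0, 1]. A `probability` mode
averaging per-tree leaf class frequencies exists behind a flag because
library conventions differ; the vote ratio is the default because it is
the definition the confidence score of a voting forest actually has.

Forest presets: the stock preset is 100 trees with leaves down to single
samples (library defaults, pinned); the `modified` preset is 200 trees with
at least 3 samples per leaf. The regularized preset exists because leaves
of one sample memorize label noise, and two forests memorize *different*
noise — exactly the mechanism that makes controls diverge on small noisy
data.

## Conditional diagnostics

All diagnostics condition on the optimization score, because the
disagreement between classifiers is strongly score-dependent — a global
correlation would average it away.

**Conditional score table.** The score codomain [0, 1] is divided into 25
equal bins (right-closed last bin); bin `i` collects the control scores of
reference molecules whose `S_opt` falls in bin `i`. The reference sample is
the held-out set augmented about ten-fold with Topliss analogs; without
augmentation the few molecules with high `S_opt` make the upper bins
unusably sparse. Empty bins fall back to the nearest occupied bin at lookup
time (logged).

**MAD curve.** `MAD(x) = mean(S_opt − S_ctrl | S_opt > x)`, reported as a
function of the threshold `x` and cut off at the largest observed `S_opt`.
The difference is signed — a control *above* the reward gives a negative
value — because the question is whether controls lag the reward; an
absolute-value mode is available behind a flag. The audit summarizes the
curve by the MAD over the top decile of `S_opt` (quantile 0.9) and warns
above 0.1, i.e. when the reward overstates the controls by more than ten
score points on the molecules that matter.

**Bias report.** The top 5% of held-out molecules by `S_opt` are compared
to each training split by nearest-neighbour Tanimoto similarity on Morgan
fingerprints (radius 2, 1024 bits). Nearest-neighbour (rather than mean
pairwise) similarity is used because the question is whether a close
relative of the molecule sits in Split 1; a full-pairwise mode would dilute
that signal with the bulk of the split.

**Tolerance band.** The sampled molecules of a generation run at step `t`
are treated as a sample of `P_t[S_opt]`. For each molecule, 10 control
scores are drawn with replacement from its bin's empirical conditional
sample; the 95% band is the (2.5%, 97.5%) quantile pair of the draws pooled
per step. Tail quantiles cannot be estimated from one or two observations,
so a bin holding fewer than 5 reference samples borrows from its nearest
occupied neighbours until that occupancy is reached (an empty bin is the
limiting case of the same rule; borrow events are logged). Without this
minimum occupancy a singleton bin makes the band collapse to a zero-width
point, and any observed series trivially "violates" it. With several runs
the per-step pool is the union of all runs' populations — the sampling
distribution the band describes is that of the algorithm at step `t`, not
of one run. **Band compliance** is the fraction
of steps at which the observed median control score (median over runs of
per-run means, the same statistic plotted in the trajectory envelopes)
stays at or above the lower bound. Compliance near 1 means the control
trajectory is consistent with the conditional law of the original data
distribution, so no exploitation beyond the pre-existing divergence needs
to be invoked.

## The generator

The goal-directed generator is a genetic algorithm on molecular graphs:
parents are chosen rank-proportionally with replacement; crossover cuts
each parent at a random non-ring single bond and joins complementary
fragments; mutation (default probability 0.01) applies one of atom
insertion / deletion / replacement, bond-order change, ring formation /
opening, with bounded retries and RDKit sanitization as the validity
gate. Survivor selection is elitist — top `population_size` of parents plus
offspring — with canonical-SMILES deduplication so the population does not
collapse to copies of a single high scorer; duplicates fill remaining slots
only when fewer unique structures exist. Elitism makes the best-so-far
score non-decreasing by construction. Control scorers are evaluated on each
recorded generation but never influence selection. Defaults: population
100, 151 generations, offspring count equal to population size; reduced
scales used in tests are stated below. The scorer/control interface is a
plain batch callable, so other generators can be plugged in.

## Topliss augmentation

Analogs are enumerated on every non-fused benzene ring of every held-out
molecule using the classical aromatic-substituent operational tree
(4-Cl; 3,4-Cl2; 4-CH3; 4-OCH3; 4-C(CH3)3; 3-CF3; 3-CF3-4-Cl; 3-Cl; 3-CH3;
2-Cl; 4-F; 4-Br; 4-NO2; 4-N(CH3)2 — configurable). Ring positions are
numbered from the attachment atom, walking toward the lower canonical-rank
neighbour, so numbering is deterministic; only H-bearing positions are
substituted and one pattern is applied per analog. On a ring with no
attachment the positional variants of a single group (2-/3-/4-Cl) are the
same molecule after canonicalization, so bare benzene yields 11 unique
analogs from the 14-pattern scheme while any attached phenyl yields 14.
Analogs carry no activity labels — they exist only to be scored. The
ten-fold target is a target, not a guarantee: when full enumeration
overshoots, analogs are subsampled per parent (round-robin over seeded
shuffles); when it falls short the achieved fold is logged.

## Synthetic data

The generator assembles molecules by attaching 1–3 substituents from a
~30-fragment library to one of ~20 aryl/heteroaryl/saturated scaffolds
(several phenyl-bearing, so augmentation has rings to work on). The true
label is the presence of a planted pharmacophore (default: a sulfonamide
group); the observed label is flipped with a noise probability, and
candidates are accepted against per-class quotas so the realized active
fraction tracks the 15% target even under noise. Two presets define the
study regimes:

| preset | n | label noise | forest | expected behaviour |
|---|---|---|---|---|
| divergent | 400 | 0.20 | 100 trees, leaf 1 | controls disagree at high `S_opt` (top-decile MAD ≈ 0.1–0.25) |
| concordant | 800 | 0.05 | 200 trees, leaf 3 | controls agree (top-decile MAD ≲ 0.05) |

What the synthetic benchmark does *not* emulate: real assay noise structure
(noise here is independent symmetric label flipping), activity cliffs,
scaffold-series correlation between train and test, potency gradations, or
the chemical diversity of screening collections. Passing the synthetic
suite therefore shows the machinery is correct and the regime contrast is
real under the planted-rule model; it does not certify behaviour on any
particular assay dataset. Occasional seeds of the concordant preset realize
datasets whose split halves genuinely disagree (the audit flags them) —
that is sampling variability of small datasets, and the audit exists
precisely to detect it.

## Paired-split and clustered dataset construction

For building splits that agree by construction, molecules are paired within
each label class by graph edit distance (nodes labelled by element, edges
by bond order) and one member of each pair goes to each split; unpaired
molecules form the evaluation set. Exact GED is exponential, so pairs are
prefiltered by heavy-atom-count difference and the distance is the best
upper bound available within a time budget: the minimum of the networkx
search's best mapping and a maximum-common-substructure bound (edit both
graphs down to the element/bond-order-exact MCS and back up). The greedy
matching accepts candidate pairs in ascending-GED order (ties broken
lexicographically on canonical SMILES), which is deterministic. Leader
clustering (diversity-picked leaders at Tanimoto distance 0.6 on 2048-bit
Morgan fingerprints, nearest-leader assignment, singletons for unassigned
actives) selects the most populated activity clusters and pulls in
inactives within the same similarity radius.

## Numerical choices and degenerate inputs

* Canonical SMILES dialect: RDKit isomeric canonical form, everywhere.
* Tanimoto of two all-zero fingerprints: 1.0 (identical empty sets), logged.
* Murcko-scaffold ratio of an acyclic molecule: 0 (empty scaffold).
* Duplicate molecules with conflicting labels at read time: first kept,
  warning logged.
* Stratified splits put odd molecules on a seed-decided side.
* Quantile estimates use numpy's default (linear interpolation) rule.
* A master seed fans out to per-stage seeds via `SeedSequence([master,
  stage_index])`, so any stage can be reproduced in isolation; every
  stochastic component takes an explicit seed or generator.

## Problem sizes used in the shipped tests

The test suite and the acceptance script run entirely on synthetic data at
reduced scale, chosen so the whole suite completes in minutes on one CPU:
generation runs use population 50 and 30 generations with 3 runs (the
full-scale defaults remain population 100, 151 generations, 10 runs);
coverage checks use 5000-molecule reference samples and 50-step synthetic
trajectories; regime-separation checks use 5 seed replicates of the two
presets at their native sizes (400/800). These sizes are the package's
test-scale defaults, not method parameters.

## Known limitations

* The GED is an upper bound under a time budget; pairings on large
  molecules may be suboptimal (deterministically so).
* Empirical tolerance bands inherit the sparsity of their reference bins;
  the minimum-occupancy borrowing rule prevents degenerate point bands but
  flattens the conditioning locally where the reference is sparse. The
  augmentation step exists to mitigate exactly this, and borrow counts are
  logged.
* Only classification scorers are treated; regression rewards would need a
  different binning of the conditional law.
* SMILES-LSTM and latent-space swarm optimizers are not included; the
  generator interface accepts any callable-scored population process.
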