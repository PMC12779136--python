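# Methods

`fluxgan` studies metabolic reprogramming between two phenotypes (a
"healthy" and a "cancer" state) when one class is severely
under-represented.  The workflow couples four models: a Wasserstein GAN with
gradient penalty that synthesizes minority-class expression profiles, a
constraint-based metabolic model contextualized per sample (iMAT + FBA), a
three-step biological filter that discards synthetic profiles with
implausible metabolism, and a random-forest classifier over flux features
whose impurity importances are rolled up to pathways and gene families.

## Expression handling

Input is a genes x samples matrix of non-negative FPKM-like values with a
binary label per sample.  Genes with zero reads in every sample are removed
before any modeling; the filter is idempotent and never touches samples.

## WGAN-GP augmentation

The generator maps a 100-dimensional standard-normal latent vector through
fully connected layers of widths 250 -> 500 -> 1000 (LeakyReLU, alpha = 0.2)
to the gene dimension with a Tanh output; the critic mirrors this
(genes -> 1000 -> 500 -> 250 -> 1, linear output).  Training uses Adam
(lr = 1e-4, betas = (0.0, 0.9)), batch size 2, 2000 epochs, and the
interpolated-sample gradient penalty

    L_gp = lambda * E_xhat[(||grad_xhat D(xhat)||_2 - 1)^2],   lambda = 10,

with one interpolation coefficient per row.  The critic is updated once per
minibatch and the generator once per five critic updates (the canonical
setting; configurable).  An epoch is one pass over the minority samples in
shuffled batches, so with four real minority samples and batch size 2 an
epoch is two critic steps.

Expression values are min-max scaled per gene to [-1, 1] to match the Tanh
output; constant genes map to -1 and invert back to their constant, and the
inverse transform clamps to the training range before clipping at zero.

The networks are implemented directly on numpy with hand-written
reverse-mode differentiation.  The gradient penalty needs the derivative of
the critic's input-gradient norm with respect to the critic parameters; for
a piecewise-linear critic (LeakyReLU hidden units, linear output) the
activation second derivative vanishes almost everywhere, so propagating the
penalty's upstream gradient forward through the tangent chain
`t_i = phi'(z_i) (t_{i-1} W_i)` and differentiating that bilinear expression
in reverse is exact almost everywhere — the same value a general autodiff
framework returns.  The implementation is validated against hand-derived
closed forms (penalty 0 for any unit-gradient critic, lambda for a constant
critic, 40 for `D(x) = 3 x_1` at lambda = 10) and against central finite
differences on random critics (relative error ~1e-9).

Because beta1 = 0, the Adam first moment reduces to the raw gradient and is
skipped; update buffers are preallocated so the optimizer does no per-step
allocation.

## Context-specific models

**GPR mapping.**  Reaction expression is the GPR tree evaluated with
AND -> min and OR -> max.  Genes missing from the matrix are skipped (an AND
over present operands only); a rule whose genes are all absent leaves the
reaction unmapped.  Unmapped reactions take the neutral discretization state.

**Discretization.**  Within each sample, the mapped reaction values get mean
mu and sample standard deviation s (ddof = 1); a reaction is highly
expressed (+1) above mu + 0.3 s, lowly expressed (-1) below mu - 0.3 s, and
moderate (0) otherwise.  The statistics are computed on the FPKM-like linear
scale.  For i.i.d. normal values the +1 fraction tends to P(Z > 0.3) ~ 0.38,
not the 0.25 of exact quartile cutoffs; the multiplier rule, not a
percentile rule, is what is implemented.  A constant vector yields all-zero
states with a logged warning.

**iMAT.**  With R_H = {state +1} and R_L = {state -1}, solve

    max  sum_{i in R_H} (y+_i + y-_i) + sum_{i in R_L} y0_i
    s.t. S v = 0,  lb <= v <= ub,
         v_i + y+_i (lb_i - eps) >= lb_i          (i in R_H)
         v_i + y-_i (ub_i + eps) <= ub_i          (i in R_H)
         lb_i (1 - y0_i) <= v_i <= ub_i (1 - y0_i) (i in R_L)

with binary y and activation threshold eps = 1 (bounds are canonicalized to
+/-1000 so the big-M rows are well posed).  The MILP is solved with HiGHS
through scipy; `mip_rel_gap` defaults to 1e-6.

The MILP optimum is heavily degenerate in v.  To make the extracted context
reproducible and functionally meaningful, the binary states are fixed at
their optimum (turning the big-M rows into tightened variable bounds) and
the flux degeneracy is resolved in two LP stages: maximize the biomass flux,
then minimize total flux `sum |v|` at that biomass.  This mirrors the
two-stage convention used for FBA below.  The context model retains
reactions with |v| > 1e-6 in the resolved solution plus the objective
reaction; all other reactions get bounds (0, 0).

**FBA.**  On the retained network, maximize the biomass flux subject to
S v = 0 and bounds; a second stage minimizes `sum |v|` (via the standard
split `t >= v, t >= -v`) with the biomass pinned at its optimum, so
alternate optima resolve deterministically.  A single-stage mode is
available.  Gross production of a currency metabolite (ATP, NADH, NADPH) is
`sum over reactions and matching metabolites of max(0, coefficient * flux)`,
summed across compartments; consumption is not subtracted.

## Biological filtration of synthetic profiles

1. **Energy envelope** — ATP, NADH and NADPH gross production must lie
   inside the [min, max] envelope of the real minority profiles, bounds
   inclusive.  Gross production is the default (net production available).
2. **Glycolysis Disorder Index** — GDI = lactate secretion / glucose uptake,
   with the COBRA sign convention (negative exchange flux = uptake, positive
   = secretion).  Candidates pass only at GDI <= 1e-6 — "zero" cannot be
   exact in floating point after two LP solves; candidates without glucose
   uptake have no defined index and are removed.
3. **Gluconeogenesis** — any marker reaction carrying more than 1e-6 flux in
   its gluconeogenic (positive) direction disqualifies the candidate.  The
   markers are configurable reaction ids; the toy network has a single
   ATP-consuming pyruvate -> glucose-6-phosphate reaction.

Filters are independent predicates applied energy -> GDI -> gluconeogenesis;
each removed sample carries its first-failure reason, and the final survivor
set does not depend on the stage order.

## Classification

Flux features are assembled over the union of active reactions across all
context models (lexicographic column order); a cell is NaN exactly when the
reaction is absent from that sample's model.  The default imputation is 0
(an absent reaction carries no flux in that context, keeping the feature
physical); a sentinel mode (min - 1.5 * range) makes absence separable when
missingness itself should be a signal.

The forest uses 1000 trees, Gini impurity, balanced class weights, a
stratified 80/20 train/test split, 8-fold stratified cross-validation on the
training part (CV on all data would leak the held-out set), and the
out-of-bag score of the fitted forest.  Everything is seeded; reports
include per-class precision/recall/F1, the confusion matrix, fold scores and
misclassified sample ids with their origin (real/synthetic).

## Multi-level importance

* **Reactions** — impurity-decrease importances normalized to sum 1, plus
  the Spearman rank correlation of each imputed flux column against the
  label (healthy = 0, cancer = 1).  For a perfectly separating feature at
  equal group sizes the attainable |rho| is sqrt(3/4) ~ 0.866, not 1;
  constant columns get rho = 0 and are flagged.
* **Pathways** — mean importance over member reactions present in the
  feature union (missing subsystem -> "Unassigned"), normalized to
  percentage shares that sum to 100 over reported pathways.
* **Genes and families** — for gene g with reaction set R(g),
  `raw(g) = sum of importance over R(g)` and
  `score(g) = raw(g) * (0.5 + 0.5 * sigmoid(k (|R(g)| - n0)))`, so genes on
  many reactions gain weight while single-reaction genes keep at least half.
  Defaults: k = 1, n0 = median reaction count over genes.  Families sum
  their member genes (mean rollup by flag); the top 15 families are tiered
  by the quartiles of their scores (type-7 quantiles; a score on a boundary
  takes the higher tier).
* **Clustering** — average-linkage agglomeration of the top-70 reactions by
  importance under the distance 1 - |Spearman rho| between flux columns,
  exported as a Newick tree with reaction-id leaves (subsystems in the
  accompanying table).
* **Activity summaries** — per class, in stable input order: a trailing
  rolling mean of the imputed flux (window 10, truncated at the start) and
  the activity ratio, the windowed fraction of samples with |flux| > 1e-6.

## The toy study system

The synthetic module stands in for a genome-scale human model plus an
imbalanced tumor/normal cohort, at desk scale: 56 reactions, 34 metabolites,
3 compartments, 41 genes (67 simulated genes including decoys), 80 samples.

The network couples central carbon metabolism (glucose uptake, lumped
glycolysis, pentose-phosphate, TCA, oxidative phosphorylation, lactate
fermentation with a lactate exchange) to a capped biomass reaction that also
consumes two branch-fed precursors:

* **acyl-CoA** from an extracellular fatty-acid import branch (transport
  with GPR `FABP1 or FABP2 or FABP4 or SLC27A1`, activation with
  `ACSL1 or ACSL3 or ACSBG1`) or from gene-gated de novo synthesis;
* **a glycan precursor** from a three-step lysosomal heparan-sulfate
  degradation chain (salvage; the enzymatic gate carries
  `SGSH or NAGLU or GNS`) or from de novo synthesis, feeding a constitutive
  O-glycan assembly chain.

The cheap routes (import, salvage) are gene-gated; the fallbacks carry no
GPR so a context can lose a branch without losing growth.  An amino-acid
catabolism reaction provides a GPR-free floor of pyruvate, NADH and
substrate-level ATP, and free sinks (pyruvate, acyl-CoA, glycan overflow,
CO2, currency demands) keep every iMAT forcing satisfiable — without these,
expression noise occasionally makes whole samples infeasible and collapses
their flux profile to zero, which would poison both classification and
importance.  A block of eight single-gene "amino-acid derivative"
conversions is metabolically inert but gives the per-sample discretization
statistics a realistic bulk of mid-expressed reactions, preventing the
planted extremes from inflating the mean +/- 0.3 SD band.  Integer mass
tags (a lumped carbon count) on every metabolite make each internal reaction
balance-checkable.

The expression simulator is log-normal per gene:
`value = 2^(baseline_g + shift + N(0, noise_sd))` where shift is
+effect_size for planted-up genes and -effect_size for planted-down genes in
cancer samples only.  Unplanted genes draw a random baseline
(N(5, 0.5) in log2 units); planted genes get fixed baselines — import genes
at mean - 1 (lowly expressed in healthy tissue), lysosomal genes at
mean + 0.5 (the healthy program) — so the planted shift is the only
systematic cohort difference across seeds; a handful of housekeeping genes
(glucose entry, glycolysis, G6PD, the synthase gating de novo fatty-acid
synthesis) are pinned at mean + 1.  Defaults: 40/40 samples balanced, 40/4
for the imbalanced preset (mirroring the 144:4 study ratio at 10:1),
effect_size = 2 (log2), noise_sd = 0.5.

Under these conditions the cancer class deterministically activates the
import branch (its reactions are forced by iMAT and carry biomass-driven
flux) and silences the salvage chain, while healthy contexts do the
opposite with sampling noise — this is the planted truth the end-to-end
tests recover: perfect held-out recall for the cancer class, the transport
reaction among the top-3 importances, "Heparan sulfate degradation" and
"Transport reactions" among the top-3 pathway shares, and the FABP/SLC27A
families in the Very High tier.

**What the simulator does not emulate:** real gene-gene covariance, batch
effects, library-size artifacts, the scale of a genome-wide matrix
(~55k genes), or a genome-scale network (~13k reactions).  Passing tests
show the pipeline recovers signals it can represent, under its own modeling
assumptions — not that those assumptions hold for real tumors.

## Problem sizes and numerical choices

* Toy end-to-end runs: 80 samples x 56 reactions; one sample's
  contextualization (MILP + three LPs) takes ~10 ms.
* GAN regression problem: 2 genes, 16 training samples, 2000 epochs.
* Tolerances: LP/MILP feasibility and mass balance at 1e-6; scaling
  round-trip exact to 1e-9; MILP relative gap 1e-6; activity threshold
  1e-6 (strictly below eps = 1).
* Tie-breaks: biomass-then-minimal-flux everywhere a solver faces alternate
  optima; quantile ties promote to the higher tier; identical importances
  order lexicographically in reports.
* Degenerate inputs: constant reaction-expression vectors discretize to all
  zeros (warning); empty candidate lists produce zero-count filter reports;
  constant feature columns get Spearman rho = 0 and are flagged.

## Known limitations

* The iMAT context keeps one deterministically chosen optimum; alternate
  optima are not enumerated or unioned.
* Importance is impurity-based and spreads arbitrarily among exactly
  collinear flux columns (stoichiometrically coupled reactions); pathway
  aggregation dampens but does not remove this.
* The gradient-penalty double backprop is exact only for piecewise-linear
  critics; swapping in a smooth critic activation would require the full
  second-order term.
* FPKM-scale discretization inherits the skewness of the linear scale; the
  +/-0.3 SD band is asymmetric in tail mass for log-normal data.
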