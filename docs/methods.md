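# Methods notes

This note records the models, conventions and numerical choices behind
traitpath, and what the synthetic-data tests do and do not establish.

## Character model

A k-state discrete character (default alphabet `H`, `S`, `A`:
hermaphrodite, separate sexes including sequential hermaphrodites, asexual)
evolves on a rooted tree as a continuous-time Markov chain with generator
`Q`. Off-diagonal `q_ij ≥ 0` is the instantaneous rate of an i→j change;
rows sum to zero. Branch lengths are in whatever units the input tree
carries (typically expected substitutions/site of a reference gene), so
rates are per unit branch length. Three nested parameterizations are
exposed:

| class | free rates (k = 3) | constraint |
|-------|--------------------|------------|
| ER    | 1                  | all off-diagonal rates equal |
| SYM   | 3                  | `q_ij = q_ji` |
| ARD   | 6                  | none |

Parameter order is documented in `mk_model.build_q`: SYM takes unordered
pairs lexicographically, ARD ordered pairs row-major.

The root prior is *equal* by default (each state weight 1/k), matching the
default of the widely used mapping implementations; `stationary` and
`custom` are available. Tips coded `?` (unknown) enter the likelihood with
an all-ones partial vector — a fully ambiguous observation, never a fourth
state — and receive genuine posteriors from the marginal reconstruction.
Parsimony treats `?` identically (any state allowed at that tip).

Assumptions worth stating: a single character evolving independently of
lineage diversification; homogeneous `Q` across the tree (no hidden rate
classes, no covarion behavior); and correctness of the supplied topology
and branch lengths. Intermediate sexual systems (androdioecy, sequential
hermaphroditism as its own state) are out of scope — sequential
hermaphrodites are coded `S` in the input table by convention.

## Likelihood machinery

- **Pruning** with per-node rescaling (divide by the max partial, accumulate
  logs), so 500+ tip trees at small rates do not underflow.
- **Matrix exponentials** via eigendecomposition of the dense k×k generator,
  vectorized over all branch lengths at once; if the eigenvector matrix has
  condition number above 1e8 (nearly defective `Q`) the code falls back to
  scipy's Padé `expm` per branch. The two routes agree to 1e-12 in tests, and
  pruning log-likelihoods match brute-force enumeration over internal states
  to 1e-10 on hundreds of random instances.
- **Fitting** maximizes over log-rates with L-BFGS-B in the box
  [1e-8, 1e3], with 5 restarts (default) dispersed ±3 log-units around a
  one-change-per-unit-length initial guess; Mk surfaces are flat and
  occasionally multimodal, and restarts are cheap. Non-convergence is
  flagged on the result, not raised. Degenerate data (e.g. all tips
  identical) legitimately drive rates to the lower bound.
- **LRT**: the reported statistic is the conventional `2·ΔlnL` with df the
  difference in free-rate counts; the raw `ΔlnL` is carried alongside.
  Model selection walks up the nesting chain ER → SYM → ARD and adopts the
  more complex class only when the forward test is significant (default
  α = 0.05) — the fewer-parameters-when-equal rule.

## Stochastic character mapping

Histories are sampled in two stages. Node states are drawn root-to-tip:
the root from `prior × downward partial`, each child j given parent i with
probability ∝ `P_b(i,j) · L_down(j)`. Each branch is then filled in from
the CTMC bridge conditioned on its endpoint states:

1. **Modified rejection sampling** — forward simulation from the parent
   state, accepting on an endpoint match; when the endpoints differ, the
   first jump time is drawn from the exponential truncated to the branch
   (at least one event must occur), which keeps acceptance workable on
   short branches. Capped at 10,000 attempts.
2. **Uniformization fallback** — the number of candidate events is drawn
   from its exact endpoint-conditioned distribution (Poisson mixture against
   powers of `R = I + Q/μ`, `μ = max leaving rate`), intermediate states
   from the discrete bridge, jump times as uniform order statistics, and
   virtual self-jumps erased. This terminates on any feasible endpoint pair
   and is exact; tests confirm its jump-count distribution matches rejection
   sampling and an analytic series expectation.

The strongest correctness check ties the sampler to an independent analytic
computation: node-state frequencies over thousands of maps match the exact
marginal posteriors within three binomial standard errors at every node and
state.

Mapping uses the ML point estimate of `Q` (empirical Bayes), per the usual
practice of mapping under the best-fitting model. A known consequence,
quantified during development: credible intervals for transition counts
built from plug-in rates under-cover the truth when the dataset is small
relative to the rate uncertainty (≈76% instead of 90% on 40-tip trees, and
worse on larger trees where intervals tighten faster than the rate estimate
improves). The calibration tests therefore condition on the generating
rates, where coverage is nominal (≈96%); conclusions that lean on interval
widths from fitted rates should be read with that caveat, or checked across
a grid of plausible rates.

Default number of simulations is 1000, the conventional choice at which
Monte-Carlo error on mean counts is well below a single change for trees of
this size.

## Parsimony and MPR averaging

Unordered states, unit cost, branch lengths ignored, polytomies handled
natively (Sankoff). Because ancestral reconstructions at minimal cost are
usually not unique, directed change counts are defined as the **uniform
average over all most-parsimonious reconstructions**: the DP carries, per
node and state, the exact count of minimal-cost subtree labelings and their
summed k×k change matrices (Python integers, immune to overflow), plus an
upward pass giving each node's state frequency across all MPRs. Averages
are exact rationals; floats appear only at presentation. Two identities are
asserted rather than approximated: the averaged matrix sums exactly to the
minimal cost, and DP counts/averages equal explicit enumeration on all
small random instances tested. "Equally parsimonious" nodes (state
fraction ½) fall out of the same computation.

This uniform-over-MPRs definition is principled and oracle-testable; other
software may average equally parsimonious reconstructions with different
(undocumented) weightings, so decimals need not match such tools exactly.

## Tree operations and conventions

- **Newick dialect**: underscores in unquoted labels are literal (species
  names like `Mnemiopsis_leidyi` survive round-trips); labels with spaces
  are quoted on output.
- **Grafting** replaces a monophyletic clade (or placeholder tip) with a
  donor subtree, the donor root inheriting the replaced clade's stem
  length — composite trees are assembled by repeated grafts onto a
  backbone.
- **Sister swap** re-roots the ingroup so a named clade is sister to all
  other ingroup tips. The moved clade keeps its own stem length; the stem of
  its new sister group accumulates the branches collapsed by the
  rearrangement; the ingroup's stem is reused for the new ingroup node.
  Published analyses rarely state their convention; this one conserves path
  lengths where possible and makes the double swap return the original
  unrooted topology (property-tested).
- **Ultrametricization** uses mean path length (each node's age is the mean
  path to its descendant tips, clamped to be monotone toward the root):
  deterministic and parameter-free, unlike penalized-likelihood dating whose
  smoothing parameter would be one more unreported knob. Applied by the
  pipeline only for the stochastic-mapping stage; ML fitting and parsimony
  consume the supplied lengths.
- Outgroups are dropped before reconstruction (their states are not
  comparable to the ingroup's), suppressing any degree-2 nodes that leaves.

## Synthetic data: what it emulates, what it does not

`make_study_like_fixture` generates 165-tip datasets with the composition
of a species-level animal sexual-mode matrix: clades of 62 + 60 + 31 + 11
+ 1 tips on a ctenophore-sister backbone, Yule topologies within clades,
lognormal (σ = 0.4) branch-specific rate noise breaking the clock, the tree
rescaled to mean root-to-tip depth 1, and a three-state character simulated
under an asymmetric-rate model (`S→H` 0.65 vs `H→S` 0.35, asexuality rare
at 0.01–0.03) from a separate-sexes root. Characters are re-simulated until
observed counts after masking 25 tips to unknown land within ±10 of
83 S / 54 H / 3 A, so every dataset matches the study-like composition;
masking is uniform by default with a clade-biased option. All ground truth
(generating rates, root state, full branch-by-branch history) is retained.

Rate-recovery experiments use Yule trees rescaled to unit mean depth
(`simulate_yule_tree(..., mean_depth=1.0)`): rates are then per unit tree
height and identifiable regardless of tip count. An unscaled 500-tip Yule
tree is ~5.3 deep, a rate-1 character saturates on it, and the ML rate is
legitimately far from truth there — verified by an independent R
implementation returning the identical estimate on the same data.

What passing these tests shows: the engines are correct (they match
enumeration, closed forms, and each other), the sampler is calibrated, and
directional rate asymmetry of the magnitude built into the generator is
recoverable by both methods at this data size. What they do not show:
robustness to misspecified topology or branch lengths, to coding errors in
the input table, to state-dependent diversification, or to rate
heterogeneity across lineages — none of which the generator emulates.

## Problem sizes and defaults used in the shipped checks

Oracle comparisons use hundreds of random trees of ≤ 5 tips (likelihood)
and ≤ 8 tips (parsimony enumeration); sampler calibration uses 5000 maps on
a 10-tip fixture and 50 replicate 40-tip datasets; rate recovery uses
twenty 500-tip trees; the end-to-end factorial run uses the 165-tip fixture
with 100–1000 maps per scenario. These sizes keep the full suite fast while
leaving each check statistically sharp.
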