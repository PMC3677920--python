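# Methods

This note documents the models implemented in `phylocoev`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Character models on trees

A categorical character with k states evolves along a rooted tree as a
continuous-time Markov chain with generator Q (off-diagonal rates
q_ij ≥ 0, rows summing to zero). The likelihood of tip data is computed
by Felsenstein pruning: conditional likelihoods are accumulated tipward
to rootward with per-branch transition matrices P(t) = exp(Qt) and
combined at the root with a prior π. Three root policies are supported:
UNIFORM (π_s = 1/k; the default, since the replication target's own
default is not documented), FIXED(s) (a point mass, used for the
"fixed sacculate root" hypothesis), and EMPIRICAL (tip-state
frequencies).

Transition matrices are computed by eigendecomposition of Q, vectorized
over branches, with a scipy scaling-and-squaring fallback whenever the
eigenbasis is ill-conditioned (condition number > 1e8; this catches the
defective generators that arise when constrained templates make rates
exactly equal). Entries below 1e-14 are zeroed and zero-length branches
get an exact identity, so structurally impossible data keep likelihood
exactly zero instead of inheriting eigendecomposition round-off.
Missing tip states ("?" in character files) contribute an all-ones
partial likelihood.

Constrained rate templates (`RateModelSpec`) express zero and
equality constraints via shared parameter slots. The named constants —
MALE_6RATE, MALE_2RATE, INDEP_4RATE, DEP_8RATE, DEP_7RATE_NOPREC —
encode the male-trait and joint penis/barrier hypotheses. Joint states
are ordered (S⁺B⁻, S⁺B⁺, S⁻B⁺, S⁻B⁻) so every single-step transition
changes one character; dual transitions are structural zeros.
MALE_6RATE frees all six ordered state pairs of the 3-state male
character, including the direct S⁺P⁻ ↔ S⁻P⁺ moves. `joint_embedding`
builds the 4-state product of two binary models; its likelihood
factorizes exactly into the two marginal likelihoods (tested to 1e-10),
which is what makes the independent 4-rate model a genuine null.

## MCMC and model comparison

The sampler is Metropolis–Hastings over the rate vector with uniform
rate priors on (lower, upper] (default upper 100, exposed in config):
each iteration perturbs one uniformly chosen rate by a sliding-window
proposal of half-width `rate_deviation` (reflected at the prior bounds,
clamped to [0.001, 2.0]) and independently resamples the tree uniformly
from the sample. This targets the posterior averaged over the fixed
tree sample. `tune_rate_deviation` doubles or halves the half-width
until the realized acceptance fraction enters the 20–40% window; the
window is only attainable when the posterior is concentrated relative
to the proposal bounds (diffuse posteriors accept nearly everything at
the maximum half-width — the tuner then simply stops at the cap).

Log marginal likelihoods use the stabilized harmonic-mean estimator
(mixture stabilization with δ = 0.01, fixed-point iteration in log
space; δ = 0 recovers the plain harmonic mean). The plain harmonic mean
has infinite variance, hence the stabilization; standard errors come
from 1000 bootstrap resamples of the log-likelihood trace, vectorized
across replicates. Model comparison follows the replication protocol
exactly: K = |Δ mean log ML| for the non-nested root comparison, and
χ² = 2·Δ(mean log ML) against a chi-square with df = the difference in
free parameter counts for nested pairs. Computing a "likelihood-ratio"
test from marginal rather than maximized likelihoods is statistically
unorthodox — the marginal likelihood already penalizes dimension, so
the test is conservative (negative statistics are clamped to zero with
a warning). The across-run "Mean" convention is the arithmetic mean of
run means and the arithmetic mean of run SEs. Per-rate comparisons
across runs use a standard paired t-test (df = runs − 1); the
published t for the q12-vs-q13 contrast is not recoverable from its
printed mean ± sd under that formula, and no attempt is made to
reverse-engineer it.

ESS is the autocorrelation-based estimate (arviz); a constant trace is
degenerate and reported as ESS = record count with a warning.

## Hierarchical mapping

For a binary character the hierarchical model places a symmetric
Beta(α, α) prior on the stationary bias π₁ and a Gamma(shape, rate)
prior on the overall substitution rate r, with generator
q01 = r·π₁, q10 = r·π₀. Priors are integrated over deterministic
quantile-midpoint grids (default 25 points per dimension) rather than
nested MCMC: deterministic, testable, and adequate for binary
characters. Hyperparameters are fitted by grid search (bias α on a
log-spaced grid refined once; Gamma by two coordinate sweeps over
shape and mean). `fit_rate_prior` integrates the bias over a moderate
Beta(2, 2) grid rather than fixing it at the empirical tip
frequencies: a point-mass empirical bias lets rare-state datasets reach
the saturation plateau and destroys rate identifiability. The fitted
hyperparameters of the original analysis (bias α = 5.888/5.906, rate
Γ(3.515, 0.038) and Γ(3.108, 0.036)) ship as named presets; note they
presume substitution-scaled branch lengths, so pipeline desk defaults
use Γ(3.5, 1.0) on unit-height trees instead.

Stochastic maps draw node states from their joint conditional
distribution (pruning pass, then preorder sampling) and branch paths
conditional on both endpoints by rejection — forward simulation until
the endpoint matches, capped at 1e5 attempts — with an
endpoint-conditioned uniformization sampler as fallback and as the
independent oracle in tests. Association between two mapped characters
is m_ij = mean over paired maps of (J_ij − J_i·×J_·j), where J is the
joint dwell-fraction table, and M = Σ|m_ij|. The published component
magnitudes do not sum to the published overall correlation, so the
aggregation is ambiguous; M = Σ|m_ij| is implemented and the component
table always reported. Predictive p-values re-simulate both characters
independently from their hyperpriors on the same trees and take
two-tailed tail fractions, p = 2·min(tails) with the (1+count)/(1+n)
convention, capped at 1. One- vs two-tailed is not documented in the
replication target; two-tailed is the conservative choice.

## Parsimony

Fitch counts and Sankoff minimum-cost reconstructions with arbitrary
cost matrices; "no parallel gains" of the sacs is a Dollo-style scheme
(loss 1, regain 1e6) — prohibitive but finite, avoiding infinite
arithmetic. The single reported labeling breaks ties toward the lower
state index after the down-pass; full per-node optimal state sets are
also computed (via an outside/down dynamic program) so transition
counts can be read as ranges.

## Synthetic data

`simulate_yule_tree` draws pure-birth trees: waiting time Exp(λk)
between the k-th and (k+1)-th birth, stopping at the n-th birth with
tips extended one further Exp(λn) waiting time (so no terminal branch
has zero length); the expected root height is
Σ_{k=2}^{n-1} 1/(λk) + 1/(λn), checked against 2000 simulated trees.
Tree samples are independent Yule trees on one label set
(outgroup joined as a sister clade, whole tree scaled to unit height)
with optional lognormal branch-length jitter (σ = 0.1) emulating
posterior spread — topological uncertainty in a real posterior is
correlated between trees, which this deliberately does not model.

Scenario generators produce the study-shaped characters: INDEPENDENT
(product of two binary chains), DEPENDENT (8-rate generator with
transitions into the concordant states S⁺B⁻/S⁻B⁺ five-fold faster by
default), PRECEDENCE (sac loss ten-fold faster than barrier gain from
the ancestral state), MALE_CHAIN (the 2-rate male chain). Base rate is
1 per unit tree height. The male 3-state character derives from the S
history plus a pedipalp overlay that can only switch on while sacs are
absent, so S⁺P⁺ never occurs. The 29-taxon fixture
(`make_study_like_fixture`) is a synthetic stand-in with a hard-coded,
biologically plausible branching order satisfying the reported
constraints: 25 ingroup + 4 outgroup, exactly two sac-and-barrier taxa,
one taxon with neither, barrier-bearing non-sacculate taxa in four
separate clades, four Dollo sac losses and at least four barrier gains.

## Desk-scale test sizes and what they show

The full protocol (10⁸–10⁹ MCMC iterations, 431 posterior trees,
43,100 predictive samples) is reproduced in structure, not in size.
Tests run minutes, with these problem sizes as the package's defaults:

* recovery of the 8 dependent-model rates: 20 seeds × 25k iterations
  over 20 trees, uniform rate prior on (0, 10] so the prior scale
  matches unit-height trees (with an (0, 100] prior the truth sits in
  the prior's extreme tail and interval coverage is meaningless);
* LRT type-I calibration: 200 replicates at 600 iterations on 10-taxon
  trees — the marginal-likelihood LRT is conservative, and stays so;
* association calibration: 100 single-map repetitions on 12-taxon
  trees (the observed map is drawn under the same hyperparameter draw
  that generated the data, which makes the predictive p-value exactly
  calibrated up to grid discreteness);
* association power: 50 replicates on 29-taxon trees under the
  strong-coupling (10×) dependent scenario, with datasets conditioned
  on both characters being polymorphic (minor-state count ≥ 4; the
  empirical characters have minor-state counts of 11 and 14) — an
  invariant character carries no association signal under any method.

Passing these shows the machinery is correct and calibrated at small
scale; it does not show that desk-scale chains mix well enough for
real 8-parameter problems (they visibly do not: ESS warnings fire), nor
that the synthetic tree samples capture the correlated topological
uncertainty of a real posterior.

## Known limitations

* Harmonic-mean marginal likelihoods are kept for fidelity to the
  replication target; stepping-stone or path sampling would be better
  and is deliberately out of scope.
* The sliding-window sampler mixes slowly on weakly identified rate
  ridges; the per-seed preference between dependent and independent
  models at desk scale is noisy even when the aggregate preference is
  clear.
* No rate heterogeneity across branches within a likelihood
  evaluation, no hidden-state models, no nexus I/O, no node-height
  re-summarization of tree samples.
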