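# Methods

`cladeage` asks one question of a higher-level timetree: does the age of a
clade predict how many extant species it contains?  Under unbounded
birth-death diversification the answer must be yes — richness grows
(conditionally) exponentially or, in the balanced case, linearly with time —
so the package pairs the regression machinery needed to measure the
age-richness relationship with the generative machinery needed to say what
that relationship *should* look like under explicit models of among-clade
rate variation.

## Data model

The unit of analysis is a terminal clade of a rooted, binary, ultrametric
timetree (branch lengths in My).  Each tip carries an extant species count
(richness ≥ 1, stored as 64-bit integers since insect-scale counts exceed
3×10⁵).  The **stem age** of a tip is the age of its parent node, which on
an ultrametric tree equals its pendant branch length; a child of the root
has stem age equal to the root height.  Ultrametricity is enforced within a
relative tolerance of 1e-6 of the root height (published timetrees carry
rounding error); polytomies are an error by default and can be resolved
with zero-length branches on request, because both the regression
covariance and the shift-selection likelihood assume a binary tree.

Richness tables are TSV (`name`, `richness`[, `source`]).  Lineages absent
from the tree can be folded into their closest sampled sister (smallest
patristic distance): the sister's richness grows by the missing count and,
when the fold collapses a cherry, the surviving tip inherits the merged
clade's stem age.  Reconciliation conserves the species total exactly and
emits a JSON audit of every merge; names matching nothing are flagged,
never guessed.  Equidistant fold targets are an error unless the
deterministic alphabetical tie-break is requested.

## Birth-death core

For one lineage with speciation rate λ and extinction rate μ (r = λ − μ,
ε = μ/λ), the number of extant descendants after time t follows the
geometric-tail law P(N=0) = a_t, P(N=n≥1) = (1−a_t)(1−b_t)b_t^{n−1} with

    a_t = μ(e^{rt} − 1)/(λe^{rt} − μ),   b_t = λ(e^{rt} − 1)/(λe^{rt} − μ).

Numerical choices: all pmf work is in log space (richness up to ~1e7);
expressions are evaluated with e^{−rt} when r > 0 and e^{rt} when r < 0 so
no exponential overflows; when |r|·t < 1e-8 the balanced-limit forms
a = b = λt/(1+λt) take over (the naive expressions cancel
catastrophically near r = 0).  μ > λ is supported everywhere.
"Conditioned" always means conditioned on ≥ 1 extant descendant;
the conditioned expectation is e^{rt}/P(survival), which reduces to
1 + λt when μ = λ.  Sampling is exact inverse-CDF on the geometric
structure, O(1) per draw, with draws capped inside the int64 range (a cap
that only binds for astronomically large clades).

Constant-rate ML fits maximise the sum of survival-conditioned log-pmfs
over (log λ, log μ) by Nelder-Mead from two starts (one-dimensional in
log λ when ε is fixed).  A fit pinned to the rate floor — e.g. every clade
monotypic, which carries no growth information — is flagged rather than
reported as converged.

## Phylogenetic regression and signal

PGLS regresses log-richness (natural log by default; slopes are
base-dependent so the base is recorded in every result) on stem age with
residual covariance V[i,j] = depth of MRCA(i,j), its Pagel's-Λ transform
(off-diagonals scaled by Λ), or the identity (OLS).  Estimation is GLS via
Cholesky; the slope is tested two-tailed on t with df = n − 2.  A residual
norm at machine-epsilon scale (constant response) reports t = 0, p = 1
instead of a 0/0 artifact.  Pagel's Λ is estimated by profile ML over
[0, 1] jointly with the Brownian root state and variance rate, compared by
AIC against the Λ = 0 model; boundary estimates are reported as such.

The independent-contrasts signal test compares the variance of
standardized contrasts against tip-label permutations (signal pulls the
observed variance down).  The permutation p-value is floored at
1/(n_perm + 1); the analytic mode fits a normal to the permuted
log-variances and reports the normal tail, which resolves the extremely
small p-values that signal-rich datasets produce.  Which variant the
variance-of-contrasts test "should" be is genuinely open; both are
provided and the mode is recorded.

Subtree scans refit the PGLS inside every subtree holding at least 10
terminals of the *reconciled* dataset (covariances re-rooted at the
subtree root), with no multiple-testing correction — a Bonferroni column
is emitted for reference only — and support re-running with a named tip
set excluded to expose trickle-down significance.  Age-truncation subsets
keep clades strictly younger than a cutoff and prune the tree to match.

## Stepwise rate-shift selection

The shift model is a mixture of constant-rate birth-death processes
painted onto the tree: a shift at a node repaints that node's stem edge
and subtree until overridden by a nested shift.  The likelihood combines,
per rate class, P(1→1) transition probabilities over internal edges with
survival-conditioned richness probabilities at the tips.  (The exact
internal-edge treatment at shift points admits several published
variants; this construction — plain 1→1 transitions, shifts taking effect
from the stem edge of the shift node — is the one implemented and tested.)

Search is greedy forward selection.  Each round screens every non-root
node with a cheap refit (the candidate's class optimised one-dimensionally
in net rate at the donor class's relative extinction, and the donor
quick-refitted on its remainder); the top 8 screened candidates get a full
two-dimensional refit of both affected classes and the winner is accepted
if the AICc improves by at least A(N−B)^C + D (coefficients as in the
GEIGER threshold function; N defaults to the tip count and is
configurable).  Screening without the donor refit demonstrably mis-ranks
candidates — with a fast clade planted in a slow background it paints the
background first — hence the two-sided screen.  Ties break to the lowest
postorder node index, so reruns are deterministic.  Parameter count is
np = 3·shifts + 2.  `include_backbone=False` drops the internal-edge
terms, reducing the single-class model exactly to the constant-rate fit
on (richness, stem age) pairs; this is also the right mode when richness
was generated independently of the backbone (as in the planted-shift
recovery studies), since backbone edge lengths then carry no rate signal.

## Two-state higher-taxon simulator

The null model for age-richness rank correlations simulates lineages and
higher taxa jointly.  From two lineages at the crown age, each lineage
waits Exp(β) with β = λ + μ + Φ + α and then speciates (λ), dies (μ),
irreversibly becomes a higher taxon (Φ), or redraws (λ, μ) with
replacement from a fitted rate-class pool (α).  Φ tracks the current λ by
default: a tree of N higher taxa must contain N − 1 backbone speciations,
so the two rates must be roughly balanced for realistic trees.  A taxon
formed at T₁ keeps its parent's rates and draws its present-day richness
from the unconditioned progeny law over T_c − T₁; a zero draw is a taxon
that died before the present.  Lineages reaching the present unconverted
are kept as richness-1 terminals (droppable by flag).  Stem ages are read
from the pruned surviving-terminal tree, exactly as an empiricist must,
because T₁ is unobservable.  Simulations with terminal counts outside
[0.5, 1.5]× the observed count are rejected (bounds configurable), as is
any runaway exceeding 10× the upper bound; fewer than 3 terminals cannot
support a rank correlation and is likewise a rejection.  Lineages are
processed depth-first — event streams are independent, so this equals a
global next-event scheduler but with a reproducible draw order.  The null
p-value is one-tailed lower with a +1 pseudocount.  Whether the crown
start should condition on both root children surviving is unstated in any
source; the implementation conditions only on the rejection bounds, and
the calibration test (p uniform when the observed dataset is itself a
simulation) passes under that choice.

## Relaxed-rate hierarchical model

Clade net rates are i.i.d. LogNormal(m, s) at fixed ε (run at 0 and 0.99,
mirroring the low/high-turnover bracketing); richness given the rate is
the conditioned progeny law at the observed stem age.  Priors (the sources
state none): m ~ Normal(0, 10²), s ~ half-Cauchy(1) — both weakly
informative at the scale of per-My log rates.  The sampler is
Metropolis-within-Gibbs: vectorised element-wise random walks on log rᵢ, a
conjugate Gibbs draw of m, a random walk on log s, and a joint rescale
move (s′ = cs, x′ = m + c(x − m)) whose acceptance ratio reduces to
likelihood × prior(s) × c; the rescale roughly doubles the effective
sample size of s, whose single-site mixing is the bottleneck.  Proposal
scales adapt every 100 iterations during burn-in and freeze afterwards,
keeping the retained chain Markovian.  Defaults are 2 chains × 20,000
iterations, 50% burn-in, thinning 10 — recovery of (m, s) on 150-clade
datasets is comfortable at half that length, and heavier runs are one
setting away.  Diagnostics: split-R̂ on m and s across chains and an
initial-positive-sequence ESS.

Posterior-predictive simulation redraws clade rates from LogNormal(m, s)
at sampled hyperparameter states (a flag switches to the conditional
variant reusing the fitted per-clade rates), simulates richness on the
fixed tree and ages, refits the PGLS slope per draw, and reports
SES = (β_obs − mean β_sim)/sd β_sim with both the empirical tail
(fraction of simulated slopes ≤ observed) and its normal approximation,
since either convention is defensible for the parenthetical tail value.

## Robustness studies

*Type-I error under pure signal.*  Log-richness is evolved by Brownian
motion on the (Λ-transformed) tree — heritable clade size, zero age
effect — and each replicate is regressed on the true stem ages by OLS and
PGLS(BM).  Tree shape matters enormously here: on single-level Yule trees
OLS rejects ~11% of the time at Λ ≈ 0.7, far short of the severe
miscalibration seen on real supertrees.  The `two_level` synthetic
backbone (an old Yule backbone of ~10 deep lineages, each carrying a young
radiation, root age 400 My) reproduces the structure of assembled
higher-taxon timetrees — few ancient splits, many recent ones, strong
covariance clumps — and there OLS rejects ~45% of replicates at
Λ = 0.724 while PGLS holds ~5% when the generating Λ is 1.  PGLS
analysing Λ < 1 data with a BM covariance over-corrects and is
conservative; that direction of error is harmless for the package's
purpose and is reported as-is.

*Clade-age error.*  Richness is drawn (survival-conditioned) at fixed
ages; the ages are then perturbed by Normal(0, (δ·age)²) for δ in
0.1–0.6, resampling — not clipping — any non-positive value, which skews
the perturbed ages upward at large δ exactly as the truncated error model
implies (a 100-My clade at δ = 0.6 has nominal 95% bounds 0 and 217.6).
The Pearson correlation of perturbed age with log-richness (Spearman
optional) is summarised per δ; under high-turnover rates (λ = 0.71,
μ = 0.64) on 330 clades the δ = 0.6 distribution stays almost entirely
positive — age error degrades but does not destroy a true age-richness
relationship.

## Synthetic data: what it does and does not emulate

The generators produce ultrametric backbone trees (Yule, birth-death, or
two-level; exact tip counts, strictly positive pendants via a final
exponential hold) and richness under four models: `constant_rate`
(age-richness coupling at its strongest), `lognormal_relaxed` (coupling
diluted by rate spread), `bm_signal_only` (heritable clade size,
age-independent by construction; the unrounded log values are kept in the
ground-truth record because regression studies should see the continuous
variable while pipeline stages need integer richness, floored at 1), and
the full `higher_taxon_process`.  Ground-truth records contain the seed
and every latent draw, so datasets replay exactly.

What passing tests on these data do **not** show: the generators draw
clade boundaries from clean stochastic processes, so they contain none of
the taxonomic artefacts of real higher-taxon compilations —
human-delimited "higher taxa" of wildly uneven rank, richness counts of
varying quality, non-random incomplete sampling, or correlated age
uncertainty.  Results on synthetic data validate the machinery, not the
biology of any particular empirical compilation.

## Problem sizes

Defaults used by the test suite and the acceptance script: trees of
40–300 tips; 400–500 Monte-Carlo datasets for Type-I error; 50 replicates
for recovery studies (planted 10× shift in a 40–80-tip clade of a 200-tip
tree; (m, s) credible-interval coverage at 150 clades); nulls of 99–400
accepted simulations with ~25–40 terminals.  These sizes reproduce every
qualitative regime of interest; all of them are plain function arguments
and scale up without code changes.

## Known limitations

- No time-varying or diversity-dependent rate likelihoods; the fitted
  models are constant-rate mixtures or i.i.d. rate draws.
- The shift-selection search is greedy with a screened candidate set; it
  is deterministic and recovers planted shifts reliably, but it is a
  heuristic, not an exhaustive model search.
- PGLS treats ages as known; age uncertainty is handled by simulation
  (the δ studies), not by an errors-in-variables estimator.
- The contrasts-test analytic mode rests on a normal approximation to the
  permuted log-variance; its extreme tail is an extrapolation.
- Exact name matching only; no taxonomy-aware synonym resolution.
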