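# Methods

## Model

`fossiltrait` models a single continuous trait evolving along a rooted,
time-calibrated phylogeny whose tips may terminate before the present
(fossil tips). Along a branch of duration `t` the child state is

    x_child ~ N( x_parent + mu0 * t ,  sigma2 * t )

where `sigma2` (squared trait units per Myr) is the Brownian diffusion rate
and `mu0` (trait units per Myr) a directional trend. On an ultrametric
(extant-only) tree `mu0` is unidentifiable — a trend trades off exactly
against the root state, since every tip sits at the same distance from the
root — which is why the trend is only estimated when fossil tips are
present; otherwise it is fixed to 0 by default.

Both parameters may *shift* on the tree: a shift anchored at a non-root node
assigns a new value to the branch subtending that node and to all descendant
branches, until overridden by a nested shift. Every non-root node (2n − 2 of
them on a binary tree of n tips) is an eligible anchor, and rate and trend
shifts are anchored independently.

The likelihood is *augmented*: the states at internal nodes are explicit
parameters, and the likelihood is the product over branches of the normal
density above. No root-state prior term is included (flat prior), there is
no measurement-error term on tip values, and zero-length branches (sampled
ancestors — fossils placed as direct ancestors, represented as labelled
degree-2 nodes) contribute no density; their observed value simply fixes the
state of that node.

## Sampler

One MCMC iteration performs, in order:

1. **Birth–death move over shift configurations.** A continuous-time
   birth–death process on model space is simulated for one unit of virtual
   time: births occur at rate `beta = 1` (the kind, rate vs trend, is chosen
   with probability 1/2; the anchor uniformly among eligible non-root nodes;
   the value from its prior — exponential for rates, N(0, 1) for trends);
   each existing shift dies at rate
   `delta_j = L(without j) / L(with j)`,
   the ratio of augmented likelihoods, where "without j" reassigns the
   shift's clade to the current value of its parent class (nested shifts are
   preserved). Shifts that improve the fit are nearly immortal; shifts that
   do not are removed almost immediately. Waiting times are exponential with
   rate `beta + sum(delta_j)`; at most `max_events = 100` events are
   executed per iteration. Death rates are computed in log space and capped
   at `e^40`.

   The bare likelihood ratio is the default (`policy="likelihood_only"`).
   The alternative `policy="stephens"` multiplies `delta_j` by
   `beta_kind / lambda`; that constant is the exact detailed-balance
   correction when births draw values from the prior, and it makes the
   no-data stationary distribution of the per-kind shift count exactly
   Poisson(`lambda` = 1) — the property the prior-recovery test checks. The
   bare ratio is equivalent to halving the prior mean number of shifts per
   kind, i.e. it is slightly more parsimonious; empirically this is what
   keeps the posterior mode of the *total* shift count at 0 on homogeneous
   data (two independent ~Poisson(1) counts would make a total of 1 the
   single most probable value).

2. **Metropolis–Hastings updates of the continuous parameters.** Every rate
   class (background plus each rate shift) receives a multiplier proposal
   `value * exp(lambda (u − 1/2))` with `lambda = 2 ln d`, `d = 1.5`, and
   log-Hastings `ln m`. Every trend class receives a symmetric sliding-window
   proposal of width `w = 0.5 * sd(tip values)`. The root state receives a
   sliding window of width `4w` (flat prior, pure likelihood ratio); the
   wider window keeps its acceptance rate in the usual working range, the
   root conditional being much narrower than the tip-value spread. Widths
   are fixed (no adaptation) for reproducibility.

3. **Gibbs sweep of ancestral states.** The full conditional of an internal
   state is the product of three normal densities — ancestor
   `N(x_parent + mu0 t1, sigma2 t1)` and the two descendants
   `N(x_child − mu0 t, sigma2 t)`, each with its own branch-resolved
   parameters — which is itself normal (precision-weighted mean). Each
   unobserved internal non-root state is redrawn directly from this
   conditional in post-order (tips first), which propagates tip information
   rootward within one sweep. Direct conditional draws are what make the
   cost per iteration linear in the number of tips.

Priors: exponential on `sigma2` with rate `1 / (Var(tips) / height)`
(weakly informative, scale-matched to the data); N(0, 10) on trend
parameters; Poisson(1) on the number of shifts of each kind; flat on the
root state. New shift *values* are drawn from an exponential with mean
`Var(tips) / height` for rates — a fixed, data-scaled prior rather than one
tied to the current background value, so the prior does not move during the
run — and from N(0, 1) for trends (deliberately narrower than the N(0, 10)
estimation prior; both constants follow the sampler's design).

Initialisation: one class, `sigma2 = Var(tips) / height`, `mu0 = 0`, root
and internal states at the mean observed value of each node's clade.
Defaults: 200,000 iterations, sampling every 100, 25% burn-in. Chains are
bit-reproducible given a seed; replicate analyses over a posterior sample of
trees derive per-tree seeds from the master seed.

The inner loop is compiled with numba over flat node-indexed arrays. The
pure-Python operations (`bm_likelihood`, `ancestral_gibbs`, `shift_bdmcmc`)
implement the same computations one step at a time; the test suite checks
the kernel's recorded log-likelihoods against the Python reference at
sampled states exactly, and the whole sampler against a marginal
multivariate-normal oracle on small trees.

## Synthetic data

The simulator emulates the validation design: forward birth–death trees
(birth 0.25/Myr, death 0.15/Myr) conditioned on a target number of living
lineages, with extinct lineages retained as fossil tips at their true
extinction times. A fixed number of fossils (20, 5, 1 or 0) is kept by
uniform subsampling; incomplete present-day sampling keeps a uniform
fraction of extant tips. There is no preservation model: fossil ages are
exact extinction times, and fossil counts are set by design rather than by a
sampling rate.

Traits are evolved on the *pruned* (analysis) tree. For shift-free Brownian
motion the marginal law of the retained nodes is identical to simulating on
the complete tree and pruning afterwards; doing it on the analysis tree
makes the true ancestral states, parameters and shift count well defined at
exactly the nodes the sampler estimates, which is what the recovery metrics
need.

Scenario parameters (per replicate): `sigma2 ~ U(0.1, 1)`;
`mu0 = ±U(0.2, 1) * sqrt(sigma2)` in trended scenarios; true rate shifts
multiply the background rate by 10 (alternating increase/decrease when there
are two), anchored at internal nodes whose clades hold 15–40% of the tips
and are mutually disjoint. Scenario sizes: 50 extant + 20 fossil tips for
the main grid; 200 extant taxa with 44% retained plus 20 fossils for the
platyrrhine-sized setting. These ranges are this package's stand-ins where
the original per-scenario settings are not published in the main text; with
them, recovery of a rate *decrease* is noticeably harder than of an increase
(the Kullback–Leibler signal of a ÷10 shift is several times smaller than
that of a ×10 shift), which is the main driver of imperfect shift-count
recovery in the two-shift scenario.

What passing these simulations does *not* show about real data: there is no
topological or age uncertainty (the analysis tree is the true tree), no
measurement error or intraspecific variance on tip values, no preservation
bias in which lineages become fossils, and trait values are exactly
Brownian. Empirical applications should run replicate chains over a
posterior sample of trees (`run_replicates`) and treat clade-level summaries
(which tolerate topological variation by re-locating each clade's MRCA per
tree) as the robust output.

## Accuracy metrics

Point estimates are posterior means after burn-in. The tree-level rate and
trend estimates average the branch-resolved parameter over branches and
samples (identical to the class value under a homogeneous configuration).
MAPE = mean |est − true| / |true| (rates); MAE = mean |est − true| (trends).

Ancestral-state accuracy is reported as the coefficient of determination of
the regression of posterior-mean states on true states (the squared Pearson
correlation, `r_squared_fit`). This is deliberate: when the estimator is
biased by design — trend-free reconstruction of trended data on an
extant-only tree — the raw `1 − SS_res/SS_tot` (also provided, as
`r_squared`) can go negative even though estimated and true states remain
strongly associated, and the regression-based definition is the
reconstruction-accuracy summary this literature reports. Both functions are
exported; the validation harness uses the regression-based one.

Shift recovery scores the posterior mode of the *total* (rate + trend) shift
count against the truth; ties between equally frequent counts resolve toward
the smaller count (parsimony).

Range-through-time summaries interpolate posterior-mean states linearly
along each branch (the Brownian conditional expectation between two known
endpoints is linear in time), take the min/max over all branch segments
crossing each 1-Myr bin, and average the band over replicate analyses.

## Numerical choices and edge cases

- Extant/fossil classification tolerance: a tip is extant if its age is
  within `1e-6 * tree height` of the present (posterior tree samples carry
  floating-point jitter at the present).
- Multifurcations are rejected (the conditional-posterior algebra assumes
  two descendants); degree-2 nodes are accepted as sampled ancestors.
- Death rates: log-space, capped at `e^40`; a birth with no eligible anchor
  is a no-op; a birth–death step exceeding 100 events aborts with a warning,
  keeping the last configuration.
- `sigma2 = Var(tips)/height` floors at 1e-8; window width falls back to 0.5
  when tip values are constant.
- Tie-break in the posterior-mode count: smallest most-frequent value.

## Problem sizes used in the shipped validation runs

The acceptance script and the acceptance tests run a scaled-down replication
of the validation study: 10–15 replicates per scenario and 200,000-iteration
chains (sampling every 100, 25% burn-in), against 100 replicates and
5-million-iteration chains in the original design. These sizes are the
package's defaults for a desk-scale reproduction; all reported numbers are
computed fresh from simulation at run time.
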