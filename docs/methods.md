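# Methods

This note documents the models implemented in `montane`, the choices made
where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## Time axis and data model

All analyses run on dated, ultrametric, strictly bifurcating species
trees with branch lengths in Ma. Time is measured backward from the
present (Ma BP): tips sit at age 0 and the crown node at the crown age.
Validation enforces bifurcation, non-negative branch lengths, unique tip
labels, and ultrametricity within an absolute tolerance (default 1e-6 Ma,
configurable) that absorbs the floating-point jitter typical of posterior
tree samples; tip ages are snapped to exactly 0 afterwards. Polytomies
are rejected rather than silently resolved, because both likelihoods
assume binary cladogenesis and silent resolution would distort node
counts. Incomplete sampling enters as a clade-level sampling fraction
f = sampled/known species, a data property that is never shared or
estimated.

## Birth-death models of diversification tempo

Five nested parameterizations of the speciation rate lambda(t) and
extinction rate mu(t) are supported: both constant; lambda or mu
exponential in a paleotemperature proxy T(t), e.g.
lambda(t) = lambda0 * exp(alpha * T(t)); and lambda or mu exponential in
age, lambda(t) = lambda0 * exp(gamma * t). Because t increases into the
past, gamma > 0 means faster speciation in the past; the sign of alpha
and beta is interpreted relative to the declared proxy orientation
(whether larger proxy values mean warmer or colder is user-declared,
never guessed, since delta-18-O series are inversely related to
temperature).

The likelihood integrates the standard backward system

    dE/dt = mu - (lambda + mu) E + lambda E^2,        E(0) = 1 - f
    dD/dt = -(lambda + mu) D + 2 lambda D E,          D(0) = f at tips

multiplying the incoming D's and lambda(t_node) at every internal node
(the root included). Because the D equation is linear given E, the
whole-tree log-likelihood reduces to sums of
Psi(t) = int_0^t [-(lambda + mu) + 2 lambda E] ds over the branching
times; a compiled fixed-step RK4 kernel (default step 0.005 Ma) returns E
and Psi on the node-age grid in one pass. By default the likelihood is
conditioned on crown survival, dividing by
lambda(t_crown) (1 - E(t_crown))^2; the flag is recorded and held fixed
across compared models, so AIC differences never depend on it. The
constant-rate case was checked against an independently coded closed form
(and spot-checked against `ape::birthdeath`, which agrees to four
decimals); the kernel's step error is orders of magnitude below the 1e-6
oracle tolerance used in the tests.

Fitting maximizes the likelihood with a Nelder-Mead simplex in
log-rate space (sensitivities on the identity scale), with multi-start:
one method-of-moments start plus lognormal-jittered replicates
(about +/-50% on rates), all seeded and logged. Model support is
summarized as AICdiff = AIC(null) - AIC(focal) for the nested
constant-rate null: -2 means the extra parameter bought no likelihood,
values above 2 are read as substantial support. When a focal model is
compared to a fitted null, the null solution (sensitivity 0) is supplied
as an extra start, which guarantees the nesting inequality numerically.

### Multi-clade sharing

Treating each clade as an independent realization of shared dynamics, the
joint likelihood is the product of per-clade likelihoods at one shared
parameter vector (sampling fractions and crown ages stay clade-specific).
The lineage-specific "combination" model is the same joint model with all
parameters clade-specific, so its AIC is the sum of per-clade AICs and
the shared model is nested within it with df = k (m - 1) for m clades
(df = 10 for the two-parameter model over six clades). The shared
solution seeds every lineage-specific fit, so a specific combination can
never fit worse than the shared model; a violation raises rather than
being reported. Phylogenetic uncertainty is handled by refitting on
posterior tree draws, pairing trees across clades by draw index (the
clade posteriors are independent, so the pairing is arbitrary but must be
fixed); the per-draw AICdiff table and its median are reported, and a
batch aborts if more than 20% of draws fail.

## Multi-region cladogenetic model (generalized GeoSSE)

A lineage's state is the non-empty subset of n regions (or two bedrock
types / elevation belts) it occupies: 2^n - 1 states, 31 for the five
European mountain regions, ordered by subset size then lexicographically.
Rates: within-region speciation s_i for each occupied region (daughters
{i} and S); total state-change (vicariant) speciation s_x for widespread
lineages; range expansion ("migration") d_ij from occupied i to
unoccupied j; extirpation x_i (extinction when the lineage is endemic).
For n = 2 this is exactly the three-state GeoSSE model, which was the
binding constraint on the generalization: the total rate s_x is split
uniformly over the 2^(|S|-1) - 1 unordered bipartitions of S, which
reduces to GeoSSE's between-region speciation at |S| = 2. Migration in
the reported tables always refers to the anagenetic range-expansion rates
d, not extirpation.

The likelihood integrates per-state (E_S, D_S) along every branch
(compiled RK4 kernel, default step 0.01 Ma, with per-branch rescaling of
D against underflow) and applies the symmetrized cladogenetic combination
at nodes. Tips start at D = f for the observed state and E = 1 - f in
all states: sampling is assumed uniform across states because
state-specific sampling fractions are unavailable. Root states are
weighted proportionally to their likelihoods (FitzJohn weighting);
survival conditioning is available but off by default, and both choices
are held fixed across compared models. The two-region likelihood is
verified against an independently coded direct integration of the full
six-equation system, and the degenerate single-region case against the
birth-death likelihood.

Models within the family are defined by named constraints -- s equal
across regions or free, s_x zero or free, x equal or free, d equal /
symmetric / free -- and four standard AICdiff tests free or constrain one
feature each: state-change speciation (df 1), per-region speciation
differences (df n-1), extinction differences (df n-1), migration
directionality (df n(n-1)/2). The fully constrained two-region model has
three parameters (s, x, d). Fine-scale geography (87 units) is never fit
with this machinery: the state space grows as 2^n, and n is capped at 8
(ODE dimension 510); fine-scale questions are answered by the overlap
analysis instead.

The best model can be rerun in a Bayesian setup with a univariate slice
sampler (stepping-out and shrinkage) cycling over the free rates,
started at the ML fit. Priors are independent exponentials; by default
the prior mean is twice the clade set's crude Yule rate estimate, a
weakly informative scale-aware choice recorded with the chain. Marginal
ancestral states are computed by recomputing the likelihood with each
internal node restricted to each state, holding the root weights fixed at
the unrestricted run's values; rows normalize to 1 and the two-tip case
matches exhaustive enumeration. The proportion of state-change
speciation events is a standing-flora average: present-day species counts
per state weighted by their states' speciation rates, with the s_x share
of the total flux as the state-change proportion.

## Sister-species overlap

For every cherry (sister pair), Schoener's D is computed along four
dimensions: fine geography (87 operational units), coarse geography
(units aggregated to 5 regions by a mapping that covers each unit exactly
once), bedrock, and elevation belt. Binary occupancy vectors are
normalized to proportions -- uniform weight over occupied categories,
the presence/absence convention for this index, with "both" generalists
as (1,1) -- and D = 1 - 0.5 sum|p_i - q_i|, computed via the equivalent
sum-of-minima form so that disjoint ranges give exactly 0 (zero overlap
is a categorical event and is tested without tolerance). Summaries report
the median D and the proportion of zero-overlap pairs per dimension,
pooled and per lineage; pairs lacking data in a dimension are dropped and
reported by name.

## Synthetic data and validation experiments

The generators produce data with the statistical structure the analyses
assume, not the biology of any real clade:

* Birth-death trees are simulated forward from two crown lineages;
  time-varying rates use thinning at the rate's upper bound (exact for
  bounded rates, trivially correct for piecewise-linear proxies).
  Extinct lineages are pruned, survivors subsampled binomially at f, and
  the run is conditioned on at least two sampled survivors. For
  recovery experiments an optional stronger conditioning accepts only
  runs in which both crown lineages leave sampled descendants, matching
  the crown conditioning of the likelihood; without it (and especially
  under tip-count stopping) the extinction MLE is upward-biased by
  design-model mismatch, not by an estimator defect.
* The multi-region simulator is a Gillespie algorithm drawing events from
  exactly the rates that define the likelihood, including the bipartition
  convention for vicariant splits.
* The synthetic paleocurve is a linear cooling trend over 40 Ma with a
  seeded sinusoid-plus-noise oscillation confined to the last 2.6 Ma, on
  a "larger is warmer" orientation.
* Occupancy tables plant an exact number of fully disjoint cherry pairs
  at the fine scale (the requested allopatric fraction must be a whole
  number of cherries), all other cherries sharing at least one unit.

The six-clade template mirrors the study system: known richnesses
(29, 50, 35, 27, 24, 86), sampling fractions (26/29, 45/50, 28/35, 1, 1,
62/86), and crown ages drawn within each clade's credibility window
(4.7-10.7, 10.1-16.5, 6.4-28.5, 13.7-24.5, 3.2-7.9, 12.5-38.1 Ma).

The sensitivity experiment parameterizes a Pleistocene slowdown as a step
at 2.6 Ma BP acting through a 0/1 temperature covariate: the speciation
rate drops to a chosen fraction of its Tertiary value, and the same step
covariate is supplied to the fitted temperature-dependent model, so the
fitted family can represent the simulated signal exactly. This is the
minimal faithful stand-in for a full proxy-driven design. Per-clade
Tertiary rates are set from each template clade's richness and drawn
crown age (net rate r = ln(N/2)/T with extinction at 20% of speciation),
so simulated datasets have realistic sizes. Power is the fraction of
replicates in which the shared temperature model beats the constant-rate
null by more than 2 AIC units; the drop-factor-1.0 row measures the
false-positive rate.

Passing these experiments shows that the estimators recover the rates
and orderings they were given under the model's own assumptions at the
study's data sizes. They do not address model misspecification (real
clades violate constant rates, uniform sampling within states, and
maternal-lineage tree assumptions), nor identifiability limits shared by
all time-dependent diversification models, which are mitigated here only
by restricting to five explicit hypotheses.

## Numerical choices

* RK4 step sizes: 0.005 Ma (birth-death) and 0.01 Ma (multi-region
  model) by default; the power experiment uses 0.02 Ma and the assembly
  demonstrations 0.05 Ma, where rates of order 0.1-1 per Ma make the
  integration error (fourth order in the step) negligible against AIC
  differences of order 1. E is clamped to [0, 1] against roundoff drift;
  D is renormalized per branch with the log factor accumulated.
* Optimizer: Nelder-Mead, xatol 1e-6, fatol 1e-8, up to 400 k iterations
  for k free parameters; non-convergence of every start is flagged, never
  silently reported.
* Degenerate inputs: all-zero occupancy vectors, empty region sets,
  non-nested model pairs, and zero speciation flux in the state-change
  proportion raise immediately rather than returning NaN.
* Determinism: every stochastic routine takes a mandatory seed, derived
  streams use `numpy.random.default_rng`, and identical configurations
  byte-reproduce outputs (asserted in the tests).

## Known limitations

* Extinction rates from reconstructed phylogenies are weakly identified;
  on pure-birth data the extinction MLE sits at the zero boundary in only
  about half of replicates (verified against an independent reference
  implementation), so single-clade extinction estimates should be read as
  order-of-magnitude.
* The vicariant-split convention for ranges of three or more regions
  (total rate, uniform over bipartitions) is one of several defensible
  generalizations; it is configurable in principle and recorded in
  outputs, and only the two-region case is pinned by the GeoSSE
  equivalence.
* The state-change proportion weights rates by present-day counts, not by
  the reconstructed history; it is a standing-flora summary.
* Posterior-tree batching treats draws as exchangeable and ignores
  cross-clade dependence (none exists if clade posteriors are
  independent).
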