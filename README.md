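# montane

Multi-clade models of diversification tempo and biogeographic assembly
for mountain plant radiations.

## The problem

Temperate alpine floras — the European mountain system in particular —
pose a set of linked questions: did Pleistocene cooling slow plant
speciation? Were speciation events driven by geographic isolation, by
bedrock shifts (calcareous vs siliceous), or by divergence across
elevation belts? And how much did lineages *move* along those gradients
rather than speciate across them? Answering these questions for several
clades at once requires comparable dated phylogenies and a comparative
framework that can pool information across clades. `montane` implements
that framework for dated, ultrametric species trees with incomplete
sampling:

1. **Diversification tempo.** Five nested birth–death models on a
   backward time axis t (Ma BP): constant rates; speciation or extinction
   exponential in a paleotemperature proxy, e.g.
   λ(t) = λ₀·exp(α·T(t)); or exponential in time, λ(t) = λ₀·exp(γ·t).
   Likelihoods follow the standard E/D backward ODEs with sampling
   fraction f, are fitted by simplex in log-rate space, and are compared
   by AICdiff = AIC(null) − AIC(focal) against the constant-rate null
   (−2 ⇒ the extra parameter bought nothing; > 2 ⇒ substantial support).
   A multi-clade mode multiplies per-clade likelihoods at one shared
   parameter vector and compares shared against lineage-specific fits,
   with posterior-tree batching for phylogenetic uncertainty.
2. **Evolutionary assembly.** A generalized multi-region GeoSSE (ClaSSE)
   model whose states are the non-empty subsets of n regions (3 states
   for two bedrock types or elevation belts; 31 states for 5 geographic
   regions): within-region speciation s_i, state-change (vicariant)
   speciation s_x of widespread lineages, range-expansion "migration"
   d_ij, and extirpation x_i. Includes ML fitting under named constraint
   sets, the four standard AICdiff feature tests, a slice-sampling MCMC
   rerun for credibility intervals, marginal ancestral states, and the
   state-change speciation proportion.
3. **Sister-species overlap.** Schoener's D
   (D = 1 − 0.5·Σ|p_i − q_i| over normalized occupancy vectors) for every
   sister pair along fine geography (87 units), coarse geography
   (5 regions), bedrock, and elevation, with zero-overlap proportions as
   the signature of speciation along each dimension.
4. **Validation machinery.** Seeded simulators (thinning for
   time-varying birth–death, Gillespie for the multi-region model,
   synthetic paleocurves and occupancy tables) and a sensitivity
   experiment measuring the power to detect a Pleistocene speciation
   drop. See `docs/methods.md` for model details and assumptions.

## Worked example

```python
import numpy as np
from montane import (BDModelSpec, CladeData, GeoSSEParams, aicdiff,
                     fit_bd, sim_bd_tree, sim_geosse_tree)
from montane.geosse import Constraints, fit_sse

# a clade simulated with lam=0.4, mu=0.1 over 10 Ma, refitted
tree = sim_bd_tree(lam=0.4, mu=0.1, crown_age=10.0, f=1.0, seed=7)
fit = fit_bd(CladeData(tree=tree), BDModelSpec("BCST_DCST"), seed=0)
print(tree.n_tips, round(fit.params["lambda0"], 3),
      round(fit.params["mu0"], 3), round(fit.lnl, 2))
# 33 0.333 0.0 -65.12

# two-region assembly: simulate 4:1 migration asymmetry, recover its sign
gen = GeoSSEParams(n=2, s=np.array([0.3, 0.3]), sx=0.1,
                   x=np.array([0.05, 0.05]),
                   d=np.array([[0.0, 0.2], [0.05, 0.0]]))
clades = [sim_geosse_tree(gen, root_state=(0,), n_tips=40, f=1.0, seed=100 + s)
          for s in range(6)]
sse = fit_sse(clades, Constraints(d_mode="free"), seed=0, h=0.05)
print(round(sse.params.d[0, 1], 3), round(sse.params.d[1, 0], 3))
# 0.212 0.059
```

The first block prints the tip count, the refitted speciation and
extinction rates, and the log-likelihood for one simulated clade: the
truth was 0.4 and 0.1, and the extinction estimate lands on the zero
boundary — extinction is weakly identified from single reconstructed
trees, which is why the multi-clade machinery exists. The second block
recovers the direction and rough magnitude of the simulated migration
asymmetry (d̂_AB = 0.212 > d̂_BA = 0.059, truth 0.2 vs 0.05) from a
shared fit across six 40-tip clades.

The `analysis/` directory holds the narrative pipeline on a synthetic
six-clade system mirroring the study template (sizes, sampling fractions
and crown-age windows): `01_simulate_dataset.py` builds it, `02` runs the
five-model tempo selection, `03` the bedrock assembly tests + MCMC + ASR,
`04` the sister-overlap summary, `05` the detection-power grid. Each
writes its tables under `results/` and prints what it found.

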