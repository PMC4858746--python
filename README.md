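# mimevol

Spatial and phylogenetic analyses of Batesian mimicry evolution, built to
run end-to-end on synthetic data with known ground truth.

Coral snakes (Elapidae) are venomous "models" whose red–black banded (RBB)
warning pattern is imitated by many harmless New World colubrids. Testing
that hypothesis at continental scale needs two kinds of machinery, both of
which this package provides for Python users (systematists, macroecologists
and method developers):

1. **Spatial co-occurrence** — build species range polygons from occurrence
   records (alpha hull / convex hull / point buffer by record count), clip
   them to a coastline, rasterize presence on 2° or 0.5° grids with an
   inclusive 50%-coverage rule, and ask whether model richness predicts
   mimic richness using (a) simultaneous-autoregressive error regression,
   *y = Xβ + u*, *u = λWu + ε*, with distance-band neighbor weights grown
   in 50-km steps and selected by AIC, and (b) a permutation null that
   shuffles the species identity tags of all non-model range polygons —
   preserving every range shape, the per-cell richness totals and the model
   raster exactly — with the one-tailed *p* the fraction of null slopes at
   or above the observed slope.
2. **Phylogenetic trait history** — model the binary color pattern
   (0 cryptic, 1 RBB) as a two-state Markov process with gain rate *q01*
   and loss rate *q10* per Myr, find clades with decoupled rates by a
   stepwise-AIC shift search (an *m*-matrix model costs *k = 2m + (m−1)*
   parameters; shifts accepted at ΔAIC > 2), estimate rates by MCMC under
   exponential priors centered at 10× the whole-tree symmetric ML rate,
   draw stochastic character maps (exact endpoint-conditioned branch
   histories by uniformization), and project every gain and loss onto
   latitude via Brownian-motion ancestral midpoints and the linear
   interpolation δ·s_x + (1−δ)·s_y along branches.

A synthetic-data layer (`simulate_yule_tree`, `simulate_discrete_history`,
`simulate_bm_latitude`, `simulate_virtual_biogeography`) generates trees,
trait histories, latitudes and a virtual continent with a planted
model→mimic richness coupling, so every stage can be validated against
parameters you chose.

## Worked example

```python
import mimevol as mv

tree = mv.simulate_yule_tree(n_tips=80, birth_rate=0.05, seed=21)
model = mv.PartitionModel([mv.RateMatrix2(q01=0.01, q10=0.05)])
traits, truth = mv.simulate_discrete_history(tree, model, 0.0, seed=22)

prior = mv.PriorSpec.from_whole_tree_rate(tree, traits)
posterior = mv.mcmc_rates(tree, traits, model, prior, n_steps=20000, seed=23)
ensemble = mv.sample_map_ensemble(tree, traits, model,
                                  posterior=posterior, n_maps=500, seed=24)
summary = mv.summarize_ensemble(ensemble, n_time=1000)
```

Running `python examples/03_stochastic_mapping.py` (which is this analysis)
prints:

```
13/80 tips in the banded state
whole-tree symmetric ML rate: 0.0063/Myr -> prior mean 0.0635
posterior mean rates: q01=0.0110, q10=0.0483 per Myr (truth 0.01, 0.05); ESS [1338. 1183.]
posterior gains per map: 16.1 (truth 17); losses: 14.7 (truth 10)
trait frequency at the present: 0.1625 (observed tip frequency 0.1625 -- equal by construction)
maximum-credibility configuration: 8 gains, 1 losses (map 48)
```

The posterior rate means (0.0110, 0.0483) bracket the generating values
(0.01, 0.05), the ensemble's mean gain count per map (16.1) sits next to
the 17 gains of the true simulated history, and the
frequency-through-time curve ends exactly at the observed tip frequency
(a structural property of conditioning the maps on tip states). The
maximum-credibility map is sparser than the posterior mean because it
favors the per-branch event configurations that recur most often across
the ensemble.

The other scripts in `examples/` each demonstrate one capability: trait
simulation (01), the rate-shift search (02), range building and
rasterization (04), the SAR + permutation co-occurrence tests (05), and
the latitudinal gain/loss reconstruction with the contrasts-based
conservatism test (06).

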