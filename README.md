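# dietmix

Dual diet analysis for marine top predators, parameterised for
bottlenose dolphins (*Tursiops truncatus*) in the Gulf of Cadiz: what a
predator *ingested*, from the hard parts left in stomachs, and what it
*assimilated*, from the stable-isotope composition of its tissue.

The package is for trophic ecologists who need both halves of that
picture with honest uncertainty: stranding-network stomach datasets are
tiny (13 stomachs here), so index estimates need bootstrap confidence
limits; and isotope mixing models silently produce answers even when
the source geometry cannot explain the consumers, so the model design
needs an explicit mixing-polygon check before its posteriors are
believed.

## What it computes

**Stomach contents.** Hard-part records (otoliths, bones, cephalopod
beaks) are converted to prey counts (each otolith = 0.5 fish; highest
estimate across structures wins) and to lengths and weights through
allometric regressions. Per taxon the package reports

- %N, %O, %W — share of prey numbers, of stomachs, of reconstructed weight,
- IRI = (%N + %W) × %O — the Index of Relative Importance (0–20,000),
- %P_i — prey-specific abundance (weight share over only the stomachs
  containing taxon *i*), paired with %O for the Amundsen–Costello
  feeding-strategy diagram,

with confidence limits from bootstrap resampling of whole stomachs.

**Stable isotopes.** Prey species are Ward-clustered into isotopically
coherent source groups and pooled exactly; a Bayesian mass-balance
mixing model then estimates the diet proportions **p** on the simplex:

x<sub>ij</sub> ~ Normal( Σ<sub>k</sub> p<sub>k</sub>(μ<sub>kj</sub>+λ<sub>kj</sub>),
√( Σ<sub>k</sub> p<sub>k</sub>²(σ<sub>kj</sub>²+τ<sub>kj</sub>²) + ξ<sub>j</sub>² ) )

with Dirichlet(1) prior on p, uniform priors on the residual scales
ξ<sub>j</sub>, and TDF-corrected sources (λ ± τ is a required input).
Sampling is adaptive random-walk Metropolis on additive-log-ratio
coordinates; convergence is monitored with split-chain R̂. A
Monte-Carlo mixing-polygon simulation (random source polygons from the
combined source + TDF uncertainty) verifies that every consumer is
covered by at least 5% of simulated polygons — the 95% mixing region —
before the posterior is taken seriously.

A synthetic-data module generates both kinds of dataset with known
ground truth (the stomach generator is exactly invertible by the
reconstruction rules; the isotope generator samples the model's own
likelihood), so the full pipeline is testable without any field data.

## Worked example

```python
import numpy as np
from dietmix import diet_indices as di, gulf_cadiz as gc
from dietmix import synthetic_data as sd, mixing_model as mm, mixing_polygon as mp

# --- stomach-content side: published raw inputs -> reporting-mode indices
row = di.diet_row(215, gc.TOTAL_PREY, 8, gc.N_STOMACHS,
                  50603.24, gc.TOTAL_WEIGHT_G, mode="reporting")
print("Congridae:", row)

# --- isotope side: synthetic 51-consumer dataset from the four source
#     groups, validated and fitted
config = sd.default_gulf_config(tdf_means=(1.0, 1.6), tdf_sds=(0.4, 0.5),
                                true_proportions=(0.5, 0.3, 0.15, 0.05), seed=404)
dataset = sd.simulate_isotope_dataset(config)
data = config.to_mixing_data(dataset.records[["d13C", "d15N"]].to_numpy())

result = mp.consumer_probabilities(dataset.records, data,
                                   mp.PolygonSimConfig(n_iter=1500, seed=1))
print("polygon pass:", mp.validate_design(result)["passed"],
      "| min inside-probability:", result.probabilities.probability.min())

post = mm.run_mcmc(data, mm.ModelConfig(seed=505))
print(mm.summarize_posterior(post)[["source", "mean", "median", "lo95", "hi95"]]
      .round(3).to_string(index=False))
print("max R-hat:", round(mm.posterior_rhat(post).max(), 4))
```

prints

```
Congridae: {'pctN': 21.48, 'pctO': 61.54, 'pctW': 35.18, 'IRI': 3486.86}
polygon pass: True | min inside-probability: 0.3566666666666667
 source  mean  median  lo95  hi95
Group 1 0.520   0.521 0.443 0.596
Group 2 0.304   0.306 0.214 0.387
Group 3 0.135   0.131 0.023 0.255
Group 4 0.041   0.041 0.008 0.077
max R-hat: 1.0398
```

Reading it: conger eel (Congridae) contributes 21.48% of prey items,
occurs in 61.54% of stomachs and carries 35.18% of reconstructed
weight, giving IRI 3486.86 — the dominant ingested fish family. On the
isotope side, every simulated consumer lies comfortably inside the 95%
mixing region (minimum inside-probability 0.36 ≫ 0.05), so the
four-source design is valid; the posterior then recovers the generating
diet (0.5, 0.3, 0.15, 0.05) with every truth inside its 95% credible
interval and all chains converged.

## Command line

Each stage is also a subcommand of `dietmix`:

```sh
dietmix simulate stomachs --config stomachs.yaml --seed 7 --out sim/
dietmix reconstruct --hardparts sim/hardparts.csv --regressions sim/regressions.csv --out occurrences.csv
dietmix indices --occurrences occurrences.csv --n-stomachs 13 --bootstrap 1000 --seed 1 --out indices/
dietmix cluster --isotopes isotopes.csv --k 4 --linkage ward2 --out groups/
dietmix mix --consumers consumers.csv --groups groups/groups.csv --tdf tdf.csv --seed 1 --out mix/
dietmix polygon --consumers consumers.csv --groups groups/groups.csv --tdf tdf.csv --seed 1 --out poly/
```

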