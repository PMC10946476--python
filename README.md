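# bloodmealnet

Analysis of weighted bipartite networks linking blood-feeding Diptera
(mosquitoes, biting midges, tsetse, sand flies, black flies) to their
vertebrate hosts, as compiled from molecular blood-meal surveys. The
package is for vector ecologists and disease ecologists who want to ask
how the structure of fly–host feeding networks varies with latitude and
with anthropogenic land use, and whether humans and domestic animals
reshape that structure.

## What it computes

Each network is a Diptera × host matrix **N** whose cell *n\_ij* counts
the blood meals linking fly *i* to host *j* in one study and habitat
class (Agricultural, Near-natural, Village/Urban). From the matrix the
package computes:

* **Interaction evenness**, IE = *H* / ln *L*, where
  *H* = −Σ *p* ln *p* over the link-weight proportions and *L* is the
  number of links. Both denominator conventions in circulation are
  implemented: realized links (the default) and all matrix cells; every
  output records which was used.
* **Network specialisation H2′** = (*H*₂max − *H*₂) / (*H*₂max − *H*₂min),
  the observed two-dimensional entropy standardised between the minimum
  and maximum entropies achievable by any nonnegative **integer** matrix
  with the observed row/column totals. The extrema come from a
  combinatorial search (proportional fill plus cycle pushes for the
  maximum; multi-start greedy packing plus cycle pushes for the minimum)
  that is provably exact whenever the smaller matrix dimension is ≤ 3 and
  is verified against exhaustive enumeration in the test suite.
* **A targeted-removal null model**: delete humans and domestic animals
  (chickens, dogs, cats, goats, cattle, horses, pigs, sheep) from each
  network, recompute IE, and compare against removal of an equal number
  of randomly chosen host species (default 100 replicates) via a z-score.
* **Incidence-based rarefaction** (Hill number order q = 0) of host,
  Diptera and interaction richness as a function of blood-meal effort,
  with Chao2 extrapolation, to assess sampling completeness per habitat.
* **Habitat/latitude models**: Gaussian GLMs of IE and H2′ on habitat,
  |latitude|, species richness S, log matrix size and dominant Diptera
  family (plus family interactions), nested-model deviance tests, Tukey
  HSD habitat contrasts, and richness-vs-latitude linear models with
  blood-meal count as a sampling-effort covariate.

A Dirichlet-multinomial **synthetic generator** reproduces the structure
of the compiled literature data (47 networks split 14/18/15 across the
three habitat classes, ≈190 blood meals each, agricultural communities
dominated by cattle) so the entire pipeline can be exercised and
calibrated without any download. See `docs/methods.md` for the model and
its assumptions.

## A worked example

```python
import numpy as np
from bloodmealnet.metrics import interaction_evenness, h2_prime

cattle_dominated = np.array([[40, 1], [1, 2]])   # 44 meals, one pair has 40
print(round(interaction_evenness(cattle_dominated), 4))  # 0.2879
print(round(h2_prime(cattle_dominated), 4))              # 0.3840
```

An IE of 0.29 says a single fly–host pair carries almost all interaction
weight — the signature of cattle-dominated agricultural networks. The
H2′ of 0.38 says the network is moderately more specialised than the
random expectation under its marginal totals.

Running the end-to-end pipeline on the synthetic study conditions
(`python examples/06_full_pipeline.py`, equivalently
`bloodmealnet run-all --simulate default --seed 5`) prints

```
47 networks, 9063 blood meals
mean IE by habitat: {"Agricultural": 0.731976, "NearNatural": 0.871669, "VillageUrban": 0.831615}
habitat term on IE: {'X2': 0.0549..., 'df': 2, 'p': 0.00144...}
```

— agricultural evenness sits well below the other habitats and the
habitat term is significant, while the latitude term is not. The other
`examples/*.py` scripts walk through each capability on small inputs.

## Command line

`bloodmealnet` exposes thin subcommands over the library: `validate`,
`build`, `metrics`, `nullmodel`, `rarefy`, `glm`, `simulate` and
`run-all` (YAML config, per-stage CSV outputs, and a `manifest.json`
capturing config and seeds for exact reruns).

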