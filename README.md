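# plovernet

Social-network and breeding-structure analysis for resident shorebird
populations, built around the question: **does who a bird associates
with before breeding predict who it pairs with, where it nests, how its
nest fares, and whether it disperses afterwards?**

The package targets the data regime of a colour-ringed Kentish plover
(*Charadrius alexandrinus*) population: sparse multi-year sighting
streams from repeated non-breeding surveys, socially monogamous pairs,
an August–December breeding season in a handful of discrete habitats,
and strong habitat fidelity between years. It provides:

- **Pre-breeding social networks.** Birds sighted within the same
  10-min sampling period are grouped by a 20 m chain rule (gambit of
  the group: all members of a spatio-temporal group are taken to
  associate pairwise). Dyadic edges are weighted by the simple ratio
  index,

  `SRI = x / (x + y_AB + y_A + y_B)`,

  where `x` counts periods with the dyad grouped together, `y_AB`
  periods with both seen but apart, and `y_A`, `y_B` periods with only
  one seen. Node degree and strength summarise individual sociality.
- **Breeding structure.** Nests are linked when their incubation
  intervals (laying date to incubation end, closed) share at least one
  day; per-nest context covers counts and distances of concurrent
  nests, 100 m neighbourhoods and neighbour success; between-year
  dispersal records capture habitat fidelity and movement distances.
- **Permutation inference.** Three null schemes — data-stream
  (identities shuffled within sampling periods), mate randomisation
  (female identities shuffled among pairs within habitat and season)
  and nest randomisation (location/timing tuples shuffled within
  habitat and season) — wrapped around arbitrary model statistics,
  with two-tailed add-one permutation p-values.
- **A registered model suite** (GLM / mixed models via statsmodels,
  likelihood-ratio tests, VIFs) mapping each analysis to its response
  family, fixed and random terms, and null scheme.
- **A synthetic-data generator** with known effect sizes (pair
  co-location, nest success, success-dependent dispersal) so every
  analysis can be checked for parameter recovery.

## Worked example

```python
from plovernet import analyses, synthetic
from plovernet.config import PopulationConfig

sim = synthetic.simulate_dataset(PopulationConfig(seed=1))
bundle = analyses.build_bundle(sim.sightings, sim.nests)
result = analyses.pairing_permutation_test(
    bundle, n_perm=1000, seed=1, stratum=("year", "habitat"))
```

prints (via `python examples/03_pairing_permutation.py`):

```
observed SRI slope (log-odds): 52.84
null mean +- sd:               -3.88 +- 51.71
two-tailed permutation p:      0.0020 (1000 randomisations)
```

The observed logistic slope of pair formation on SRI is far above the
null distribution obtained by re-pairing birds at random within their
nesting habitat and season, so the simulated pair co-location signal
(q = 0.5) is correctly detected: birds that associated more before
breeding bred together more than habitat fidelity alone can explain.
The `examples/` directory has one short script per capability
(simulation, network construction, pairing test, breeding structure
and dispersal, full pipeline); each prints the numbers it computes and
a line on what they mean.

A thin CLI wraps the same pipeline:

```bash
plovernet simulate --n-individuals 80 --seed 7 --out run/
plovernet analyse --sightings run/sightings.csv --nests run/nests.csv \
    --analyses A2_pairing,A9_stay_prev_success --n-perm 1000 --out run/
plovernet report run/
```

## Layout

```
src/plovernet/
  config.py       population / survey / ground-truth configuration
  synthetic.py    sighting-stream and nest generator
  network.py      chain-rule grouping, SRI networks, node metrics
  breeding.py     incubation overlap, neighbourhoods, dispersal
  permutation.py  null schemes, permutation p-values, test runner
  models.py       GLM / mixed fits, LRT, VIF
  analyses.py     dataset builders + registered analysis suite
  calibration.py  type-I error and power of the pairing test
  pipeline.py     orchestration, validation, manifests
  cli.py          click front end
docs/methods.md   model assumptions, parameters, design choices
examples/         narrative scripts, one per capability
```
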