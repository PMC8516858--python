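# ballmoss

Individual-based simulation of the spread of a selfing, clonally growing
epiphyte — ball moss, *Tillandsia recurvata* — across tree landscapes,
together with the microsatellite summary statistics used to describe its
spatial genetic structure (SGS) and an approximate Bayesian computation
(ABC) layer that calibrates the simulator against observed SSR data.

Ball moss is a weedy bromeliad of dry and deforested landscapes in the
Americas. Its cleistogamous flowers self-fertilise, leaf axils bud new
ramets, and tiny plumose seeds travel on the wind, so populations on
scattered host trees form dense mosaics of inbred clonal lineages. The
package lets you ask how that genetic mosaic develops over colonisation
time, how it varies with tree density, and what abrupt deforestation or
reforestation does to it.

## What is simulated

A rectangular landscape is discretised into 0.01 m² patches carrying
scattered trees (trunk + circular crown). Each plant is one ramet on a
crown patch with a monthly energy budget: it gains `1 − shading` units
per month, pays 0.5 units maintenance, matures at 48 months, reproduces
once (selfed seeds plus one clonal ramet) when holding ≥ 10 units during
the annual reproductive season, and dies at 72 months, at zero energy, or
with its host tree. Seeds fly one patch at a time for up to
`5 × wind_speed` patches; every crown patch crossed captures them with
probability `capture_probability`; captured seeds germinate with
probability `germination_rate` onto free patches (one plant per patch).
Each season, `regional_seed_rain` immigrant seeds with fresh founder
genotypes enter at the landscape edges; every immigrant that establishes
founds a multi-locus lineage (MLL). Genotypes are seven diploid SSR loci
under strict single-step stepwise mutation (rate `mutation_rate` per
transmitted allele).

Five free parameters (seed rain, wind speed, mutation rate, germination
rate, capture probability) carry priors and are estimated by rejection
ABC from six summary statistics — mean alleles per locus *K*, mean
allele-size range *R*, *H*<sub>E</sub>, *F*<sub>IS</sub>, global
Weir–Cockerham *F*<sub>ST</sub>, and the modified Garza–Williamson
*M* = *k*/(*R*+1). The `sumstats` module additionally implements AMOVA,
Loiselle kinship, the *S*<sub>p</sub> statistic
(−*b*<sub>F</sub>/(1−*F*<sub>(1)</sub>)), allele/MLG/MLL turnover,
allelic richness and private alleles, and Mantel isolation-by-distance
tests on linearized *F*<sub>ST</sub>, Edwards, Nei and Reynolds
distances. Landscapes can also change: tree growth (0.13 cm DBH/year),
Yoda −3/2 self-thinning, natural regeneration, and abrupt
deforestation/reforestation events.

## Worked example

Fifty years of colonisation of a ~0.2 ha grove of 20 trees, replicated
five times with the posterior-median parameter vector:

```python
from ballmoss.experiments import run_time_experiment

res = run_time_experiment(replicates=5, years=50, master_seed=7)
print("phases: lag_end", res.lag_end, "log_end", res.log_end)
print("peak abundance      ", round(res.peak_abundance()))
print("individuals per MLL ", round(res.individuals_per_mll_at_peak(), 1))
print("MLLs at end of Log  ", round(res.mll_at_log_end(), 1))
print("max F_ST during Lag ", round(res.max_fst_during_lag(10.0), 3))
```

prints

```
phases: lag_end 13.0 log_end 24.0
peak abundance       12307
individuals per MLL  170.3
MLLs at end of Log   71.0
max F_ST during Lag  0.381
```

Read: the population lingers at low abundance for ~13 years (Lag) while
immigrant lineages accumulate and differentiation among trees peaks
(*F*<sub>ST</sub> ≈ 0.38, each tree dominated by few selfing clones),
then grows logistically (Log) to a plateau of ~12,300 plants — about
170 ramets per founding lineage — as seed exchange among trees erodes
the structure. `res.records` holds the full yearly trajectory
(abundance, MLL/MLG counts, clone fraction, K, R, H_E, F_IS, F_ST, NGW)
per replicate.

Fitting the simulator to an observed statistics vector:

```python
import numpy as np
from ballmoss.calibration import (PriorSpec, ReferenceConfig,
                                  build_reference_table, ABCCalibration)

table = build_reference_table(PriorSpec(), 2000, ReferenceConfig.reduced(),
                              np.random.default_rng(0))
observed = dict(K=3.2, R=2.8, H_E=0.45, F_IS=0.75, F_ST=0.25, NGW=0.83)
fit = ABCCalibration(observed, table).fit(tolerance=0.01)
print(fit.summary())
```

The `ballmoss` command line wraps the experiment drivers
(`ballmoss time|density|dynamic|abc|stats`, each with `--seed`,
`--replicates`, `--out` and a YAML `--config`).

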