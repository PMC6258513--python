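# invasionkit

Modelling biological invasions from opportunistic spatio-temporal
occurrence records, for invasion ecologists and biosecurity analysts
working with presence-only sighting databases.

Human-aided (anthropogenic) dispersal dominates many invasions, yet it
behaves nothing like natural spread: it is fast, long-ranged and largely
independent of the current distribution. `invasionkit` separates the two
processes and then characterises the natural one:

1. **Origin classification.** Each record's nearest-neighbour distance
   d_i to same-or-earlier-year records (with a forced past-year
   correction that preserves long human-mediated jumps hidden by survey
   gaps) is modelled as a two-component mixture
   `L_y(d) = (1 − π) g_y(d) + π f(d, σ)`, where g_y is the Monte-Carlo
   distribution of random-point nearest-neighbour distances up to year y
   (the spatially uniform anthropogenic component) and f is a
   half-Gaussian (the natural component). The EM algorithm estimates π, σ
   and per-record natural-origin probabilities W_i; records with
   W_i < 0.5 are classified anthropogenic.
2. **Dispersal-kernel estimation.** Natural dispersal follows the
   exponential-power kernel
   `f(x) = C / (2 α Γ(1/C)) · exp(−|x/α|^C)`, truncated at a maximum
   distance (30 km by default) with the shape fixed at C = 2 (a cluster
   analysis of (α, C) combinations shows kernels group into a few
   spatially indistinguishable classes representable by Gaussian-shaped
   members). α is estimated by grid search: replicate invasions are
   simulated conditionally on the classified series — anthropogenic
   records copied verbatim, natural records regenerated from the existing
   pool — and compared with the observed series through the sum of
   squared differences of their Ripley K-functions (isotropic edge
   correction over the study polygon). Habitat-suitability filtering,
   jackknife resampling and forward forecasting complete the pipeline.

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a labelled virtual invasion (400 records over 80 years, true
α = 15 km, 10% anthropogenic, inside the bundled synthetic two-island
window), classify it, and recover the kernel:

```python
import numpy as np
from invasionkit import (
    DispersalKernelEstimator, OriginClassifier,
    VirtualInvasionParams, generate_virtual_invasion,
)

params = VirtualInvasionParams(alpha=15.0, n_total=400, anthro_frac=0.1)
series = generate_virtual_invasion(params, np.random.default_rng(1000))

clf = OriginClassifier(random_state=2000)
labels = clf.fit_predict(series)
print(f"pi = {clf.pi_:.3f}, sigma = {clf.sigma_:.2f} km")
print(f"estimated anthropogenic fraction = {clf.anthropogenic_fraction_:.3f}")
print(f"accuracy vs truth = {np.mean(labels == series.origin):.3f}")

est = DispersalKernelEstimator(
    candidates=(4.5, 7.5, 11.0, 15.0, 20.0), n_reps=20, random_state=3000,
)
est.fit(series.with_origin(labels))
print(f"alpha_hat = {est.alpha_:g} km (U-shaped profile: {est.u_shaped_})")
```

which prints

```
pi = 0.877, sigma = 4.76 km
estimated anthropogenic fraction = 0.113
accuracy vs truth = 0.973
alpha_hat = 15 km (U-shaped profile: True)
```

π is the fitted probability that a record is of natural origin, σ the
half-Gaussian scale of natural nearest-neighbour distances; here 11.3% of
records are classified anthropogenic (truth: 10%), 97% of individual
labels are correct, and the grid search recovers the true α = 15 km with
a trustworthy interior-minimum dissimilarity profile.

The same pipeline is available from the shell:

```bash
invasionkit simulate --n-total 400 --seed 1 --out virtual.csv
invasionkit classify --points virtual.csv --seed 2 --out-dir out/
invasionkit estimate --points virtual.csv --n-reps 20 --seed 3 --out-dir out/
invasionkit cluster-kernels --seed 4 --out-dir out/
```

Windows are GeoJSON/WKT polygons (`--window`), rasters ESRI ASCII grids
(`--hsm`, `--intensity`); without `--window` the bundled synthetic
coastline is used. `--coord-scale 0.001` converts metre coordinates to the
package's working kilometres.

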