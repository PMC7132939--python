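# mvbkit

Quantitative analysis of organelles segmented from volume electron
microscopy (FIB-SEM) stacks — written for the study design in which
multivesicular bodies (MVBs) are reconstructed from serial sections of
cortical neuropil, but applicable to any point-like organelle catalog.

Volume-EM studies of organelles answer four recurring questions, and
`mvbkit` implements the estimator for each:

1. **How many per μm³?** Unbiased 3D counting-frame ("brick") density
   estimation: an object is counted iff its centroid lies inside the
   half-open frame [lo, hi), so inclusion faces count and exclusion planes
   do not, making E[count] = λV exactly. Cavalieri point counting (grid
   spacing *s*, every *k*-th section) estimates volume fractions.
2. **How big?** Voxel-count morphometry under anisotropic voxel geometry,
   tissue-shrinkage correction (measurement / factor, with linear 0.90 →
   area 0.81 → volume 0.73), and a maximum-likelihood log-normal size fit:
   ln V ~ N(μ, σ²), μ̂ = mean(ln v), σ̂ with divisor n.
3. **Where?** Compartment percentage tables (dendrite / excitatory axon /
   inhibitory axon / nonsynaptic) and concentration ratios
   (% of objects ÷ % of volume; > 1 means enrichment), with χ²,
   Mann–Whitney, and Kruskal–Wallis + Dunn tests.
4. **Randomly placed or clustered?** 3D point-pattern statistics — the
   nearest-neighbour function G, empty-space function F and Ripley's K
   (border correction for G/F, translation correction for K; under CSR,
   G(r) = F(r) = 1 − exp(−λ(4/3)πr³) and K(r) = (4/3)πr³) — with
   Monte-Carlo CSR envelopes (100 simulations, global simultaneous band by
   default) and a random / clustered / regular / mixed verdict.

A first-class synthetic generator (`mvbkit.synthetic`) produces multi-stack
ground-truth catalogs — CSR or Thomas-clustered positions, log-normal
volumes, multinomial compartments, Bernoulli morphology flags — and voxel
phantoms, so every estimator is tested by parameter recovery. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from mvbkit import (CatalogSpec, ProcessSpec, CountingFrame, Box3D,
                    generate_catalog, estimate_density, fit_lognormal,
                    envelope_test, PointPattern3D)

# 29 stacks over layers I-VI, CSR positions at 0.21 objects/um^3,
# log-normal volumes (mu=-5.1375, sigma=0.9173)
catalog = generate_catalog(CatalogSpec(), ProcessSpec.csr(0.21), seed=1)
print(f"{len(catalog)} objects in {catalog['stack_id'].nunique()} stacks")

windows = {sid: Box3D(lo, hi) for sid, (lo, hi) in catalog.attrs["windows"].items()}
frames = {sid: CountingFrame(w) for sid, w in windows.items()}
dens = estimate_density(catalog, frames)
print(f"mean density across layers: {dens.grand_mean:.2f} ± {dens.grand_sem:.2f} per um^3")

fit = fit_lognormal(catalog["volume_um3"])
print(f"log-normal fit: mu={fit.mu:.4f}, sigma={fit.sigma:.4f}, mean={fit.mean*1e3:.2f}e-3 um^3")

sid = 0
pts = catalog.loc[catalog.stack_id == sid, ["x_um", "y_um", "z_um"]].to_numpy()
res = envelope_test(PointPattern3D(pts, windows[sid]), nsim=100, seed=1)
print(f"stack {sid}: n={len(pts)}, spatial verdict: {res.verdict.value}")
```

Output:

```
1829 objects in 29 stacks
mean density across layers: 0.21 ± 0.00 per um^3
log-normal fit: mu=-5.1433, sigma=0.9062, mean=8.80e-3 um^3
stack 0: n=75, spatial verdict: random
```

Reading it: the counting-frame estimator recovers the generating intensity
(0.21 μm⁻³) as the unweighted mean of the six layer means; the MLE size fit
recovers the generating log-normal parameters to sampling precision at
n = 1829 (the fitted mean exp(μ̂ + σ̂²/2) is 8.80 × 10⁻³ μm³); and the
G/F/K curves of stack 0 stay inside their 100-simulation CSR envelopes, so
its points are classified as randomly placed.

## Command line

```sh
mvbkit simulate --seed 1 --out results        # ground-truth catalog + windows
mvbkit all --seed 1 --out results             # full pipeline on simulated data
mvbkit all --catalog my.csv --windows my.json --out results   # on your data
mvbkit measure stack.tif --out catalog.csv    # label TIFF -> object catalog
mvbkit volfrac stack.tif --spacing-nm 632 --step 40
```

`mvbkit all` writes `catalog.csv`, `density.csv` (per-stack, per-layer and
pooled rows), `volfrac.csv`, compartment/size tables, `lognormal_fit.json`,
per-stack envelope JSONs with verdicts, and the resolved run configuration;
the same config and seed reproduce the outputs byte for byte.

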