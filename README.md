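# bhicc

Computational toolkit for drug screening with spheroids grown in a
bioinert-hydrogel inverted colloidal crystal (iCC) framework — an agarose
scaffold carrying a hexagonal-close-packed (HCP) array of ~250 µm spherical
voids, templated by elastic alginate microgels. Each void hosts one
multicellular tumour spheroid, so a single well carries hundreds to
thousands of biological replicates whose drug response can be read either
at high throughput (plate-reader well scans) or at high content
(two-photon 3D fluorescence volumes).

The package covers the quantitative methods of that platform end to end:

- **Microgel contact mechanics** — the equilibrium centre-to-centre
  distance $D_i$ between settling elastic microgels of diameter $R$ solves
  a quartic in $x = D_i/2$ (with $a = R/2$ and dimensionless load
  $\lambda$):

  $$x^4 - a x^3 - 3a^2x^2 + 5a^3x - 2a^4(1-\lambda) = 0,$$

  which factors as $(x-a)^3(x+2a)$ at $\lambda = 0$ (rigid tangency) and
  perturbs as $D_i/R \approx 1 - (2\lambda/3)^{1/3}$ for small loads. The
  flattened contact disc, $R_\text{cap} = \sqrt{R^2 - D_i^2}$, becomes the
  interconnecting channel diameter after templating. Compressive moduli
  come from the small-strain slope of stress–strain curves.
- **Packing geometry** — exact enumeration of hexagonal-lattice circles in
  a circular dish (per-layer void counts), multi-layer HCP capacity, the
  ideal packing fraction $\pi/(3\sqrt 2) \approx 74\%$, and void number
  density $\sqrt 2/d^3$.
- **Synthetic data with ground truth** — 3-channel
  (scaffold/live/dead) volumes of HCP spheroid arrays, plate-reader 6×6
  well scans, and correlated histology channel pairs, all deterministic
  given a seed.
- **High-content imaging** — void detection from the scaffold channel,
  spheroid contouring by thresholding the OR-merged live/dead channels,
  per-voxel viability, per-slice equivalent-circle diameters, circle maps,
  and 2D lattice metrics.
- **High-throughput plate-reader analysis** — scaffold gating
  (green > 2000 a.u.), the voxel-to-pixel ratio correction
  $\rho_\text{corr} = \pi\,(3\rho/4\pi)^{2/3}$, Gaussian histogram fits,
  and dose-table assembly.
- **Dose-response statistics** — Hill-equation fitting
  $v(d) = b + (t-b)/(1 + (d/\mathrm{IC}_{50})^{n})$ with multi-start
  nonlinear least squares, plus rank-based ROC AUC for group separation.

## Worked example

Simulate a six-dose high-content screen (19 spheroids per field, HepG2-like
Hill parameters IC50 = 18.92 µM, n = 2.807), run the imaging pipeline, and
fit the dose-response:

```python
import pandas as pd
from bhicc import LatticeSpec, HillParams, build_void_lattice, simulate_volume
from bhicc.hc_imaging import process_volume, records_to_frame
from bhicc.dose_response import fit_viability_profile

spec = LatticeSpec(void_diameter=250.0, container_diameter=1450.0)
lattice = build_void_lattice(spec, seed=0)
truth = HillParams(ic50=18.92, n=2.807)

frames = []
for i, dose in enumerate([0, 10, 20, 50, 100, 200]):
    vol, gt = simulate_volume(lattice, diam_mean=179.2, diam_sd=9.76,
                              dose=dose, hill=truth, seed=100 + i)
    records, circle_map = process_volume(vol, expected_diameter=250.0)
    frame = records_to_frame(records)
    frame.insert(0, "dose_uM", dose)
    frames.append(frame)

table = pd.concat(frames, ignore_index=True)
print(table.groupby("dose_uM")["viability"].agg(["mean", "std", "count"]).round(3))
fit = fit_viability_profile(table["dose_uM"], table["viability"])
print(f"IC50 = {fit.params.ic50:.2f} uM, n = {fit.params.n:.3f}, R^2 = {fit.r_squared:.4f}")
```

prints

```
          mean    std  count
dose_uM
0        1.000  0.000     19
10       0.857  0.002     19
20       0.460  0.002     19
50       0.062  0.002     19
100      0.009  0.001     19
200      0.001  0.000     19
IC50 = 18.89 uM, n = 2.810, R^2 = 1.0000
```

Every detected void yields one viability readout; the fitted IC50 and Hill
coefficient recover the generating parameters to a fraction of a percent,
because the per-spheroid dead-voxel fractions carry only binomial noise at
~20 000 voxels per spheroid.

The same workflows are available from the shell:

```sh
bhicc pack --void-um 250 --container-mm 5 --layers 5
#   per layer: [313, 327, 313, 327, 313]
#   total:     1593
#   packing fraction: 0.7405
#   number density:   90.5 per uL
bhicc mechanics --calg 0.03 --ec-kpa 2156 --radius-um 253.3
bhicc simulate-wellscan --seed 1 --out scan.csv
bhicc ht-analyze scan.csv --out summaries.csv
bhicc run --mode both --seed 1 --out-dir out/
```

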