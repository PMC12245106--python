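# Methods

This note documents the models implemented in `bhicc`, the defaults and
the reasoning behind them, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter.

## Microgel contact mechanics

Elastic alginate microgels settling under gravity in water deform at
their mutual contacts. Balancing gravity, buoyancy and the elastic
restoring stress leads to a quartic equation for the half-distance
$x = D_i/2$ between neighbouring microgel centres, with $a = R/2$:

$$x^4 - a x^3 - 3a^2 x^2 + 5a^3 x - 2a^4(1 - \lambda) = 0 .$$

Two printed variants of the loading group are supported,
$\lambda_{(2)} = 2\rho_w C_\text{alg} g / E_c$ and
$\lambda_{(3)} = \rho_w C_\text{alg} g / (3E_c)$; which applies to which
packing configuration is not settled, so both are exposed as `eq2`/`eq3`.
**Units caveat:** the loading group as printed carries dimensions of
1/length in SI. This package evaluates it with SI base values inserted
literally ($\rho_w$ in kg m⁻³, $g$ in m s⁻², $E_c$ in Pa) and treats the
result as the dimensionless $\lambda$; `solve_contact_distance` also
accepts $\lambda$ directly so a caller can substitute any other
nondimensionalisation.

At $\lambda = 0$ the quartic factors exactly as $(x-a)^3(x+2a)$: rigid
spheres touch at $D_i = R$. The physical root for $\lambda > 0$ detaches
from the triple root as $D_i/R \approx 1 - (2\lambda/3)^{1/3}$; the solver
brackets this root and bisects (Brent), rejecting loads for which no root
exists in $(0, a]$. Root residuals are verified below $10^{-10} a^4$. The
contact-disc ("cap") diameter follows from the chord relation
$R_\text{cap} = 2\sqrt{(R/2)^2 - (D_i/2)^2}$; despite the symbol it is a
diameter, which is the convention that matches the reported channel sizes
(tens of µm for ~250 µm microgels). Compressive moduli are the slope of
an ordinary least-squares line (with intercept) through the first 11
points of a stress–strain curve, i.e. the small-strain limit.

## Packing geometry

Void capacity is an exact lattice enumeration, not an area estimate: a
void of diameter $d$ lies inside a dish of diameter $D$ iff its centre is
within radius $(D-d)/2$, and centres sit on a triangular lattice of pitch
$p$ (default $d$). The default registration places one void at the dish
centre with rows along x, which makes counts deterministic; because the
true registration of a self-assembled template is unknowable, a
best-of-translations mode scans a 6×6 grid of lattice offsets over the
fundamental cell and reports the maximum. Layers alternate A/B
registrations at spacing $p\sqrt{2/3}$. The packing fraction
$\pi/(3\sqrt2) \approx 0.7405$ and number density $\sqrt2/d^3$ are ideal
HCP values, independent of the container.

## Synthetic data generators

The generators exist to close the loop on every analysis: each pipeline
is tested by its ability to recover known ground truth.

**Volumes.** The scaffold (green) channel is a bright plateau (3000 a.u.
on a 12-bit-like 0–4095 scale, so the conventional >2000 a.u. gate is
meaningful) with dark spheres at the void centres and dark cylinders of
the channel diameter joining lattice neighbours within 1.3 pitch. Each
occupied void holds a centred spheroid whose diameter is drawn from a
normal distribution (defaults: mean 179.2 µm, SD 9.76 µm, the HepG2-like
size distribution); each spheroid voxel is independently dead with
probability $1 - v(d)$ where $v$ is the Hill response at the dose, live
voxels emit blue and dead voxels red at 3000 a.u. over a 100 a.u.
background. Noise is Poisson (gain 1) followed by Gaussian read noise
(SD 50 a.u.). Default voxel size is 5 µm isotropic — 50 voxels across a
250 µm void — keeping a ~120-void field under ~200 MB. Dead voxels are
spatially random by default because the downstream scoring is
count-based; a rim-death mode exists for robustness experiments.
Deliberately **not** modelled: optical PSF anisotropy beyond the voxel
grid, depth attenuation, photobleaching, spheroid eccentricity or
necrotic-core structure, and partial void occupancy correlations. Passing
closure tests therefore demonstrates correctness of the measurement
logic, not robustness to every optical artefact of real two-photon data.

**Well scans.** Each well contributes a 6×6 grid of scan points (the
design gives 4 wells × 36 points = 144 readouts per dose). In-framework
points carry green at the plateau; blue and red intensities are
proportional to the local live and dead volume fractions, perturbed by a
per-point fill variation (SD 0.02) and additive read noise (SD 30 a.u.),
so the raw red/blue ratio encodes $(1-v)/v$. An optional circular mask
drops grid corners below the gate, emulating a square scan grid clipped
by a round well (real instruments report 27–36 usable points; the full
36-point grid is the default).

**Histology.** Channel pairs are bivariate normal with a prescribed
Pearson correlation, affinely mapped to 8-bit-like scales and left
unclipped so the correlation is exact.

## High-content imaging pipeline

1. **Void detection.** The scaffold channel is smoothed at a quarter of
   the expected void diameter; candidate centres are local minima at
   least half a void diameter apart and darker than the midpoint of the
   smoothed dynamic range. Each candidate is then refined to the maximum
   of the Euclidean distance transform of the dark phase within 0.6 void
   radii — the centre of the inscribed dark sphere — averaging over the
   argmax plateau to cancel voxel-grid bias. The refinement matters:
   interconnecting channels and missing boundary neighbours displace the
   smoothed minimum by up to ~3 voxels, while the inscribed-sphere centre
   stays within ~1 µm of truth. A Hough-sphere transform was not needed
   because the voids are dark, quasi-periodic, and of known diameter.
2. **Contouring.** Within each ROI sphere, the voxelwise maximum of red
   and blue (an OR merge) is thresholded — Otsu by default, fixed value
   optional — and the largest connected component is the spheroid
   contour. The merge makes the contour provably independent of the
   live/dead split, which the tests assert exactly.
3. **Viability.** The red channel is thresholded within the contour;
   viability is $1 - \text{dead voxels}/\text{contour voxels}$. Otsu on a
   unimodal red distribution (fully live or fully dead spheroid) would
   split pure noise, so when the implied classes are separated by less
   than 4 pooled SDs the contour is scored all-live or all-dead by
   whether red carries more than half the merged signal. Whether
   "viability" should be voxel-based or cell-based is ambiguous in
   practice; the voxel-based definition is used and documented on every
   output.
4. **Diameter.** Per z-slice equivalent-circle diameter
   $2\sqrt{A_z/\pi}$, maximised over z. On digital spheres this is
   unbiased to well under one voxel.
5. **Lattice metrics.** For 2D microgel-assembly images, neighbour pairs
   are centre pairs within 1.3 pitch (the six hexagonal contacts),
   deduplicated; each pair's $D_i$ maps through the chord relation to a
   per-pair cap diameter. Per-pair averaging is deliberately kept
   distinct from evaluating the cap at the mean distance: the chord
   relation is strongly concave near contact, so the two differ (a
   Jensen-gap the tests reproduce).

Failures at single ROIs (empty voids) become flagged records, never
exceptions, so one empty void cannot abort a plate.

## High-throughput plate-reader path

Scan points are retained only if green is **strictly** above the gate
(default 2000 a.u., matching the conventional ">2000" phrasing). The raw
per-point dead/live ratio is volume-proportional, while the dose-response
is referenced to a cross-sectional (pixel) scale; the correction
$\rho_\text{corr} = \pi(3\rho_\text{raw}/4\pi)^{2/3}$ is the exact sphere
volume → great-circle-area map ($4\pi/3 \mapsto \pi$, monotone, concave).
Per-dose histograms of corrected ratios are fitted with a least-squares
Gaussian (Freedman–Diaconis binning, floor of 10 bins, capped at
$4\sqrt n$ bins so a collapsed IQR cannot blow up the histogram); if the
fit fails or explains <90 % of histogram variance the summary falls back
to sample moments with a flag. For Hill fitting, the Gaussian means are
inverted through the exact inverse of the area correction back to the raw
volumetric ratio $\rho$ and mapped to the viability-like response
$1/(1+\rho)$ — the live fraction of a live+dead mixture — then normalised
to the zero-dose response and fitted in 2-parameter mode (top 1,
bottom 0). This choice makes the noiseless pipeline exactly
self-consistent with the generator, which the tests verify; fitting the
corrected means directly (without normalisation) is available through the
4-parameter fitter.

## Hill fitting

The 4-parameter model $b + (t-b)/(1+(d/\mathrm{IC}_{50})^n)$ is fitted by
bounded nonlinear least squares with multi-starts over a 7-point
geometric IC50 grid spanning [min positive dose/3, 3·max dose] and
$n \in \{0.5, 1, 2, 4\}$, keeping the lowest residual — Hill fits are
multimodal at small $n_\text{obs}$ and a single start is not trustworthy.
Dose 0 is evaluated through the power form directly (response = top
exactly), avoiding any log-dose transform. Fits are scale-equivariant in
dose and report $R^2$ against total variance, per-parameter standard
errors, and flags for extrapolated IC50 (outside the dose range) and
degenerate (flat) responses.

`fit_viability_profile` aggregates per-spheroid viabilities to per-dose
**medians** before fitting. Viability lives on [0, 1], so additive
measurement noise is censored at the scale ends; the censoring biases the
per-dose *mean* inward (and the fitted $n$ upward by ~8 % at the default
noise), while the median is unaffected wherever less than half the mass
clips. Means remain available via `robust=False`.

ROC AUC uses the rank (Mann–Whitney) formulation with ties counted half,
delegated to `scipy.stats.mannwhitneyu` and cross-checked against
exhaustive pair counting in the tests.

## Histology

Colour deconvolution is standard optical-density unmixing:
$\mathrm{OD} = -\log((I + \varepsilon)/\text{white})$ with
$\varepsilon = 1/255$, projected through the pseudo-inverse of the stain
matrix and clipped at zero. The default vectors are the published
aniline-blue / acid-fuchsin pair; since the vectors any given study used
are rarely reported, results on real slides are vector-dependent and the
vectors are overridable. Pearson correlation and the joint histogram
operate on any two channels under an optional mask.

## Problem sizes and reproducibility

Closure tests run on a ~19-void field (250 µm voids in a 1.45 mm dish)
and the diameter-recovery experiment on a 100-void single-layer field at
5 µm voxels; recovery experiments use 300 spheroids per dose across the
six-dose design with 10 seeds and report medians. These sizes were chosen
so the whole suite exercises every pipeline at full fidelity while
remaining comfortable on a laptop. Every generator consumes an explicit
seed through `numpy.random.default_rng`, and `scripts/acceptance.py`
derives all of its seeds from the single `--seed` argument via
`SeedSequence`, so reruns are bit-reproducible.

## Known limitations

- The dimensionless treatment of the printed loading group is a
  documented convention, not a derivation; absolute $D_i/R$ predictions
  inherit it (trends in $E_c$ do not).
- Void detection assumes quasi-periodic dark voids of approximately known
  diameter; it is not a general blob detector.
- The histology generator produces correlated Gaussian channels, not
  renderings of stained tissue; it validates the correlation estimator,
  not the deconvolution vectors.
- Real-image thresholds (red/blue) are data-dependent; Otsu defaults are
  reproducible but not guaranteed optimal for any particular microscope.
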