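# Methods

## The lattice model

The simulator is a compartmental Cellular Potts (Glazier–Graner–Hogeweg)
model. Generalized cells are *compartments*: each of the 47 biological
cells owns four labels (apical, core1, core2, basal) stacked along its
apical–basal axis; the vitelline shell, the yolk, the outside medium
and two lateral spacer columns are additional labels. One Monte Carlo
step (MCS) performs as many label-copy attempts as there are non-frozen
lattice sites; a copy of a neighbouring site's label is accepted with
probability min(1, exp(−ΔH/T)). ΔH is evaluated incrementally (local
contact change, the two affected volumes/surfaces, and only the links
incident to the two affected compartments); the per-label registry
(volume, surface, centroid sums) is updated in place, and an exact
recount is used in the test suite to confirm the incremental
bookkeeping never drifts. A copy that would annihilate a non-medium
compartment is rejected outright, so every compartment keeps at least
one site. Compartment connectivity is not otherwise enforced;
fragments can detach, which is why the furrow readout works on each
cell's largest connected component (below).

The contact term distinguishes intra-cell from inter-cell interfaces:
labels sharing a parent cell interact through a cheaper matrix
(J_intra = 6 between cell compartments) than labels of different cells
(J = 10, apical–apical 12). Without this distinction a cell's four
compartments have no reason to stay assembled and the tissue
disintegrates within a few hundred MCS. Other defaults (lattice energy
units): apical–vitelline 4 (weak adhesion to the shell),
other-compartment–vitelline 14, cell–yolk 16 (basal–yolk 8),
vitelline–yolk 30 (a bare shell is expensive, which is what drives
flanking cells to spread over surface vacated by the invaginating
mesoderm), cell–medium 40. Constraint multipliers λ_V = 2, λ_S = 0.05,
temperature T = 6. The yolk is a single unconstrained label — a
passive fluid reservoir whose total volume is free; the medium outside
the shell is inert. Surfaces are counted as heterologous neighbour
pairs in the 8-neighbourhood, which is also used for contact energy
and copy-source selection (standard anisotropy reduction).

## Geometry

The default layout is a semicircular arc: the 47 cells are radial
wedges with their apical surfaces (arc width w0 = 10 sites) against a
frozen vitelline shell of radius R = (47·w0 + 2·spacer)/π, apical
height fractions (0.15, 0.35, 0.35, 0.15) of h0 = 40, yolk filling the
half-disc, a frozen cap closing the diameter, and frozen spacers
pinning the band's ends. The curvature is load-bearing, not cosmetic:
a contractile chain pressed against a *flat* wall is pure in-plane
compression with no inward force component, and in flat-layout
experiments furrow depth saturated near 0.2 h0 at every stiffness
tested. On the arc, chain tension has an inward (purse-string)
component everywhere. The flat row remains available
(`GeometryConfig(arc=False)`) for comparison. A desk-scale preset
(`reduced_config()`: w0 = 8, h0 = 32, ≈33k sites, 2500 MCS, a few
seconds per run) keeps all other parameters identical and reproduces
the same qualitative behaviour as the full scale; the sweeps in the
tests and the acceptance script use it.

## Contractility and stiffness schedules

Apical-constriction links connect apical compartments of adjacent
mesodermal cells. Their stiffness is A·m(x)·r(t) with m a Gaussian in
cell position (σ = 4 cells — contractility strongest at the ventral
midline, decaying toward the peripheral mesoderm, zero outside) and r
a smoothstep ramp over 300 MCS; their rest length is
gap0·(1 − c·m(x)·r(t)) with contraction fraction c. The shrinking rest
length matters: with a fixed zero rest length, quadratic springs pull
hardest on the *longest* links, so the apical chain collapses into a
midline ball (cell extrusion, no fold); tracking a gradually
shortening target contracts the chain coherently, the way
focal-point-plasticity links with a decreasing target distance do.
Sub-apical (apical↔core1) and sub-basal (core2↔basal) links per cell
take λ_sa, λ_sb from the group schedule: uniform, grouped (central /
peripheral mesoderm / neuroectoderm), or a linear ramp between start
and final values. Presets reproduce the three experiment families:
both mesodermal axes varied together (`fig5d`), central vs peripheral
sub-apical stiffness at shared sub-basal (`fig5e`), and a dynamic ramp
(central up, peripheral down) against a constant-30 control
(`fig5f` / `fig5f_control`). Mesodermal core2 target volumes grow
linearly to 1.15× over 500 MCS (heightening), with the surface target
scaled along.

A = 300 and c = 0.7 were calibrated jointly with the growth factor:
the regime is genuinely narrow. Stronger drive (c ≥ 0.75 or growth
≥ 1.2×) lets a stiffness-independent "crumple" mode score as a furrow
even with soft cells; weaker drive (c ≤ 0.55) leaves stiff tissue
below 0.3 h0. At the chosen point the model expresses, over replicate
seeds: zero depth without contractility; failure (≤ 0.15 h0) for soft
mesoderm (λ_sa ≤ 10); furrows of 0.6–0.7 h0 for λ_sa ≥ 30 with a
near-flat sub-basal dependence; and deeper furrows for the dynamic
ramp than for its constant control.

## Furrow depth

Depth is the inward displacement (radial, for the arc) of the
apical-most coordinate of the central mesodermal cells from their
initial apical surface, in units of h0, clamped at zero.
`furrow_depth` follows that definition literally for the single
midline cell; the sweep observable (`furrow_depth_group`, the default)
takes the median displacement over the nine central cells, each
restricted to its largest connected component. The median makes the
metric blind to one cell being stochastically squeezed out of the
epithelium — a legal CPM rearrangement that is not a fold and that
otherwise contaminates the no-contractility control. "Final" depth is
the mean of the trailing 5% of snapshots, damping lattice fluctuation.

## Quantification chain

* **ROI statistics** — median, mean, SD, max, min over masked pixels.
* **Onset normalisation** — subtract the value at a named reference
  timepoint (end of cellularisation / gastrulation onset).
* **Hotspot filtering** — threshold at the (1 − f) quantile (f = 0.04
  by default) of the reference frame, frozen and applied to all frames
  (a per-frame mode exists); pixels ≥ threshold are kept, so constant
  frames keep everything.
* **Shape phases** — area, Crofton perimeter, moment-ellipse axes and
  circularity 4πA/P² per mask. Circularity is reported unclamped:
  discrete near-circles overshoot 1 by a few percent, and clamping
  would create plateaus that displace the maximum. The earliest
  maximum splits the track into phase 1 (apical-basal axis = major)
  and phase 2 (= minor); cells are optionally filtered to transition
  times within the 10th–90th percentile (inclusive, linear
  interpolation; skipped with a warning below 3 tracks).
* **MTSD** — orientation dispersion about the axial mean. Per-pixel
  orientations come from a structure tensor on derivative-of-Gaussian
  gradients (scale 1.0, tensor smoothing 1.5); finite-difference
  gradients lock onto raster staircases and bias the mean by up to
  ~3.5°. Weights are intensity × anisotropy, gated at anisotropy 0.9
  (suppresses background, crossings, fibre end caps). The mean is the
  axial Fréchet mean — the direction minimising the weighted mean
  squared wrap-around deviation on a 0.25° histogram — which stays
  defined for bimodal fields where the vector resultant vanishes; the
  MTSD is the root of that minimum. For finite samples this estimator
  sits slightly below the ideal uniform limit 180/√12 ≈ 52°
  (≈ 50° at 600 fibres), a selection effect of minimising over the
  mean, not an implementation error.
* **Detrended association** — first difference (the windowed series),
  KPSS level check with a Schwert-style fixed bandwidth
  4·(n/100)^¼ (good power against residual random walks without
  inflating size on short-memory series; a constant differenced series
  is stationary by convention), then per-series ARMA(p, q) with
  (p, q) ≤ 2 selected by AICc, and the Spearman correlation of the two
  residual series. Non-convergent fits fall back to demeaned series
  with a warning. For jointly Gaussian innovations with correlation ρ
  the expected Spearman value is (6/π)·arcsin(ρ/2), which the
  generators record as truth.
* **Modulus** — v = ν_B·λ/(2n·sin(θ/2)), M = ρv², defaulting to
  water-like constants (n = 1.33, ρ = 1000 kg/m³, 532 nm,
  backscattering).

## Synthetic data

The generators plant the exact structure each stage assumes and record
it: shift-map stacks (background 5.10 GHz, a disc hotspot ramping to
+25 MHz, Gaussian noise — the recovery experiments run at SNR 4);
elliptical masks interpolating columnar (40×10) to squamous (8×50)
with the analytic isotropy crossing; fibre fields drawn as *analytic*
Gaussian-profile ridges (rasterized 1-px lines quantize angles at
atan(1/L) and staircase the gradients); and paired polynomial-trend +
ARMA(1,1) series with jointly Gaussian innovations at a planted
correlation. All are bit-reproducible given a seed, and every
quantification stage has a generator-backed recovery test. What
passing recovery tests do **not** show: robustness to non-Gaussian
noise, optical blur and registration error of real microscopy, or to
hand-drawn mask variability — the generators idealise all of these.

## Known limitations

* The model is a 2D toy: no third dimension, no mesoderm EMT after
  invagination, no explicit perivitelline fluid, and an MCS↔minutes
  mapping left unspecified.
* The myosin input is a parametric stand-in (Gaussian × smoothstep)
  for measured myosin curves; all of its parameters are exposed so a
  tabulated curve can be substituted.
* Central-soft mesoderm flanked by stiff peripheral cells still
  produces a ~0.5 h0 fold in this calibration (the stiff flanks
  transmit the constriction), so "central softness fails regardless of
  peripheral stiffness" is not expressed; neither is a resolvable
  optimum at low-but-nonzero peripheral stiffness. Both would likely
  require the original model's exact parameterisation.
* Furrow nucleation is stochastic near regime boundaries (λ_sa ≈ 20,
  or contraction near the crumple threshold), where replicate depths
  are bimodal; grid summaries should always be read as means over
  replicates, as the sweep driver reports them.
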