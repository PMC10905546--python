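# Methods

This note records the models behind `tumorperf`, the parameter choices that
matter, the numerics, and what the synthetic generators do and do not
emulate.

## Ex-vivo hydraulic conductivity

A 1 mm thick, 12 mm diameter tissue disc is clamped between two Ussing
half-chambers; a 16 cm liquid column (≈1.6 kPa, a realistic elevated tumor
IFP) drives PBS through the disc, and the flow is read from an air bubble
drifting along a 1 mm bore tube, imaged every 10 min for 2 h. Darcy's law
for the disc gives the nominal conductivity

    K' = (b/d)^2 * w / (rho g h) * dx/dt

with `d = 5.05 mm` the *wet* (exposed-area) diameter — not the punch
diameter — because only the exposed area conducts. The head is treated as
constant over a run: at the measured velocities (~1 µm/s in a 1 mm tube)
the column drops by far less than 1% of `h` in 2 h.

Bubble velocity is the ordinary-least-squares slope over all frames. The
first/last-difference alternative discards ten of thirteen observations and
yields no uncertainty; OLS gives both, and its standard error propagates to
`K` multiplicatively (the rest of the chain is a constant factor). A
negative slope (back-flow) is reported with a leak-suspect flag rather than
rejected, since leakage is screened separately before each run.

PBS viscosity is interpolated linearly between the tabulated water anchors
1.1×10⁻³ Pa·s at 18 °C and 8.9×10⁻⁴ Pa·s at 25 °C — over this 7 °C window
the curvature of the water viscosity curve is below 0.5%, so a two-anchor
line suffices; outside the window the line extrapolates with a warning.
The correction `K = (mu_PBS / mu_IF) K'` re-references the measurement to
interstitial fluid at body temperature (`mu_IF = 3.5×10⁻³ Pa·s`).

## Microstructure relations

Kozeny–Carman estimates intrinsic permeability `k = eps³/(Q alpha²)` with
`Q = 5` (valid for porosity < 0.7); `K = k/mu`; hindered diffusion
`Deff = eps·D`. At fixed pore surface density these force `K ∝ eps³` and
hence `Deff ∝ K^(1/3)`. The flattened power-law notation is ambiguous
between exponent 3 and 1/3; **1/3 is the only value consistent with the
porosity-hindrance law and the cubic conductivity–porosity scaling**, so it
is the default, with the exponent exposed as a parameter so the cubic
reading can be run for comparison.

## Correlation statistics

Each pair (density↔density, density↔K) in each grouping (pooled, per tumor
type) is a stand-alone simple linear regression reporting signed Pearson r,
|r| (both, since published tables in this area often tabulate magnitudes
beside signed slopes), R², the two-sided slope t-test p-value (n−2 df) and
the slope standard error (configurable to the residual standard error).
Sidedness is a choice: two-sided is the conservative default. No
multiple-testing correction is applied, matching how such tables are
conventionally reported; the per-cell p-values are descriptive.

Conductivity enters on a log₁₀ scale by default because measured K spans
more than an order of magnitude across samples and the biological effect
(matrix density restricting flow) is multiplicative. Normal-peritoneum
samples sit an order of magnitude above the tumor trend and are excluded
from the pooled grouping by default (flag `include_normal`); per-type
groups always keep their own samples. Groups with fewer than three samples
or a constant predictor are emitted with a reason code, not dropped.

## Geometry and conductivity maps

The simulated tumor is a 10 mm diameter sphere: necrotic core (Ø 5 mm),
hypoxic shell (2.5 mm thick — with the defaults the shell reaches the tumor
surface and the viable rim has zero width; both shells carry the vascular
source, so a thinner shell merely relabels cells), embedded in normal
tissue out to `R_domain = 4 R_t = 20 mm`, standing in for the far boundary
where IFP is normalized to 0.

Radial conductivity maps are monotone shape-preserving (PCHIP) interpolants
through anchors: constant `K_necrotic` in the core (default: the deep-slice
value `K2`), rising to the superficial-slice value `K1` at the tumor edge,
then a smooth ramp of width 0.5 mm to `K_normal`. PCHIP through the anchors
adds no parameters beyond the measured values, is C¹ (the solver's harmonic
face averaging then never sees a jump), and is monotone between anchors.
Homogeneous maps use `K_normal = 5 K_tumor`; heterogeneous maps use the
measured normal-peritoneum conductivity `2.8×10⁻¹³ m²/(Pa·s)` since all
three profile anchors come from measurements in that configuration. The
packaged heterogeneous edge/core pairs (6.0/3.5 and 12/3.0 ×10⁻¹⁵) are
synthetic stand-ins inside the measured envelope, with intra-tumor
variation within the observed factor ~4 and the second map having the
larger edge-to-core ratio.

## Steady interstitial flow

Darcy + continuity with Starling source and lymphatic sink:

    -div(K grad p) = Lp S/V (p_v - p - sigma(pi_v - pi_i))
                     - LpL SL/VL (p - p_L)

Both terms are linear in p, so the cell-centered finite-volume system
(spherical symmetry, harmonic face conductivities, zero flux at r = 0,
p = 0 at `R_domain`) is one direct sparse solve. The scheme is second-order
on smooth profiles (verified against the closed-form solution
`p = p_e [1 - (R/r) sinh(alpha r/R)/sinh(alpha)]`, `alpha = R sqrt(Lp S/V / K)`)
and discretely conservative: the outer-boundary outflow equals the volume
integral of the net source to solver precision.

Parameter defaults (every one overridable in the config) are in the
published tumor/normal ranges: tumor `Lp = 2.1×10⁻¹¹ m/(Pa·s)`,
`S/V = 2×10⁴ 1/m`, `p_v = 2080 Pa`, `sigma = 0.82`, `pi_v = 2670 Pa`,
`pi_i = 1960 Pa`; normal tissue `Lp = 2.7×10⁻¹² m/(Pa·s)`,
`S/V = 7×10³ 1/m`, `sigma = 0.91`, `pi_i = 1330 Pa`, lymphatic conductance
`1.33×10⁻⁷ 1/(Pa·s)` at `p_L = 0`. The tumor combination sets the effective
filtration pressure `p_e = p_v − sigma(pi_v − pi_i) ≈ 1.50 kPa`, the
plateau IFP of an avascularly-drained tumor and consistent with the 1.6 kPa
head used in the ex-vivo rig as a realistic elevated IFP. Vascular exchange
is off in the necrotic core (avascular necrosis) and lymphatics exist only
in normal tissue; both switches are per-region configuration. Because the
plateau equals `p_e` whenever `alpha ≫ 1` (true for all measured K), the
peak IFP is insensitive to K while the edge boundary layer — width
`sqrt(K/(Lp S/V))`, tens to hundreds of µm — carries all the K dependence:
lower K steepens the edge and raises near-edge IFP; higher K widens the
layer, increases the Darcy velocity, and spreads the non-zero-IFV zone.
Just outside the edge the elevated IFP can exceed the normal-tissue
filtration pressure, reversing the Starling term to reabsorption; this is
physical and allowed.

## Drug transport

On the frozen steady velocity field, the concentration obeys

    dC/dt = div(Deff grad C) - div(u C) + phi_V - phi_L

with `Deff` evaluated cell-wise from the local K through the 1/3 power law
(reference `Deff0 = 3×10⁻¹⁰ m²/s` — a small-molecule, cisplatin-like
effective diffusivity — at `K0 = 8.8×10⁻¹⁵`, the middle measured anchor;
fixing `K0` across study cases is what lets conductivity differences
translate into diffusivity differences). The conservative divergence form
is used even though the constant-coefficient Laplacian is common shorthand:
with spatially varying `Deff` the two differ, and only the conservative
form preserves mass. Transvascular exchange uses the transmural Peclet
number `Pe = J_V(1−sigma_d)/(Ld S/V)` with `Pe/(e^Pe − 1) → 1` at `Pe = 0`
handled analytically; with plasma concentration `c_p = 0` (short, 30–60 min
administration) it is a pure sink. Drug wall permeability `Ld = 10⁻⁷ m/s`
and `sigma_d = 0.1` are small-molecule literature-range values.

The surface dose is a Dirichlet condition `C = 0.17 mol/m³` (an
intraperitoneal-cisplatin-range concentration) pinned at the cell
containing the tumor edge, acting on both sides; `C = 0` at the far
boundary and initially everywhere else. Discretization: finite volume,
first-order upwinded advection, fully implicit backward Euler (default
`dt = 5 s`, one LU factorization reused across steps). The implicit
M-matrix guarantees positivity and the maximum principle without a CFL
restriction, which is why no explicit mode is shipped; upwinding adds
numerical diffusion of order `u·dr/2 ≈ 10⁻¹² m²/s` at the default grid —
three hundred times smaller than `Deff`. The discrete mass budget (free
cells vs. boundary influx minus vascular+lymphatic clearance) closes to
machine precision and is checked to <10⁻⁶.

Penetration depth is the largest distance from the tumor edge (inward or
outward) where C exceeds 1% of the surface concentration at the final
time; the threshold is configurable, and the high-K/low-K penetration
contrast is insensitive to it over 0.5–5%.

## Synthetic generators

The bubble-track generator inverts the chamber equation: from a true
(interstitial-fluid-referenced) K it computes the PBS-referenced value at a
sampled run temperature, the implied velocity, and emits
`position = v t + N(0, 5 µm)` at 10-min frames over 2 h. 5 µm is sub-pixel
for a mm-bore tube camera and makes the velocity SNR ~10³ at mid-range K —
noiseless tracks invert exactly; noisy tracks recover K within 3 standard
errors at the nominal ~99% rate (13 frames, t-distribution with 11 df).

The cohort generator plants `log10 K = a + b·collagen% + N(0, sd)` with
collagen ~ U(10, 50)%, `a = −13.52`, `b = −0.028` (spanning the measured
tumor envelope 1.6×10⁻¹⁴ down to ~1.2×10⁻¹⁵ across the collagen range), and
`sd = 0.167` chosen in closed form so the population R² =
b²Var(x)/(b²Var(x)+sd²) = 0.79, the strength of the observed pooled
collagen–K association. Cell and fibroblast densities are independent
draws, so their K associations are null at the nominal type-I rate. Tumor
type labels rotate round-robin over the six tumor categories; two
normal-peritoneum samples are appended around the measured 2.8×10⁻¹³.
K noise is lognormal because conductivities are positive and spread over an
order of magnitude.

What the generators do *not* emulate: per-tumor-type mean differences in K
or densities (labels are exchangeable), correlated slices within a tumor
(real cohorts pool multiple slices per specimen), head decay or leakage
artifacts in the chamber, and the nonlinearity that makes normal tissue
fall off the tumor collagen–K trend. Passing tests therefore demonstrate
that the pipeline recovers what was planted under idealized sampling — not
that real cohorts satisfy the linear model.

## Problem sizes and tolerances

Default simulations use 800–1000 uniform cells over 20 mm (12.5–25 µm
spacing, resolving the thinnest IFP boundary layer with several cells) and
5–10 s implicit steps over 30–60 min; a full nine-case parameter study runs
in under a second on one CPU. Monte-Carlo sweeps use 500 seeds for the
round trip and cohort statistics, putting binomial uncertainty on reported
rates near ±1%. The flow solver is validated to <0.01% L2 against the
closed-form sphere solution at 400 cells; the transport solver to <2%
against the planar erfc solution near the edge at short time and <0.5%
against the exact spherical-surface-source form (`w = rC` reduction).

## Known limitations

Spherical symmetry replaces a 3-D box domain — exact for the radial
geometry and maps studied, but unable to represent corner effects or
non-spherical tumors. Flow and transport are one-way coupled (no
poroelasticity, no transient IFP). The drug model omits binding, metabolism
and cell-kill; plasma pharmacokinetics are frozen at zero. First-order
upwinding smears steep fronts by design; a flux limiter is a possible
extension. The 1/3 diffusivity exponent is a modeling inference, not a
measured quantity.
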