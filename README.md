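# tumorperf

Tumor tissue hydraulic conductivity, microenvironment correlations, and
radial interstitial fluid flow / drug transport simulation.

Elevated interstitial fluid pressure (IFP) in solid tumors is a major
barrier to drug delivery, and estimating it — invasively or from dynamic
imaging — requires the tissue **hydraulic conductivity** *K*
[m²/(Pa·s)], the ease of bulk flow through the interstitium. `tumorperf`
implements the computational chain around ex-vivo *K* measurements in human
tumor samples:

1. **Ex-vivo conductivity** (`tumorperf.exvivo`): a tissue disc clamped in a
   modified Ussing chamber passes buffer under a constant hydrostatic head;
   the flow is read from the drift of an air bubble in a calibrated tube.
   Darcy's law gives the nominal conductivity
   *K′ = (b/d)² · w · (dx/dt) / (ρ g h)*, corrected to interstitial-fluid
   viscosity via *K = (μ_PBS/μ_IF) · K′*. Bubble velocity is an OLS slope
   over all frames, with a standard error.
2. **Microstructure relations** (`tumorperf.microstructure`):
   Kozeny–Carman permeability *k = ε³/(Q α²)*, *K = k/μ*, hindered
   diffusion *D_eff = ε D*, and the derived power law
   *D_eff/D_eff⁰ = (K/K⁰)^{1/3}* mapping local conductivity to drug
   diffusivity.
3. **TME statistics** (`tumorperf.tme_stats`): simple linear regressions
   relating *K* (on a log₁₀ scale) to collagen-fiber, cancer-cell and
   fibroblast area densities, pooled and per tumor type.
4. **Flow + drug simulation** (`tumorperf.geometry`, `ifp`, `drug`): a
   three-region spherical tumor (necrotic core, hypoxic shell, viable rim)
   in normal tissue; steady Darcy flow with a Starling transvascular source
   *J_V = L_p S/V (p_v − p_i − σ(π_v − π_i))* and a lymphatic sink in
   normal tissue, solved by a conservative finite-volume scheme in
   spherical symmetry; then transient advection–diffusion drug transport
   with transmural Peclet-number exchange on the solved velocity field.
5. **Synthetic data** (`tumorperf.synthetic`): bubble tracks generated from
   a known *K* and tissue cohorts with a planted inverse collagen–*K*
   relationship, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from tumorperf import (
    generate_bubble_track, conductivity_from_track,
    homogeneous_profile, TumorGeometry, TransportParams,
    RadialGrid, solve_steady_ifp, simulate_drug, DrugParams,
)

# 1. measure K from a (synthetic) bubble track
track = generate_bubble_track(K_true=7.3e-15, noise_sd_position=5e-6, seed=1)
res = conductivity_from_track(track)
print(f"K = {res.K_corrected:.3e} m^2/(Pa s) "
      f"(velocity {res.velocity:.2e} +/- {res.velocity_stderr:.1e} m/s)")

# 2. simulate IFP and drug penetration for that conductivity
geom = TumorGeometry()                     # 10 mm tumor in normal tissue
grid = RadialGrid.uniform(geom.R_domain, 800)
prof = homogeneous_profile(res.K_corrected)  # K_normal = 5 K_tumor
flow = solve_steady_ifp(grid, prof, geom, TransportParams())
field = simulate_drug(flow, prof, DrugParams(K_ref=8.8e-15), grid=grid,
                      geometry=geom, transport=TransportParams())
print(f"max IFP  = {np.max(flow.p_i):.0f} Pa")
print(f"peak IFV = {np.max(np.abs(flow.u_i)):.2e} m/s")
print(f"penetration depth = {field.penetration_depth*1e3:.2f} mm")
```

Output:

```
K = 7.298e-15 m^2/(Pa s) (velocity 1.03e-06 +/- 4.1e-10 m/s)
max IFP  = 1498 Pa
peak IFV = 3.37e-08 m/s
penetration depth = 3.06 mm
```

The recovered conductivity agrees with the injected 7.3×10⁻¹⁵ within its
standard error. The IFP plateaus at the effective filtration pressure
(~1.5 kPa) in the tumor core and collapses to ~0 in normal tissue; the
interstitial velocity peaks at the tumor edge; the drug front (1% of the
0.17 mol/m³ surface concentration after 60 min) reaches ~3 mm from the
edge.

The same stages are scriptable from the shell:

```bash
tumorperf synth tracks --k-true 7.3e-15 --seed 1 --out tracks.csv
tumorperf conductivity --input tracks.csv --out k_values.csv
tumorperf synth cohort --seed 1 --out cohort.csv
tumorperf correlate --input cohort.csv --out table.csv
tumorperf simulate ifp --out ifp.csv
tumorperf simulate drug --flow ifp.csv --out drug.csv
tumorperf study --out-dir study/
```

`tumorperf study` runs the conductivity parameter study — three measured
anchor values (9.4×10⁻¹⁶, 8.8×10⁻¹⁵, 1.6×10⁻¹⁴ m²/(Pa·s)) plus two
heterogeneous edge/core maps and their homogeneous equivalents — and writes
a tidy summary (peak/edge/mean IFP, peak IFV and its extent, penetration
depth) plus per-case radial profiles, all stamped with the configuration
hash for byte-identical reruns.

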