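# Methods

This note records the model equations, the assumptions behind them, the
numerical choices, and what the bundled benchmark fixtures do and do not
represent.

## Filtration

Dead-end, incompressible, constant-pressure cake filtration. The filtrate
volume V(t) obeys Darcy's law with a cake term and a medium term,

    dV/dt = ΔP·A / (μ·(α·w·V/A + R_m)),

with w the dry solids deposited per unit filtrate volume (all solids are
assumed deposited by the dryland point, so w = m_solid / V_dryland). The
specific cake resistance is Carman–Kozeny,

    α = 180(1−ε) / (ρ_s·x_sv²·ε³),     k = 1/(α·ρ_s·(1−ε)),

with x_sv = sphericity × Sauter mean of the slurry PSD. Cake porosity ε is
an *input* (empirically estimated in the benchmark cases), not predicted
from the PSD; the porosity relation is used only for volume bookkeeping.
The ODE is integrated with `solve_ivp` (rtol 1e-10) and checked in the
tests against the exact quadratic closed form t(V); both agree to 1e-6.

Endpoints. *Dryland*: the free slurry liquid is exhausted; the residual
liquid is exactly the cake void volume at mother-liquor composition.
*Breakthrough*: bookkeeping removal of pore liquor down to a residual
fraction (default 0.10) of the void volume, composition unchanged. No
deliquoring physics (multiphase flow, capillarity) is modelled.

Hindered settling (Richardson–Zaki, u = u_Stokes(1−φ_v)^n, n = 4.65) is an
optional flag, off by default; when enabled it raises the effective
deposition concentration w by the ratio of the settling velocity at the
Sauter size to the mean filtrate velocity — a first-order pre-concentration
correction, not a sedimentation solver.

## Particle size distribution

Mass-by-size bins with a uniform *number* density within each bin. This
convention makes every mass integral a closed-form quartic, so
growth/dissolution can be applied as exact edge motion (method of
characteristics) followed by conservative overlap re-binning: mass
bookkeeping is exact to round-off, with no numerical diffusion.

Growth/dissolution follows McCabe ΔL: a size-independent linear rate
G = sign(σ)·k_g·|σ|^g moves all diameters equally, so small particles lose
mass fastest and bins shrinking through zero dissolve entirely —
reproducing the fines-first dissolution that raises D50 during washing.

The benchmark slurry PSDs are lognormal. The tabulated moments (median
size 77/94 µm, spread 174 µm) are interpreted as **mass-weighted**, with
the quoted size treated as the mass median (D50): particle-size analyzers
report volume-weighted distributions, and the benchmark's own
end-of-washing D50 tables list the raw material at exactly the quoted
size, which a number-weighted reading cannot reproduce (its spread/mean
ratio of 2.3 would put the mass median in the millimetre range). A
number-weighted moment-matching constructor (`fit_lognormal_psd`) is also
provided and tested; when its span is not given it is widened
automatically from the distribution's partial-moment quantiles, because
heavy-tailed inputs (std ≫ mean) carry second-moment mass far beyond the
visible sizes and a fixed 0.1–1000 µm grid cannot realize the requested
moments. Tabulated PSDs bypass the fit entirely via the config.

## Washing

All wash models are integrated in wash-ratio space (W_r = V_w/V_v). With
volume-matched outflow the flow rate cancels from the species balances,
so wash curves depend only on W_r; hydraulics (constant-pressure Darcy by
default, or constant flow) only set the time axis t(W_r) and the kinetic
relaxation rates, and the equilibrium enforcement makes accepted case-2
runs insensitive to the latter. Outflow is written on a
volume-concentration basis (species outflow = m_j·Q/V_liq with ideal
volume-additive mixing), which conserves liquid volume under matched
volumetric flows for any density pair and yields the exact exponential
washout c/c0 = e^(−W_r) for the single-tank model.

- **Displacement (1a/2a)**: piecewise filtrate composition — mother
  liquor below W_r = 1, wash input above. With dissolution (2a) the wash
  liquor in the voids leaves saturated at c_sat(w = 1); the dissolved mass
  ramps linearly to c_sat(1)·ρ_wash·V_v at one cake volume and is removed
  homogeneously (uniform diameter scaling, shape preserving).
- **Dilution (1b/2b)**: one perfectly mixed holdup, the N = 1 special
  case of the cascade below.
- **Cascade (1c/2c)**: N equal-void-volume tanks in series (default 10),
  layer 1 at the wash inlet. The linear flow operator is advanced by an
  exact affine matrix-exponential propagator per step, so the no-kinetics
  solution matches the Erlang tanks-in-series closed form to solver
  round-off.
- **Axial-dispersion PDE (1c plug-flow form)**: ∂u/∂W_r =
  (1/Pe)∂²u/∂ζ² − ∂u/∂ζ for the local mother-liquor fraction u on the
  dimensionless cake depth, finite-volume method of lines (default 200,
  tests 400 cells), BDF with tridiagonal sparsity. The inlet carries
  advective flux only (the dispersive flux is dropped at the cake top),
  the outlet is zero-dispersive-gradient. Central differencing switches
  to first-order upwind when the cell Péclet number exceeds 2 (logged in
  the metadata). The matching semi-infinite closed form — the flux-inlet
  (third-type) advection–dispersion solution, *not* the Dirichlet-inlet
  form — agrees with the solver to 2e-4 in sup norm at Pe = 100 and 400
  cells. The fixed molecular diffusivity default is 1e-9 m²/s (taken to
  be in m²/s), which at bench velocities gives Pe ~ 1e4–1e5: effectively
  a slightly smeared displacement front. A packed-bed dispersion
  correlation D_L = D + 0.5·u_s·d_p is available as a stand-in where a
  velocity-dependent coefficient is wanted.

### Case-2 equilibrium

The washing models assume the solid and liquid stay equilibrated: after
every flow substep (ΔW_r = 0.005) each holdup's solute concentration is
relaxed to the solubility curve at its local wash-solvent fraction.
Because solute exchange does not change the solvent composition, the
equilibrium solute mass is simply c_sat(w)·(solvent mass) — the
*instantaneous flash* mode solves this algebraically and moves the PSD by
the ΔL that exchanges exactly that mass (bisection on the conservative
shift). The *kinetic* mode integrates the power-law rate instead and
re-runs with k_g × 10 (starting from 1e-6 m/s) until max |σ| ≤ 1e-3 over
the whole run, mirroring the stipulation that the rate constant be chosen
to hold the system at equilibrium. The two modes agree on the final solid
mass change to ~2e-4 relative on the benchmark cases; the Nernst–Brunner
film model (dm/dt = (D/δ)·A_tot·(c_sat − c), δ defaulting to
min(d50/2, 30 µm)) is exposed as the alternative rate form for users who
want a physical time scale rather than a relaxation device.

Deposition requires existing crystal surface: if a layer's solid fully
dissolves, later supersaturation does not nucleate new particles
(nucleation, agglomeration and breakage are out of scope).

Porosity is recomputed per layer from the fixed layer geometry and the
current solid volume; saturation is liquid volume over void volume.
Breakthrough-fed washes first rewet the cake top-down (no outflow until
the voids are full, consuming W_r equal to the emptied fraction); filtrate
fields are NaN during rewetting.

### Mass-balance audit

Every run closes initial(solid + cake liquid) + fed wash =
final(solid + cake liquid) + cumulative filtrate per species; the runner
raises if any residual exceeds 1e-8 relative (observed: ≤1e-13).

## Benchmark fixtures

The two bench cases (paracetamol/isopropanol at 5.895 g solid, 39.9 g
liquid, solute fraction 0.12, ε 0.44, sphericity 0.4127, R_m 1e7 m⁻¹;
mefenamic acid/2-butanol at 4.34 g, 43.4 g, 0.07, 0.3916, 0.4680,
7.05e7 m⁻¹; both at 500 mbar through a 27 mm filter, 25 °C, isothermal)
are generated verbatim from their benchmark operating table. Values the
main text does not tabulate ship as clearly labelled, editable stand-ins
in `properties/`:

- pure-component densities and viscosities: literature values at 25 °C;
- binary solubility curves: synthetic. Each is **anchored at the
  mother-liquor saturation** (c_sat(0) = 0.12/0.88 = 0.13636 g/g for
  paracetamol) so the feed starts exactly saturated, as stated for the
  crystallization liquor. The water and acetonitrile curves carry an
  interior maximum; the heptane curve keeps the documented ~10× drop by
  w = 0.5 followed by a minimal further decline; dodecane and the
  mefenamic-acid curve fall steeply to near zero. The water curve's
  wash-end value (0.017024 g/g) is the benchmark instantaneous
  displacement-wash loss (60.8 mg) divided by the wash mass filling the
  voids — the same arithmetic the displacement model uses, inverted.

Because the curves are synthetic, case-2 *magnitudes* (mg dissolved or
deposited) are fixture properties, not quantitative reference
predictions; the *directions*, curve morphologies, PSD/porosity trends and
all case-1 results are curve-shape independent and are what the test
suite asserts. Users holding the measured binary plots can drop them into
`properties/` or the config and recover quantitative comparisons.

Temperature is carried but unused in kinetics (isothermal runs); the
growth/dissolution activation energy is fixed at zero.

## Problem sizes and determinism

Default discretizations: 120 PSD bins, 10 cake layers, ΔW_r = 0.01 output
grid with 0.005 equilibrium substeps, 200 PDE cells (400 in the
verification tests). A full case-2c run completes in seconds to tens of
seconds on one core. There is no randomness anywhere in the pipeline;
repeated runs are bit-identical.

## Known limitations

- Incompressible cakes only; no cracking, shrinkage or medium blinding.
- No deliquoring physics; breakthrough is a bookkeeping endpoint.
- A single solute; no impurity adsorption/desorption.
- The wash-phase hydraulic time axis uses the filtration-value cake
  resistance with the evolving mixture viscosity; resistance feedback
  from dissolution-driven porosity change is not fed back into t(W_r)
  (wash curves against W_r are unaffected).
- Solubility basis is g solute per g solute-free solvent mixture; curves
  on another basis must be converted before loading.
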