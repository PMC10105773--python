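# Methods

This note documents the models implemented in `limnoch4`, their
assumptions, the defaults that matter, and the numerical choices — in the
spirit of a model-description paper, so a user can judge what a given
output does and does not mean.

## The two P_net estimators

**0-D full-scale balance.** The surface mixed layer (SML) is treated as a
well-mixed reactor at steady state. Sources are the littoral sediment flux
(`A_s·F_s`), the vertical flux through the SML base (`A_z·F_z`, positive
upward into the SML), bubble dissolution (`R_dis·∀_SML`) and net production
(`P_net·∀_SML`); the only sink is emission through the surface (`A_a·F_a`).
Solving for the residual,

    P_net,fs = (A_a·F_a − A_s·F_s − A_z·F_z)/∀_SML − R_dis .

The steady-state assumption means a campaign is interpreted as a snapshot
of a quasi-stationary stratified period; storage change is neglected.
Negative `P_net` is meaningful (net oxidation) and is not clipped anywhere.

**1-D lateral-transport model.** Surface CH4 is assumed radially symmetric
on a disk of radius `r_max = sqrt(A_a/π)`, with `r = 0` at the lake center
and the littoral annulus starting at `r_s = sqrt((A_a−A_s)/π)`. The SML
thickness `H(r)` equals the mixed-layer depth in the pelagic region and
ramps linearly to zero at the shore. The steady balance per unit volume is

    0 = K_H (1/(H r)) ∂/∂r (H r ∂C/∂r)
      + (K_z/H)(C_hyp − C)/Δz
      − (k̄_CH4/H)(C − H_cp·pCH4,atm)
      + F_s(r)/H + R_dis(r) + P_net ,

with `F_s(r)` nonzero only for `r ≥ r_s`, zero-flux conditions at both
radial boundaries, and `K_H = 1.4·10⁻⁴·L^1.07` m² s⁻¹ with `L = r_s`.
`P_net,lt` minimizes the squared misfit to the measured transect stations.
Because the steady equation is linear in `C` and affine in `P_net`, the fit
is a one-parameter linear least squares: we solve once at `P_net = 0` and
once at `P_net = 1` and project the data onto the sensitivity field. A
shore-to-shore transect is folded about its midpoint before fitting
(`r = r_max −` distance to the nearest shore).

Numerics: cell-centered finite volume, 200 cells by default (a
grid-convergence test in the suite compares 200 vs 800 cells), harmonic-mean
face thickness, direct banded solve. The shore cell's thickness is floored
at 0.05 m to avoid the `H → 0` singularity; an implicit-Euler transient
mode exists for cross-validation and converges to the steady solution.

**Cross-model consistency.** For a radially symmetric lake whose boundary
fluxes are exactly the exchanges the 1-D field implies, the volume-integrated
1-D budget reproduces the 0-D `P_net` to well under 1 % (the test suite
requires 5 % over twenty synthetic lakes and a regression R² > 0.95).

## Monte Carlo uncertainty

10,000 iterations by default. `F_a` and `F_s` are drawn from gamma
distributions moment-matched to the measured mean and SD
(`κ = μ²/SD², θ = SD²/μ`) so that draws cannot be negative; `F_z` and
`R_dis` from normal distributions. In the lateral variant `P_net` is
refitted per draw; `F_a` and `F_z` have no direct term in the 1-D equation,
so their draws scale the coefficients they parameterize (`k̄_CH4` with
`F_a/μ(F_a)`, `K_z` with `F_z/μ(F_z)`) — flux uncertainty mapped to
coefficient uncertainty at fixed gradient. `R_dis` stays at its mean in the
lateral variant (its SML contribution is small). All draws derive from one
seed; identical seeds give bit-identical sample vectors.

## Gas exchange

Henry solubility `H_cp(T)` comes from the published moist-air equilibrium
fit for CH4 in fresh water (salinity terms dropped), evaluated as
equilibrium concentration per unit partial pressure so that altitude enters
linearly through the barometric site pressure. The Schmidt number uses the
standard freshwater polynomial in temperature. k600 parameterizations
implemented: CC98 (`2.07 + 0.215·U10^1.7`), MA10-NB (`2.045·U10 + 2`),
MA10-MB (`2.25·U10 + 0.16`), MA10-PB (`1.75·U10 − 0.15`, clipped at zero at
low wind — a piston velocity cannot be negative; the clip is logged), VP13
(`2.51 + 1.48·U10 + 0.39·U10·log10(A)` with `A` in km²), plus a
chamber-mean passthrough. Conversion to CH4 uses `(600/Sc)^n` with
`n = 2/3` below 3.7 m s⁻¹ wind and `1/2` above.

Headspace back-calculation: total moles after equilibration (gas phase by
ideal gas, water phase by Henry's law at the measured mixing ratio) minus
the CH4 introduced with the ambient fill gas, per water volume. Negative
results (blank contamination) clip to zero with a warning.

## Surface and benthic flux estimators

Floating chamber: OLS slope of the headspace ppm curve over the first
5 minutes (first 10 s skipped as a placement artifact, configurable),
converted by the ideal gas law; deployments with fit R² < 0.97 are flagged
and excluded rather than returned. Chamber k: `k = F_a/(C_w − C_eq)`,
undefined within a configurable ε of equilibrium.

Benthic chamber (closed incubation, ~1 h): three methods. The integrated
method uses only the endpoint head-space pressures and dissolved
concentrations. The transient method fits `(F_s, k_bc)` to the full curve;
we fit the closed-form integral `P(t)` of the transient balance rather than
the differentiated series — same parameters, no numerical differentiation
of 1 Hz noise — with `k_bc` bounded in [0, 40] m d⁻¹. The equilibrium
method uses the linear tail slope once the exponential transient (time
scale `1/(b·k_bc)`) has decayed; on series too short for that decay it
biases high and the transient method should be preferred. The chamber
estimate is the mean of the three; the combined littoral `F_s` averages the
chamber and porewater estimates, with the SD taken across the independent
estimates.

Porewater method: Fick's law over the linear top 3 cm (OLS slope),
`F_s = φ·D_CH4·θ⁻²·∂C/∂z` with defaults φ = 0.9, θ² = 1.2,
`D_CH4 = 1.5·10⁻⁵ cm² s⁻¹`; positive flux = efflux to the water column.

## Vertical mixing

Thorpe analysis of a CTD cast in a layer around the SML base (default
±1 m, configurable): sort temperatures into the stable arrangement,
displacement = distance each sample moves, `L_max` = largest displacement,
`L_T = (√2/7.3)·L_max`, `K_z = γ_mix·L_T²·N` with γ_mix = 0.15 and `N` from
the sorted profile's density gradient (temperature-only equation of state —
adequate for dilute alpine waters; conductivity is ignored). Displacements
below twice the noise-equivalent length (0.01 °C sensor noise divided by the
layer-mean gradient) are zeroed; a cast with no surviving overturn returns
a near-molecular floor `K_z = 10⁻⁷ m² s⁻¹`, flagged, rather than zero. The
vertical CH4 flux is `F_z = K_z·∂C/∂z` with the gradient measured across
the SML base at ~1 m resolution; positive means CH4 moves up into the SML.

## Bubbles

**Single-bubble dissolution.** A bubble of default diameter 5 mm carrying
{CH4, CO2, O2, N2} rises from its release depth; per depth step and gas the
exchange is `A_bubble·k_b·(H_cp,i·P_bub·x_i − C_water,i)`, the radius is
recomputed from total moles and local pressure, and the rise speed comes
from a piecewise clean-bubble terminal-velocity fit. The gas-side transfer
coefficient uses the Sherwood correlation `Sh = 2 + 0.6·Re^1/2·Sc^1/3`;
both correlations are injectable callables since published discrete-bubble
models differ in these closures. Midpoint (RK2) stepping at 0.05 m;
per-gas mass is conserved by construction (clipped losses) and the suite
checks closure to 0.5 % and 1 % grid convergence of the SML dissolution
`r_i` against 10×-finer steps. N2 is carried as the inert balance gas
(default synthetic composition 70 % CH4 / 30 % N2).

**R_dis aggregation.** `R_dis(z) = Σ_bottom..z r_i·(F_eb,SWI,i/n_0,i)·
ΔA_sed,i / A_p(z)`; `F_eb/n_0` is interpreted as the bubble number flux,
since both are per-bubble CH4 amounts.

**Sediment ebullition.** A steady two-layer column: above a non-ebullitive
surface layer `z_eb,min` (exposed as a parameter; default 2 cm) production
and diffusion balance (`φD_i C_i″ + W_i = 0`); below it free gas forms
whenever the summed dissolved-gas pressure `Σ K_H,i·C_i` would exceed the
local critical pressure `P` (hydrostatic + atmospheric, no overpressure
term), adding the stripping sink `E·K_H,i·C_i/P` per gas — each gas is
stripped in proportion to its partial-pressure contribution, and `E` is the
total gas ebullition per bulk volume. CH4 production is
`W(z) = W₀·exp(−z/λ)` with λ = 0.05 m; `W₀` is calibrated (scalar root
find) so the diffusive SWI flux equals the measured `F_s`. Numerically the
column is marched to steady state with implicit diffusion steps plus
proportional saturation clipping; the clipping rate at steady state is
`E(z)`, which makes total production = SWI diffusion + ebullition hold to
better than 1 % by construction. An independent shooting-method solve
verifies the finite-difference profile on an unsaturated toy column.

`F_eb,need = P_net·∀_SML/(β·A_sed)` gives the ebullition flux that would be
needed to sustain a given `P_net` purely by bubble dissolution, with β the
SML-dissolved fraction from the single-bubble model.

## Sensitivity analyses

- **Transfer-velocity error on P_net:** `P_net_err = (F_a·A_s/(P_net·∀_SML))·k_err`.
  The source relation multiplies `F_a` by the sediment area `A_s` even
  though the atmospheric term of the 0-D budget uses `A_a`; we implement it
  as printed and expose `atm_area="surface"` to use `A_a` instead. Undefined
  at `P_net = 0` (consistent with excluding negligible-P_net cases).
- **k600 configuration grid:** simulated transect concentrations under
  combinations of (`P_net` ∈ {0, P_net,fs}) × (k parameterizations),
  compared to the measured stations by RMSE / Pearson-R² / mean normalized
  bias, all in log10 space when concentrations span orders of magnitude.
  MNB is defined as `100·mean((pred−obs)/obs)` — the formula is not
  standardized in the literature; the alternative `bias/mean(obs)` was
  rejected to keep "normalized" pointwise.
- **F_s,need:** the littoral flux that closes the 0-D budget at
  `P_net = 0`, with a Monte Carlo variant.
- **Upscaling regression:** OLS of the specific rate `P_net/C_CH4` (d⁻¹) on
  `Chla × LC × Z_s`, with the light climate `LC = 2.5·Z_s/H_SML`.

## SML detection

The SML base is the shallowest depth where `∂T/∂z` (z positive downward)
first drops below −1 °C m⁻¹, using centered differences and optional
3-point median pre-smoothing (default on; raw sensor spikes otherwise
produce spurious gradients). Profiles whose gradient never crosses the
threshold are returned as unstratified at their deepest depth instead of
erroring, so shallow fully mixed lakes remain processable.

## Synthetic data: what it does and does not emulate

The generators produce: internally consistent lake geometry (areas ↔ radii
↔ SML volume by the revolution integral of `H(r)`); boundary-flux tables in
which `F_a` and `F_z` are *derived* from the forward 1-D solution at the
lake's true `P_net` (they are the exchanges a chamber/gradient campaign
would measure, and independent draws would make the budget inconsistent by
construction); transects sampled from the steady curve with multiplicative
lognormal noise (default 5 %); two-layer CTD casts with optional block-
reversal overturns and 0.02 °C noise; linear chamber curves (0.5 ppm
noise); closed-form benthic incubation curves; and linear-top/exponential-
tail porewater profiles. Preset ranges are anchored to observed conditions
in small pre-alpine lakes — eutrophic surface fluxes of a few
mmol m⁻² d⁻¹, oligotrophic an order of magnitude lower, SML depths of
1–6 m — parameterized as ranges rather than as any individual lake.

Not emulated: wind-driven advection of the surface patch, macrophyte
near-shore CH4 accumulation (observed in real transects as single
high-concentration shore stations), δ13C dynamics (isotope columns are
carried through untouched), storage change between campaigns, and
conductivity effects on density. Passing tests therefore demonstrate
correctness of the estimators under the models' own assumptions, not that
those assumptions hold in any particular lake.

## Known limitations

- The lateral model's `P_net` is spatially uniform; a radially varying
  production would be absorbed into the fitted constant.
- The 0-D/1-D agreement degrades when the measured fluxes are mutually
  inconsistent (real campaigns); the Monte Carlo spread is then the honest
  summary, not the point estimate.
- The bubble correlations are clean-bubble defaults; surfactant-covered
  ("dirty") bubbles dissolve faster. Both closures are injectable.
- The sediment model is steady-state; episodic ebullition (pressure drops,
  temperature pulses) is out of scope.
- The equilibrium benthic method requires `1/(b·k_bc)` ≪ deployment time;
  it is reported with a low-confidence flag when the tail slope is not
  distinguishable from noise.
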