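# Methods

This note records the model, its parametrization, the numerical choices,
and what the synthetic-data studies do and do not demonstrate.

## Model

### Solution thermodynamics

The cytosol is treated as an ideal dilute binary solution of water and
dissociated salt.  The water mole fraction at cell volume V is
`x_w = [(V − V_b)/v_w] / [(V − V_b)/v_w + φ·n_s]` with osmotically
inactive volume V_b, water partial molar volume v_w = 18.02 cm³/mol,
dissociation constant φ = 2, and salt content n_s.  The equilibrium
freezing temperature solves `ln x_w = (ΔH_f/R)(1/T_R − 1/T_f)` with
ΔH_f = 1.436 kcal/mol taken temperature-independent and T_R = 273.15 K.
Both this relation and its inverse (the equilibrium dehydration curve
V_eq(T)) are evaluated in closed form; no root finding is involved.

n_s is never measured directly; it is pinned by requiring the isotonic
cell (V = V0) to freeze at T0 = −0.5 °C, the freezing point of
physiological saline.  This closes the parameter system exactly and
makes the isotonic state internally consistent by construction:
changing V_b re-derives n_s.

### Dehydration

Cell volume along a linear ramp at rate B follows the two-parameter
water-transport ODE (see README).  Defaults and units:

| parameter | meaning | default | units |
|---|---|---|---|
| V0       | isotonic volume (radius 7.51 μm) | 1774.2 | μm³ |
| V_b      | osmotically inactive volume | 0.25·V0 | μm³ |
| L_pg     | permeability at 273.15 K | 0.1166 | μm·min⁻¹·atm⁻¹ |
| E_Lp     | water-transport activation energy | 11.9236 | kcal·mol⁻¹ |
| B        | cooling rate | 5–100 | K·min⁻¹ |

L_pg and E_Lp are the pooled-fit values for HeLa cells; V_b is an
assumption (its true value is rarely reported) and is itself a fitted
parameter in stage 1.  With these values the membrane permeability at
−40 °C is 2.4% of its −0.5 °C value, which is why fast-cooled cells trap
water: at 5–15 K/min the trajectory hugs the equilibrium curve below
about −8 °C, while at 100 K/min the cell still holds half its water at
−50 °C.

The exchange area is recomputed from the instantaneous volume through
the sphere model at every step (`area_mode="sphere_dynamic"`); a
constant-area variant is available because the literature contains both
conventions.

### Viscosity

Water viscosity uses a free-volume form
`η_w = η_w0·exp[ V̂_w / (K11/λ · (K21 + T − T_gw)) ]` with the literature
water parameters V̂_w = 1.071 cm³/g, K11/λ = 2.18·10⁻³ cm³/(g·K),
K21 − T_gw = −152.29 K (T_gw = 136 K), and η_w0 = 0.0306 mPa·s anchored
so that η(20 °C) ≈ 1.00 mPa·s; the curve then gives 1.78 mPa·s at 0 °C
(tabulated: 1.79) and diverges at 152.3 K.  The cytoplasm adds a
crowding factor g(φ) on the salt volume fraction φ = n_s·v_s/V; the
default is a Krieger–Dougherty form (φ_max = 0.64, intrinsic viscosity
2.5) and is a pluggable callable because the exact composition
dependence is not well constrained — at physiological salt loads
(φ ≤ 0.004) the correction is below 1% and immaterial.

### Nucleation and PIF

Each mechanism's rate law and the hazard quadrature are given in the
README.  Conventions fixed here:

- η_ref and T_f0 are the isotonic-composition viscosity and freezing
  point, so Ω₀ is the rate scale of the isotonic state.
- the κ-correction (T_f/T_f0)⁴ makes κ₀ carry K⁵.
- SCN's Ω₀ is per m²·s, VCN's per m³·s; μm→m and min→s conversions
  happen in exactly one place (the hazard density).
- VCN's size factor is the total cell volume V (a water-volume variant
  `vcn_water_volume=True` exists).
- optional `prefactor_mode="dehydration"` multiplies the rate by the
  relative number of available water molecules (A/A0 for SCN,
  (V−V_b)/(V0−V_b) for VCN); default off — the dehydration dependence
  then enters only through S(T), T_f(T), η(T).
- the critical-volume gate is inclusive: the rate is active at V = V_f
  exactly.

The rate is non-monotone in supercooling: the thermodynamic barrier
opens as T falls but the diverging viscosity closes the kinetics, so
nucleation is confined to a temperature window.  A consequence worth
knowing: in this formulation the *ungated* model does not necessarily
race to PIF = 1 by −100 °C unless the kinetic prefactor is very large —
deep-subzero hazard is viscosity-suppressed, and dehydration lowers T_f
which shrinks the supercooling.  Fitted ungated curves extrapolate to
0.54–0.68 at −100 °C on plateau data rather than to 1 (the divergence
reported in the source experiments reflects fitted VCN prefactors of
1e20–1e27 sitting on the degenerate direction described below).

### PIF quadrature

PIF curves use cumulative trapezoidal quadrature on the trajectory grid
(default 0.05 K).  With a critical volume the cumulative hazard is
truncated at the gate-closing temperature found by linear interpolation
of the monotone volume trajectory, not at the nearest grid node.  This
matters for fitting: node-snapped gating makes the objective
piecewise-constant in V_f at finite-difference resolution and gradient
descent cannot move the gate at all.  Against a 10⁵-interval midpoint
Riemann oracle the curves agree to ≲3·10⁻⁵ absolute; refining the grid
from 0.05 to 0.025 K changes them by <10⁻³ relative.

## Synthetic data

The generator emulates the two data products of a cryomicroscopy
freezing study from known ground truth:

- **volume tables** — per rate, readings every 2 K from −0.5 to −45 °C,
  each synthetic cell reporting `v·(1 + σz)` with σ = 0.02
  (multiplicative segmentation noise), summarised as mean ± SEM of
  n = 30 cells;
- **event tables** — per cell (n = 200 per rate at 45/60/75/100 K·min⁻¹,
  ramp to −50 °C), a first-ice temperature drawn by inverse-CDF sampling
  of the cumulative hazard, or censoring at ramp end; the triggering
  mechanism is attributed by a Bernoulli draw on the instantaneous
  hazard share (exact for independent competing risks); SCN events are
  labelled "darkening" and VCN events "twitching" as a configurable
  convenience — the association is phenomenological, not asserted.

All randomness flows from one seed through named substreams, so tables
are bit-reproducible.

The ground-truth nucleation parameters (Ω₀^SCN = 2.7·10⁸ m⁻²s⁻¹,
κ₀^SCN = 3.5·10⁹ K⁵, V_f^SCN = 0.50·V0; Ω₀^VCN = 3·10¹⁸ m⁻³s⁻¹,
κ₀^VCN = 8·10¹⁰ K⁵, V_f^VCN = 0.40·V0) were chosen once so that, under
the conventions above, the study phenomenology is realistic: ice forms
between about −10 and −45 °C, combined PIF rises with cooling rate
(0.17 / 0.44 / 1.0 / 1.0 at 45/60/75/100 K·min⁻¹), stays below 0.5 for
rates under 75 K·min⁻¹, and plateaus once the gates close.  Published
per-study constants do not transfer across prefactor conventions, so
they cannot be used verbatim.  One structural limitation is inherent to
a *shared* parameter set: at the fastest rates the cell stays so wet
that VCN saturates before its gate closes, so V_f^VCN is informed
chiefly by the mid-rate (60 K·min⁻¹) plateau; real studies resolve this
by letting V_f grow with B.

What passing the synthetic studies shows: the estimation machinery
recovers the parameters of the model that generated the data, at
realistic study sizes and noise.  What it does not show: that the model
is correct for real cells (no imaging artifacts, no cell-to-cell
parameter heterogeneity, no seeding-transient volume excursions, no
mechanism-label misclassification are simulated).

## Fitting

Two stages, mirroring experimental practice ("pooled fitting" =
one shared parameter set against all records simultaneously):

1. **Water transport**: (log₁₀L_pg, E_Lp, V_b/V0) by bounded
   trust-region least squares on pooled normalized volumes across all
   rates; n_s re-derived from the isotonic condition for every V_b
   candidate; R² uses a single pooled SST.  Default 3 seeded LHS starts
   — the problem is well-conditioned.
2. **Nucleation**: trajectories predicted from the frozen stage-1
   estimates; (Ω₀, κ₀) per mechanism searched in log₁₀ space (bounds
   10⁵–10³⁰ and 10⁸–10¹³) because their identifiable magnitudes span
   decades; critical volumes as fractions of V0, with
   V_f^VCN = f_lo + ratio·(V_f^SCN − f_lo), ratio ∈ [0,1] — the
   ordering V_f^SCN ≥ V_f^VCN is structural, which removes a label-swap
   local optimum.  Objective: SSE of modelled combined PIF against the
   observed both-mechanisms PIF, per rate (`fit_pif`) or shared across
   rates (`fit_pif_pooled`).

The gated objective is rugged: basins in the V_f directions are a few
0.01·V0 wide, and each basin has its own compensating (Ω₀, κ₀) ridge.
The global phase therefore: (a) fits the ungated model; (b) anchors the
SCN kinetics by 2-parameter surface-only fits to the low-PIF early rise
(pure SCN before any gate closes), keeping all distinct low-SSE ridges;
(c) runs short full-space polishes from every kinetics candidate over a
dense grid of gate positions (step 0.05 in f_scn); (d) polishes the best
candidates without iteration limits, together with a seeded
Latin-hypercube design (default 20 starts).  Finite differences use a
relative step of 10⁻³ (the interpolated gate makes the objective
piecewise-smooth; the default square-root-epsilon step sees zero
gradient across a gate cell).  Refitting with the same seed is
bit-reproducible.

Diagnostics: a critical volume pinned at a search bound is flagged, and
the fit reports when a 10× perturbation of Ω₀^VCN changes the objective
by less than 10⁻³ — the classic sloppy direction of this model (any
channel whose onset lies below the data window leaves the objective
unchanged).

No confidence intervals are reported; the estimates are point estimates
with the degeneracy flag as the only uncertainty signal.

## Numerical choices

- ODE: LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ μm³ (the problem stiffens at low
  temperature as L_p collapses); dense output every 0.05 K; fitting
  loops evaluate only at observation temperatures.  Terminal volumes
  agree with a 1 mK explicit-Euler march to ~10⁻⁵ relative.
- Impermeable membrane (L_pg = 0) short-circuits to constant volume.
- Degenerate inputs raise typed errors: volumes at/below V_b,
  temperatures outside the free-volume domain (T ≤ 152.3 K), PIF values
  outside [0,1], non-monotone cumulative PIF, single-rate pooled fits.
- Event sampling inverts the cumulative hazard by linear interpolation
  within the grid cell where it crosses the cell's exponential deviate;
  flat (gate-closed) stretches can never contain an event.

## Problem sizes

The shipped studies use 5 volumetry rates × 30 cells × ~22 temperatures,
4 event rates × 200 cells, 10,000 cells for the Monte-Carlo consistency
check, 10⁵ quadrature oracle intervals, and 1 mK Euler oracle steps; the
full two-stage recovery runs in about a minute on one core.

## Known limitations

- Exchange-area convention (dynamic sphere) and the Eq-composition of
  cytoplasm viscosity are conventions, selectable but not data-driven.
- V_f^VCN identifiability degrades when no rate's gate closes inside the
  observation window (see above).
- The plateau value of a gated mechanism is extremely steep in V_f near
  the gate; with few cells the fitted V_f inherits that sensitivity.
- The generator does not model the warm-side volume artifact seen in
  fast-cooling experiments (attributed to imaging), and the
  darkening/twitching labels are a simulation convenience.
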