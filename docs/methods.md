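# Methods

## Model overview

`emboflow` models transarterial thermoembolization — delivery of a reactive
acid chloride (dichloroacetyl chloride, DCACl) dissolved in Lipiodol into a
hepatic artery — as three coupled 1D problems on a vascular graph:

1. **Geometry.** A centerline image (nonzero voxels on vessel skeletons,
   voxel value = local radius in mm) is converted to a graph: every
   centerline voxel is a pressure node, voxels within one step in each axis
   (26-connectivity) are joined by an edge whose length is the physical
   inter-center distance, and the largest connected component represents
   the artery. Degree-1 nodes are open ends: the thickest one is the
   pressurized root (the catheterized feeding vessel, overridable by voxel
   index), the rest are outflow terminals. Edge radius is the mean of its
   endpoint radii. Cycles arising from diagonal chords are retained; the
   flow problem is well posed on any connected graph.

2. **Hemodynamics.** Steady Hagen-Poiseuille flow: each edge is a resistor
   with conductance k = πR⁴/(8μL); mass balance Σⱼ kᵢⱼ(Pᵢ−Pⱼ) = 0 holds at
   interior nodes; the root is held at mean arterial pressure (100 mmHg);
   each terminal drains to the central venous pressure (5 mmHg) through a
   lumped conductance γₐ/μ representing the unsegmented downstream bed (a
   Robin condition, Σⱼ kᵢⱼ(Pᵢ−Pⱼ) + (γₐ/μ)(Pᵢ−P_CVP) = 0). The reduced
   system is symmetric positive definite and solved by a sparse direct
   method; the contract is a mass-balance residual ≤ 1e-10·q_total and the
   maximum principle P_CVP ≤ P ≤ P_MAP, not a particular algorithm.

3. **Transport.** The bolus is a homogeneous miscible mixture advected
   passively on the static flow field (no viscosity feedback, no
   occlusion feedback — both are known limitations of this model class)
   while DCACl hydrolyzes at first-order rate λ = γₜ·ε·ρ_DCACl/ρ_o.
   Finite-volume upwind on the graph: node x owns half of each incident
   cylindrical segment (ΔVx), receives flux-weighted upstream saturation
   and decays at λ. Backward Euler in time (unconditionally stable,
   positivity-preserving, saturation stays in [0, 1]). Per node, the
   reacted share of the injected volume accumulates into the damage score
   Dx; the unreacted outflux through terminal sinks accumulates into the
   escape fraction β; injected = reacted + escaped + resident holds to
   round-off at every step by construction. Nodes with Dx ≥ δ are predicted
   embolization sites. The hydrolysis heat sources a temperature-rise field
   advected by the same scheme (no conduction or perfusion losses, so the
   reported ΔT is an upper envelope within the model).

## Calibrated parameters

| parameter | meaning | units | how set |
|---|---|---|---|
| γₐ | lumped terminal-to-vein conductance | m³ | Nelder-Mead on log₁₀γₐ so that simulated perfusion matches a weight-derived reference (tolerance 1e-16; contract: relative perfusion error ≤ 1e-6) |
| γₜ | DCACl hydrolysis time constant | 1/s | multi-start Nelder-Mead (10 uniform starts in (10, 20)) minimizing g = β + (1 − α), α = balanced accuracy of predicted vs observed embolization sites |

The perfusion reference comes from porcine physiology: liver mass =
2.04% ± 0.33% of body weight, hepatic flow = 22.28 mL/min per 100 g liver;
mean ∓ SD give q_mean and the [q_min, q_max] uncertainty band. Perfusion is
strictly monotone in γₐ, so a bisection oracle cross-checks the optimizer
in the tests. The calibration is performed on log₁₀γₐ because the
physically plausible range spans decades and positivity must be preserved.

Fixed physical constants (defaults in `config.py`): blood μ = 8.9e-4 Pa·s,
ρ_b = 1045 kg/m³, c_p,b = 3600 J/(kg·K); bolus ρ_o = 1280 kg/m³; DCACl
ρ = 1532 kg/m³, molar mass W = 0.147 kg/mol, 2 M solution, hence volume
saturation ε = 1000·M·W/ρ_DCACl = 0.1919; exothermic release h = 138
kJ/mol. W = 0.147 is chosen for internal consistency: it reproduces ε
exactly from the stated molarity.

## Numerical choices

- **Units.** mmHg, mL/min, µL, mm at every interface; SI internally
  (1 mmHg = 133.322 Pa). Conversions live in `units.py` only.
- **Time step.** Δt = 0.5·min(L/|u|) over flow-carrying edges (Courant
  0.5). The implicit scheme is stable at any Δt; the cap limits numerical
  diffusion. Halving Δt changes total damage by < 1% on the pipe benchmark.
- **Injection.** Default is a slug: inlet saturation 1 for
  T = V_DCACl/q_root (pure bolus briefly displacing blood at the catheter).
  `InjectionSpec(duration_s=...)` instead models a rate-limited hand
  injection with constant dilute inlet saturation. Damage patterns are
  nearly duration-invariant (Dx is normalized by injected volume and the
  quasi-steady spatial profile is the same), but the temperature field is
  not: a coherent slug self-heats toward the model's intrinsic ceiling
  h·ρ_o/(W·ρ_b·c_p,b) ≈ 319 K, whereas a ~minute-long injection keeps the
  inlet dilute and the predicted rise sub-degree — the physiologically
  observed regime. The energy equation uses blood ρ·c_p as the carrier
  continuum.
- **Stopping and the closed-form tail.** Stepping stops when the resident
  bolus volume falls below 1e-6 of the injected volume (step cap 10⁶).
  Once the inlet saturation is zero the update is a fixed linear map
  s ↦ (I + ΔtM)⁻¹s, so the remaining damage/escape integrals are geometric
  series with exact sum M⁻¹s; `tail_closure=True` finishes a run that way.
  It is the exact limit of the stepping loop and agrees with it to the
  stopping threshold (asserted in the tests); the calibration uses it
  because it cuts each simulation from thousands of steps to the injection
  window plus one sparse solve.
- **Memoization.** g(γₜ) evaluations are cached per calibration context
  (keyed on γₜ rounded to 10 decimals); Nelder-Mead restarts re-use them.
- **Degenerate inputs.** All-zero centerline volumes, non-3D images,
  non-positive radii, roots that are not open ends, zero-flow networks and
  perfusion targets above the γₐ→∞ ceiling all raise typed errors rather
  than producing silent nonsense.
- **Tie-breaks.** Equal-size components select the one containing the
  smallest flattened voxel index; builds are bit-reproducible.

## Synthetic data generator

`synthetic.py` emulates the imaging products the pipeline consumes:
voxelized bifurcating trees (dyadic layout with disjoint lateral sectors,
so non-adjacent branches can never touch on the grid; Murray's-law radii,
child = parent·2^(−1/3); endpoint jitter; straight axis-aligned tails at
the root and tips so open ends stay degree-1 under 26-connectivity) and
forward-simulated observation masks: run the full pipeline at a known
(γₜ, δ), paint tagged nodes into voxels, optionally flip labels.

Default conditions are study-scale: a 34 kg subject, 400 µL bolus, depth-5
tree, 0.5 mm voxels, root radius 2.5 mm (pig common hepatic artery
caliber) tapering to ≈0.8 mm tips, trunk 20 mm with per-generation shrink
0.8. The tree size matters scientifically: damage per node scales with
λ·ΔVx/q_x, so the vessel calibers and transit times must be large enough
for 1%-threshold tagging to be non-trivial and for distal damage to peak
near γₜ ≈ 14 1/s — otherwise the calibration objective has no interior
minimum and γₜ is unidentifiable. With these defaults the recovery
experiment inverts γₜ to ~1% relative error.

What the generator does **not** emulate: real hepatic branching anatomy
(it is a symmetric planar tree), CT noise and point-spread, segmentation
gaps (components are always connected), and registration error between
centerline and observation mask. Passing tests therefore demonstrate
correctness of the numerics and identifiability under clean conditions,
not predictive accuracy on animal imaging data, which requires the
original study's (undeposited) scans.

## Problem sizes

The default fixture graph has ~1400 nodes; transport runs take ~10 ms with
the closed-form tail and a few seconds when stepping a 60 s injection with
temperature. The uncertainty demo uses a reduced 3×3 (q_ref, δ) grid and
the parameter-recovery experiment 5 seeds × 10 starts; both complete in a
few minutes on one core. The full 10×10 grid per subject is available
through the same API/CLI and scales linearly in cells.

## Known limitations

- Miscible single-velocity advection: real boli form immiscible Lipiodol
  droplets; stasis and vessel blockage feed back on the flow, which this
  model ignores (flow is solved once, before injection).
- One scalar γₐ shared by all terminals; per-terminal outflow conditions
  are out of scope.
- No 3D tissue coupling: heat and reaction products stay in the lumen.
- The balanced-accuracy objective is piecewise constant in γₜ between
  tagging changes; Nelder-Mead handles the plateaus but reported optima
  are only meaningful to roughly the plateau width (~0.1 1/s on the
  default fixture).
- γₜ identifiability depends on the tree realization: the objective's
  valley floor (β still falling, no tagging change yet) can be flat enough
  on some jittered variants of the fixture that the global minimum sits up
  to ~17% above the generating value, while the default fixture and most
  variants recover it to ~1%. The recovery guarantee is therefore stated
  for the default fixture geometry; on new geometries the valley should be
  profiled before trusting a point estimate.
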