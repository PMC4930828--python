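# Methods

`antrosim` is a reduced-order (quasi-1D) Euler–Euler model of multiphase
digestion in the antroduodenal portion of the gastrointestinal tract: the
distal stomach (antrum), the pyloric sphincter and the duodenum.  This note
records the model, its assumptions, the numerical scheme, the choices made
where the design was genuinely open, and what the reduction can and cannot
be expected to reproduce.

## Model

### Phases and components

The chyme is treated as interpenetrating continua: a liquid phase (index
j = 1) and five food-particle size classes j = 2..6 with fixed
representative diameters 3.6, 2.8, 1.7, 0.7 and 0.2 mm.  Volume fractions
satisfy Σ_j α_j = 1.  The liquid carries ten dissolved components i = 0..9
(mass fractions, Σ_i Y_i = 1): hydrochloric acid, the NaCl + CO₂
neutralization product, sodium bicarbonate, dissolved proteins, fats and
carbohydrates, a trace chemical (lead as the exemplar), pepsin,
polypeptides, and water.  Particles share one composition β over
{protein 0.013, fat 0.001, carbohydrate 0.093 − β₆, lead β₆ = 2.8·10⁻⁷,
water 0.893} (raw carrot); all classes share one density (1040 kg/m³ in the
baseline, 1005 kg/m³ in the low-density scenario).

### Chemistry

* **Neutralization** NaHCO₃ + HCl → NaCl + H₂O + CO₂ at molar rate
  k₀₂ C₀ C₂ with k₀₂ = 10⁴ m³/(kmol·s).  The product NaCl + CO₂ is carried
  as a single inert component whose molar mass (102.45 kg/kmol) makes the
  reaction conserve mass exactly.
* **pH** is −log₁₀ of the HCl molar concentration (kmol/m³ ≡ mol/L), floored
  at 10⁻⁸ kmol/m³ so acid-free fluid reports the cap pH 8.  There is no
  hydroxide or carbonate speciation: pH is meaningful on the acidic side and
  "pH 8" simply labels the alkaline regime.
* **Proteolysis** is Michaelis–Menten in dissolved protein, linear in
  pepsin, and modulated by the quadratic activity factor
  f(pH) = max(0, a·pH² + b·pH + c) with a = −5.786, b = 26.819, c = −4.857
  (optimum pH 2.32, zero above pH 4.45).  The rate expression as written
  yields a mass rate directly (the protein factor is a mass concentration,
  the enzyme factor a molar one); no additional molar-mass scaling is
  applied, and polypeptides gain exactly the protein mass lost.

### Particle dissolution and the size cascade

Dissolution is surface-limited: bin j transfers mass to the dissolved
components at 6·k·α_j/d_j partitioned by β, with
k = k_phys · 3.246 · pH^(−2.092), k_phys = 2.72·10⁻⁴ kg/(m²·s), clamped to
zero at pH ≥ 7.  Shrinking of partially dissolved particles is represented
at fixed bin diameters by a cascade flux from bin j to bin j+1,
m″ = 6 d_{j+1}³ k α_j / (d_j (d_j³ − d_{j+1}³)), read in the form that is
dimensionally consistent with k as a surface mass-transfer coefficient.
The smallest class (0.2 mm, nondigestible fibre) neither dissolves nor
cascades; it only gains mass.

### Secretion and absorption

Gland outputs are formulated as **total region rates** (kg/s, the numerators
of the published per-volume constants) and distributed over the wall cells
of their region in proportion to wall area; the wall-layer volumes V(l)
(needed only to express volumetric densities) are derived from the geometry
as 10% of each region's enclosed volume.  Acid (upper antrum) follows a
saturable Michaelis form in the region-mean dissolved-nutrient
concentration on top of a basal rate (maximal 2.02·10⁻⁷ kg/s, basal a fifth
of that); pepsin depends on dissolved protein alone; bicarbonate (lower
antrum, outlet/proximal duodenum, pancreatic region) is saturable in the
local acid concentration — the neutralization feedback.  Water is
co-secreted at fixed mass ratios (171.3 for gastric juice; 395.5 and 78.3
for the alkaline fluids) so gland fluids have constant composition.  Every
secretion scales linearly with the region's secretory functionality
F(l)(1) ∈ [0, 1] and absorption with F(l)(2); motor functionality F(l)(3)
scales the wave amplitude.  Lead is absorbed across all wall regions at
3.34·10⁻³ s⁻¹ times the cavity–blood concentration difference (blood
concentration held at zero).

### Momentum reduction

The full per-phase momentum equations are replaced by a drift-flux closure:
the mixture moves with the area-mean axial velocity dictated by
incompressibility, and each particle class slips relative to it at the
terminal velocity solving K_j1 (v₁ − v_j) + α_j (ρ_j − ρ_mix) g_axis = 0,
with the low-Re drag correlation
K_j1 = 18 α_j α₁ η₁ / d_j² · (1 + 0.15 Re^0.687) and ρ_mix the local
mixture density.  The implicit Re dependence is solved by damped fixed-point
iteration.  Slips are corrected by the volume-mean drift so the net
volumetric slip flux vanishes (the drift-flux constraint), capped at
0.1 m/s, and sedimentation flux into cells above a 0.62 packing fraction is
suppressed.  Particle–particle drag is implemented (symmetric Wen–Yu-type
form) but inter-particle slip is set to zero in transport: the reduction
resolves only particle–liquid relative motion.  Gravity enters through a
per-cell cosine between the centerline and the vertical; the default
upright posture has cos = −0.5 in the antrum (the bulge is the lowest
point) and 0 in the duodenum.

### Geometry, motility, gating

The tract is a tube of circular cross-section along the centerline
coordinate x: an antral bulge (radius 35 mm tapering to the 4 mm pyloric
constriction over 84 mm), an 8 mm sphincter, and a 180 mm duodenal tube of
radius 10 mm.  Antral waves (period 18 s, width 20 mm, amplitude 9 mm,
speed 2.2 mm/s, lifetime 38 s) and duodenal waves (9 s, 40 mm, 3.5 mm,
5 mm/s, 36 s, born at the sphincter) indent the wall as travelling squared
sinusoids.  Contractions deepen as they propagate: the indentation grows
linearly over 19 s (reaching full depth near the mid-antrum, where gastric
peristalsis is observed to strengthen) and decays over 2 s before death.
This growth envelope is also what keeps the antral pump physiological — an
indentation appearing at full depth in the wide bulge would displace
~15 mL per cycle into the duodenum.  The pyloric gate opens for 2 s every
18 s, phased so opening coincides with a wave crest reaching the
mid-antrum.  In the solver the gate acts on the interface flux (and blocks
dispersion/diffusion) while the pyloric lumen keeps its open-gate volume; a
collapsing-lumen discretization would produce zero-volume cells.

## Numerical scheme

Finite volumes on a uniform grid (Δx = 2 mm by default, 136 cells), explicit
time stepping at a 20 ms base step with substeps capped by a combined
advective Courant number of 0.9 and aligned with gate transitions.  Each
substep:

1. **Sources** are evaluated at the start-of-step state (positivity-limited
   so no pool is overdrawn), giving also the net source *volume* per cell.
2. **Wall motion and mixture velocity**: interface volume fluxes are
   telescoped from the closed esophageal end so that every cell satisfies
   the discrete volume balance V^{n+1} = V^n + Δt(F_in − F_out) + Q exactly.
   Volume fractions therefore sum to one without renormalization.
3. **Advection**: first-order upwind for all phases and components, with the
   per-class slip added as a drift flux whose volume-mean is removed.
4. **Local sources** are applied; the stiff neutralization is integrated
   with the exact closed-form solution of the bimolecular rate law (explicit
   stepping would need sub-millisecond steps).
5. **Dispersion and diffusion** (below), then clipping of round-off
   negatives with a ledger; a run accumulating more than 10⁻⁶ kg of clipped
   mass aborts as invalid.

**Compartment accommodation.** A closed compartment cannot follow prescribed
wall motion exactly in 1D (incompressible content, no radial degree of
freedom).  Each compartment (stomach, duodenum) therefore carries a uniform
*stretch* factor multiplying its prescribed cell volumes.  While the gate is
shut the gastric stretch absorbs the wave's displaced volume (receptive
relaxation); while the compartment can drain, the stretch relaxes toward 1
with time constant τ = 8 s, discharging the stored volume as a smooth
antral-pump stroke of a few mL per cycle — chosen a priori to put liquid
gastric emptying in the physiological range of a few mL/min.  Relaxation is
one-sided: a compartment that has emptied (stretch < 1) is not re-inflated
by suction.

**Boundaries.**  The esophageal end is a closed wall (no reflux stage is
simulated).  The bowel end is an open zero-gradient boundary carried by the
telescoped flux: outflow leaves the domain, and transient inflow (a
peristaltic wave dying at the outlet refills from the bowel side)
re-entrains material at the boundary-cell composition, with the evacuation
ledger tracking the net flux.  A strictly outflow-only outlet was tried
first and rejected: combined with a closed-ended quasi-static tube it turns
every dying duodenal wave into a ratchet that pumps the stomach dry at
several times the physiological emptying rate.

**Axial dispersion closure.**  The 3D antral flow field recirculates at
cm/s between wave crests, suspending fine particles and homogenizing
solutes across the lumen — motion with no 1D counterpart.  It is
represented by an axial dispersion coefficient D = 5·10⁻⁵ m²/s (velocity
scale ~2–3 mm/s of the resolved wave field times the ~2 cm lumen),
exchanging equal volumes between neighbouring cells down the gradients of
phase fractions and liquid-borne concentrations; the exchange is exactly
volume-neutral because fractions sum to one.  Molecular diffusion of the
dissolved components (10⁻⁹ m²/s; 5.12·10⁻¹⁰ for lead) is also carried,
solute-relative with a compensating water counter-flux; it is negligible
next to the dispersion closure but kept for completeness.

**Exactness and ledgers.**  The solver maintains a global mass ledger
(in-domain + evacuated + absorbed − secreted − clipped = initial) that
closes to ~10⁻¹³ relative over full runs; gate-crossing mass is ledgered
per phase and component, which is how gastric evacuation is measured.

### The well-mixed oracle

`BatchReactor` integrates the identical source terms in a single box.  With
glands active it is a CSTR — the secreted fluid volume displaces an equal
volume of mixed content — which is exactly what the 1D solver reduces to
under spatially uniform forcing (uniform tube, no wall motion, no gravity,
one wall region); the suite verifies cell-wise agreement to 10⁻⁶ over 100
steps.  With sources off it is a closed box used as the conservation and
stoichiometry oracle.

## Initial state and study conditions

The simulated stage starts with a chewed carrot bolus (particle volume
fractions 0.044/0.110/0.344/0.088/0.014 by size class, 0.4 liquid) occupying
6.17·10⁻⁵ m³ of the gastric bulge — the volume whose particle load matches
the reference initial masses (3.85·10⁻² kg total at 1040 kg/m³) — with the
boundary cell partially occupied so the bolus volume is exact.  All liquid
starts as pure water (Y₉ = 1): deliberately non-physiological, chosen to
expose how fast the secretory fields establish themselves.  Six scenarios
are predefined: baseline; acid secretion functionality 0.5 and 0.2
(atrophic gastritis of increasing severity); alkaline secretion
functionality 0.5 and 0.2 (duodenal ulcer / pancreatic insufficiency); and
baseline functionality with 1005 kg/m³ particles.

## Problem sizes

Default production runs use Δx = 2 mm (136 cells) and the 20 ms base step.
The scenario comparisons are evaluated at t = 306 s and the evacuation claim
at t = 900 s; a 306 s run takes ~40 s and the 900 s run ~2.5 min on one
core.  The conservation checks run the closed box for 10⁴ steps and the full
1D configuration for 60 s at production resolution.

## What the reduction does and does not show

The 1D model reproduces, and the suite asserts, the *qualitative* structure
of the 3D results: the ordering of dissolved mass across scenarios (acid
deficit slows dissolution, alkaline deficit lowers antral pH and speeds it),
growth of the smallest particle class by cascade, acidic stomach/alkaline
duodenum in the baseline, graded stomach-pH rise with acid damage, graded
duodenal-pH fall with alkaline damage, enhanced evacuation of sub-0.7 mm
particles at reduced particle density, and evacuation of roughly a fifth of
the 0.2 mm class in 15 min while larger classes settle in the bulge.
Quantities tied to the cross-sectional flow structure — velocity fields,
recirculation patterns, the precise dissolution percentages of the 306 s
table (the 1D acid field is better mixed than its 3D counterpart, so
absolute dissolution runs several-fold faster) — are outside what a
quasi-1D reduction can reproduce and are only checked for sign and
ordering.  Known further limitations: no lateral (cross-section) settling,
no free air–liquid surface, no mucous-layer microscale, fixed blood
concentration for the absorbed chemical, no temperature dependence, and no
enteric enzyme reactions beyond pepsin proteolysis.
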