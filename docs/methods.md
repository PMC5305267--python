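# Methods

## Model

The simulator implements a mechano-chemical model of eukaryotic cell
polarization that couples three fields on a fixed two-dimensional domain:

* `u(x,y,t)` — active, membrane-bound Rac-GTP (μm⁻²),
* `v(x,y,t)` — inactive, cytosolic Rac-GDP (μm⁻²),
* `f(x,y,t)` — filamentous actin (μm⁻²),

plus a single scalar, the effective membrane tension `mt` (pN/μm).  The
local kinetics are of the wave-pinning type: Rac-GDP is converted to
Rac-GTP at rate

    b + c1·u²/(u²+K1²) + c2·f²/(f²+K2²) + k_s

(basal activation, cooperative self-activation, positive feedback from
F-actin, and the external stimulus k_s), and Rac-GTP deactivates at rate
`r`.  F-actin is nucleated at the membrane at rate
`c3·u²/(u²+K3²) · K_F/(K_F+mt)` and depolymerizes at rate `d_f`.  Tension
follows the total amount of F-actin instantaneously,

    mt(f) = mt0·(1 + λ·∫_cell f dA),

because mechanical equilibration of the membrane–cortex composite is
orders of magnitude faster than the reaction–diffusion dynamics.  Tension
is spatially homogeneous, which makes it the model's long-range inhibitor:
every patch of actin anywhere in the cell raises the polymerization
penalty everywhere.

The cell is embedded in a periodic 40 μm × 40 μm box through a phase field
`φ ∈ [0,1]` whose diffuse tanh layer of width ε represents the membrane
(`φ = ½(tanh((R−ρ)/ε)+1)` for the reference disk of radius R = 10 μm).
Membrane-localized quantities are weighted by `B(φ) = φ²(1−φ)²` or `|∇φ|`;
cytosolic quantities by `φ`.  Written for the weighted variables, the
evolution equations have conservative form; dividing by the static weights
gives the concentration-level system actually stepped:

    ∂u/∂t = D_u ∇·(B∇u)/φ̃ + φ·[(prod + k_s)·v − r·u]
    ∂v/∂t = D_v ∇·(φ∇v)/φ̃ − w_v·[(prod + k_s)·v − r·u]
    ∂f/∂t = D_f ∇·(φ∇f)/φ̃ + (|∇φ|/φ̃)·c3·H(u)·K_F/(K_F+mt) − d_f·f

with `φ̃ = max(φ, δ)`.  Two structural choices deserve comment:

1. **Capacity vs. mobility of Rac-GTP.**  The B(φ)-weighting of the
   u-equation cancels against its own reaction terms at concentration
   level, so the Rac-GTP kinetics act throughout the cell support, while
   its *transport* mobility remains the interface weight B(φ) (normalized
   to one at the interface midline).  Rac-GTP is therefore stored
   cell-wide but moves only along the membrane.  This is the reading under
   which the model's two printed steady-state numbers (a maximum
   concentration of ~0.52 μm⁻² together with a total Rac-GTP amount of
   ~92.5 over a 314 μm² cell) are mutually consistent: the polarized state
   fills a finite fraction of the interior, not just a ring.

2. **Mass-conserving conversion.**  The conversion term enters the
   v-equation with the same capacity measure φ as the u-equation
   (`w_v = φ`), so total Rac `∫φ(u+v) dA` is conserved exactly by the
   reactions.  The as-printed interface weighting `|∇φ|/φ` is retained as
   the option `conversion_measure="interface"`; it creates a mass defect
   of order 10% per polarization transient, destroying the wave-pinning
   mass budget that the conserved system relies on.  The membrane coupling
   weight used for f-production (and for v-conversion in the "interface"
   option) is Tikhonov-regularized, `|∇φ|·φ/(φ²+δ²)`, so it matches
   `|∇φ|/φ` on the interior side of the interface but vanishes with φ
   outside the cell; without this the exterior tail of the interface layer
   slowly drains the cytosolic pool.

### How polarization works here

From the standard initial state (u = 2, v = 6, f = 0 μm⁻², noise optional)
the cell relaxes to a rest state u_L ≈ 0.077 μm⁻² with the Rac pool almost
entirely cytosolic (v_rest ≈ 7.9 μm⁻²; conversion conserves the pool, and
F-actin production is too slow to trap the transient).  A sufficiently
strong and long stimulus holds a membrane region active long enough for
F-actin to accumulate past the knee of the bistable kinetics; the front
then persists after stimulus removal.  The front's growth is arrested by
the two global inhibitors acting together: depletion of the cytosolic pool
and, dominantly, the rising membrane tension, which throttles F-actin
production through K_F/(K_F+mt) until the front-edge kinetics reach their
Maxwell balance (at mt* ≈ mt0 + 1.7 pN/μm for the default kinetics).  The
pinned mass is therefore F* = (mt*/mt0 − 1)/λ: cells with higher basal
tension pin smaller, sharper fronts (with a somewhat lower peak — the
tension penalty on actin outweighs the less-depleted pool), need stronger
stimuli to polarize, and above mt0 ≈ 0.7 pN/μm cannot stably polarize at
all under this calibration.

## Parameter calibration

The model's kinetic constants are not uniquely fixed by theory; the
defaults were calibrated once, before the experiment suite was frozen,
against the model's printed anchor behaviors: the initial concentrations
u0 = 2, v0 = 6, f0 = 0 μm⁻²; bistable well-mixed kinetics with a high
stable level u_H = 0.5210 μm⁻² at the polarized operating point
(background pool v* = 7.707 μm⁻², operating tension mt0 + 1.05 pN/μm);
a low level u_L ≈ 0.07; a Maxwell-balanced (pinned) front at that
operating point; a resting state that survives ±30% initial-condition
changes; and aspiration/recovery timescales of order 50–150 s.  The
defaults (`ModelParams`):

| group | values | notes |
|---|---|---|
| diffusion | D_u = 0.1, D_f = 0.25, D_v = 50 μm²/s | D_u < D_f ≪ D_v; √(D_f/d_f) = 5 μm sets the F-actin layer depth |
| Rac cycle | b = 0.007, r = 1.0 s⁻¹ | |
| Hill terms | c1 = 0.07, K1 = 0.4; c2 = 0.042, K2 = 1.2; c3 = 0.125, K3 = 0.4 | K-values in μm⁻² |
| actin | d_f = 0.01 s⁻¹ | slow turnover: sets collapse/recovery times |
| tension | mt0 = 0.2 pN/μm, λ = 0.046, K_F = 2 pN/μm | λ sets the pinned front mass |
| geometry | R = 10, ε = 1, L = 40 μm | |
| numerics | N = 128, dt = 0.01 s (reference); N = 96, dt = 0.02 s (desk scale) | |

A useful reduced description used throughout (`f_membrane_level`): the
F-actin concentration felt by the membrane kinetics is the one-sided
surface-source balance `f_mem = c3·H(u)·K_F/(K_F+mt) / √(D_f·d_f)`.  The
well-mixed fixed points computed with this closure at the operating point
(v*, mt0+1.05) reproduce the simulated polarized maximum to a few percent
and define the separatrix midpoint `(u_L+u_H)/2 ≈ 0.30` used as the
polarization criterion everywhere.

## Experiments and their operational definitions

* **Polarization / thresholds.**  Graded stimulus `k_s = amp·(R+ξ)` on the
  cell support for a duration; the cell is polarized when the membrane
  maximum of u exceeds the separatrix midpoint and holds it to the end of
  the run.  Threshold searches start from the rested state (the standard
  initial condition is critically poised and its threshold degenerates to
  zero) and bisect geometrically to 2% by default; at basal tension the
  thresholds are small in absolute terms (amp ~1e-3 at 25 s duration)
  because the slow actin integrator accumulates weak sustained biases.
  Steady-state readouts (maximum and total Rac-GTP) are taken at t ≈
  450–600 s after stimulus onset; the pinned state retains a slow residual
  drift (<2%/100 s), so the readout time is part of the protocol.
* **Stability (n_p/n_s).**  The cell is polarized toward 0°, then a
  schedule of graded events with direction uniform on {0°, 90°, 180°,
  270°}, amplitude U(0.0025, 0.014), duration U(10, 40) s and 75 s
  recovery gaps is applied.  n_s counts events whose direction differs
  from the previous one; an event redirects (n_p) when the post-event
  polarity angle lies within 45° of the event direction and the pre-event
  angle did not.  The event distributions were calibrated once so that
  both tension conditions redirect on a majority of events; the
  high-tension condition is mt0 = 0.4 pN/μm (the printed high-tension
  value for this assay is not stated; 2× basal is the strongest tension at
  which de-novo polarization from rest remains robust here).  Desk-scale
  ensembles: 8 seeds × 8 events (acceptance script), 96×96 grid, dt 0.02 s,
  one shared warm-up per condition.
* **Aspiration–release.**  At t = 400 s the tension is overridden to
  10× its F-actin-determined value; at t = 460 s the relationship is
  restored.  A sustained sub-threshold local-random stimulus (amplitude
  0.002, redrawn every 20 s) runs throughout and reseeds the front after
  release.  Collapse time = first crossing of the separatrix midpoint
  after aspiration; recovery time = first return to 95% of the
  pre-aspiration maximum after release.
* **Severing.**  The tethered shape is two disks (body radius 6 μm,
  pseudopod radius 3.5 μm) joined by a 10 μm × 2 μm neck.  The assay
  starts from the constructed steady morphology: pseudopod at u_H with its
  F-actin load scaled so tension starts at the stall value, body at rest.
  Sub-threshold noise acts on the body side throughout.  The cut
  (tanh-smoothed half-space masks at the neck midpoint) is applied 60 s
  in — the neck conducts the membrane front into the body on a ~100 s
  timescale, a known limitation of this formulation, so the tethered
  morphology is metastable rather than steady.  With tension release the
  severed body recomputes mt from its own F-actin (≈ mt0) and the noise
  polarizes it; without release it keeps the pre-cut tension and the body
  stays on the resting branch.  The polarity call for the body requires
  the body disk proper (excluding the residual neck stub) to reach
  (1−0.1)·u_H.
* **Sensitivity.**  One-at-a-time ±30% perturbations; the reported number
  is the larger relative change of the steady polarized maximum over the
  two signs, at matched readout time.
* **Dual-stimulus competition.**  Two opposite polar-cap stimuli (each
  `amp·(R+ξ)` restricted to ξ > R/4) applied to a rested cell; fronts are
  counted as connected high arcs of the angularly-binned membrane ring.
* **Traditional model.**  The overlap (projection) formulation integrates
  the same kinetics on a hard disk mask with zero-flux edges, with the
  tension factor replaced by the Brownian-ratchet law exp(−mt·δ/(n·kBT))
  (δ = 2.7 nm, kBT = 4.14·10⁻³ pN·μm, n = 3 load-bearing filaments per μm
  of edge — n lumps the sharing of tension load and was chosen so the
  factor spans a comparable range to K_F/(K_F+mt) over the operating
  tensions).  Its cytosolic pool is integrated in the fast-diffusion
  (well-mixed) limit — exact for D_v/r ≫ R² — because D_v is far beyond
  the explicit-stepping stability limit.  Its F-actin production constant
  (c3 = 0.03) differs from the phase-field value because production is
  areal rather than interface-localized.

## Numerics

Semi-implicit Fourier-spectral stepping: the full explicit right-hand side
(conservative centered-difference fluxes for the variable-coefficient
diffusion, explicit reactions) is filtered by (1 + dt·σD k²)⁻¹ in Fourier
space, equivalent to treating σD∇² implicitly with an add–subtract
splitting; σ = 2 bounds the mobility ratio of the splitting and makes the
linear part unconditionally stable.  In the constant-coefficient limit
(uniform weights) the stepper switches to the exact exponential
propagator, so pure diffusion decays at exp(−Dk²t) to machine precision
per mode.  Negative concentrations produced by the explicit reaction step
are clipped to zero and counted.  Determinism: all randomness flows from
explicit integer seeds through `numpy.random.default_rng`.

Problem sizes: reference runs use N = 128, dt = 0.01 s (~2 ms/step); the
experiment suite and acceptance script use the desk-scale configuration
N = 96, dt = 0.02 s, which reproduces the N = 128 steady levels to ~1% and
keeps the full suite within minutes.  dt self-convergence is first order,
as expected for the splitting.

## What the synthetic conditions do and do not show

All inputs are generated in silico: stimulus protocols per the model's
stimulus equations, Gaussian initial-condition noise (variance 0.01),
switching schedules from seeded RNGs.  The simulations probe the model's
internal consistency — thresholds, pinning, tension-mediated stability —
not biological measurement noise, receptor-level transduction, cell-shape
change, or population heterogeneity of real cells.  Passing tests show
that the mechano-chemical mechanism behaves as described under the
documented calibration; they do not validate the model against wet-lab
polarization fractions or deformation data, which are outside this
package's scope.

## Known limitations and deviations

Measured on the default calibration (they are asserted honestly by the
acceptance tests, which go red where the printed value is not met):

* The polarized steady maximum lands ~6% below 0.5210 μm⁻² and the total
  Rac-GTP ~7% below 92.5253 at desk scale (both within the 10% band used
  by the tests).
* De-novo polarization is impossible above mt0 ≈ 0.7 pN/μm: the tension
  needed to pin a front at low mt0 makes the multiplicative feedback
  prohibitive at mt0 = 1.0.  The 0.2 → 1.0 threshold-product ratio is
  therefore unbounded rather than ≈1.8 (the corresponding acceptance test
  is expected red); thresholds are finite and monotone over mt0 ≤ 0.6.
* The pinned state drifts slowly (the stall is a soft balance): polarity
  angle is stable for ~600 s in a quiescent cell, after which the high arc
  can close into a ring.  Experiments are scored within that window.
* The tethered morphology is metastable (neck conduction, above).
* In a mass-conserving formulation the background pool of a polarized
  cell is v* ≈ 7.7 μm⁻², not v0 = 6; the printed anchor "u_H at v = v0" is
  kept as a closure at the operating point rather than at v0.
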