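# Methods

## The model and its assumptions

`ffrwire` replaces the three-dimensional Navier–Stokes problem of blood flow
through a stenotic, guidewire-bearing coronary artery with a quasi-steady
nonlinear resistance network. The approximations, in decreasing order of
consequence:

* **Quasi-steady flow.** Each time sample of the inlet pressure waveform is
  an independent algebraic solve; fluid inertia (Womersley effects) and wall
  compliance are neglected. The diagnostics of interest — FFR, CDP — are
  built from cycle-averaged pressures, for which a resistive network is the
  standard 0D frame; the clinical pressure-to-flow derivation itself assumes
  exactly this proportionality.
* **Piecewise-Poiseuille trunk.** The trunk is discretized at its geometry
  stations (2-mm spacing, refined to stenosis_length/40 inside the lesion);
  each segment contributes fully developed laminar resistance for its local
  section — circular tube, or concentric annulus where the wire is present,
  using the exact closed form
  `R = 8μl / (π[R⁴ − r⁴ − (R²−r²)²/ln(R/r)])`. Entrance lengths and flow
  development are ignored.
* **Single-scalar rheology closure.** The Carreau viscosity is evaluated per
  segment at the Poiseuille wall shear rate `32|Q|/(πd_h³)` of that
  segment's flow section. This collapses the radial viscosity profile to one
  value per segment — consistent with a 0D/1D model, and accurate at
  coronary shear rates where the law is near its infinite-shear plateau.
* **Lumped lesion loss.** Irreversible expansion loss downstream of the
  throat is modeled Borda–Carnot: `K_t·(ρ/2)·Q|Q|·(1/A_t − 1/A_u)²`,
  `K_t = 1` by default. This is the dominant nonlinearity; it is what makes
  the pressure-derived FFR deviate from the true flow ratio. The quadratic
  term uses `Q|Q|`, keeping the pressure-drop map strictly monotone under
  backflow.
* **Rigid walls, concentric wire, no collaterals.** The wire sits on the
  centerline (eccentric annuli excluded); side-branch supply distal to the
  lesion is neglected, so severe-case flow ratios are lower bounds.

Because the network model shares its analytic frame with the clinical
derivation (series resistances, zero venous gauge pressure), the calibrated
pressure estimate `C·P_d/P_a` equals `Q_S/Q_H` *exactly* in the linear
(Newtonian, no expansion loss) regime — the test suite asserts this to
machine precision — and any discrepancy in the full model is attributable to
the quadratic loss and shear-thinning, i.e. to physics the clinical formula
ignores.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| μ₀, μ∞, λ, n | 0.055, 0.00339, 9.56, 0.2 | Pa·s, Pa·s, s, – | standard Carreau fit for human whole blood |
| ρ | 1050 | kg/m³ | whole-blood density |
| trunk diameter | 3.0 | mm | reference healthy RCA lumen implied by the 1.8/1.2/0.45-mm throats being 40/60/85% reductions |
| trunk length | 84 (−60…+24) | mm | inlet-to-bifurcation span with x = 0 at the first wire-tip station |
| stenosis length | 4 | mm | short lesion with sharp convergence/divergence |
| throat center | 10.05 | mm | midway between the two "at the throat" wire stations (9.4, 10.7 mm) |
| wire diameter | 0.35 | mm | the least flow-disturbing clinical wire size |
| wire schedule | 0, 5.3, 8, 9.4, 10.7, 13.5, 24 | mm | stepped insertion tip positions |
| mean inlet pressure | 85.89 | mmHg | cycle-mean aortic drive of the study conditions |
| cardiac period | 0.8 | s | typical resting cycle (not otherwise constrained) |
| systolic fraction | 0.35 | – | typical systole/cycle ratio |
| pulse amplitude | 40 | mmHg | typical aortic pulse pressure |
| branch split target | 63.2% | – | measured healthy main-branch share |
| K_t | 1.0 | – | Borda–Carnot sudden-expansion coefficient |
| time grid | 200 steps/cycle | – | cycle averages converged well below diagnostic precision |

Only the cycle-mean inlet pressure is externally constrained; period,
systolic fraction and pulse amplitude are declared assumptions echoed into
every report's metadata block.

**Branch sizing.** The two daughter tubes are sized at build time: total
healthy resistance is set by a design healthy flow of 10 mL/s at the mean
inlet pressure (placing the proximal velocity near 1.4 m/s, consistent with
the reference inlet velocities of ~1.15 m/s once a mild lesion removes
~17–21% of the flow), and the parallel pair is partitioned to the split
target. Daughter diameters follow Murray's law (d ∝ flow fraction^(1/3)),
which equalizes wall shear across the branches; the split is then invariant
to the rheology, and the healthy run recovers 63.2/36.8 exactly rather than
only in the Newtonian limit.

## What the synthetic fixtures do and do not emulate

The generator reproduces the *conditions* of the reference study — three
severities on a common trunk, the seven-position wire schedule, a pulsatile
inlet with the stated cycle mean, zero-gauge outlets — on an idealized
straight circular vessel. It does **not** reproduce: the real RCA's
non-circular cross-sections (the study's 11.12-mm² trunk area vs 7.07 mm²
circular here), curvature and tortuosity, 3-D recirculation and pressure
non-uniformity over a cross-section, or elastic walls. Consequently,
passing tests demonstrate the *direction and ordering* of the guidewire
distortion (wire ⇒ less flow, lower FFR, higher CDP; effect severe ≫
moderate > mild) and the internal consistency of the diagnostic formulas —
not the 3-D per-station pressure magnitudes, which a lumped model cannot
and does not claim to match. The pressure-derived FFR here has no Bernoulli
recovery, so station pressures decrease monotonically downstream.

## Numerical choices

* **Root solve.** Per time step, Brent's method on Q over a guaranteed
  bracket `[0, 10·p/R_floor]`, with `R_floor` the network resistance at the
  infinite-shear viscosity (a strict lower bound on Δp/Q). Tolerances are at
  machine precision (rtol = 4·eps), so closed-form oracle comparisons hold
  to 1e-10 and better.
* **Branch split.** Fixed-point iteration on the branch viscosities
  (tolerance 1e-14 relative, cap 100); mass conservation at the bifurcation
  is exact by construction.
* **Carreau overflow guard.** For λγ̇ > 1e6 the bracket
  `[1+(λγ̇)²]^((n−1)/2)` is evaluated in log form; the branch join is
  continuous to ~1e-13 relative.
* **Degenerate inputs.** A wire at least as wide as the local lumen yields a
  flagged zero-flow solution (pressures: inlet value up to the blockage,
  zero beyond), not an error; zero-diameter wires reproduce the wire-free
  case identically; `inner_radius = 0` in the annulus formula returns the
  tube value exactly (the logarithmic term is otherwise singular — note the
  physical convergence of annulus to tube resistance as r → 0 is only
  logarithmic, ~12% high at r/R = 1e-4).
* **Averaging.** Trapezoid rule over exactly one period, endpoint included;
  the synthetic waveform's mean is shifted to the target exactly, so the
  mean inlet pressure is reproduced to round-off at any sampling.

## Measurement conventions

* Distal pressure station: first station downstream of the lesion window
  (13.5 mm for the default fixtures), before the bifurcation; wire cases
  read pressure at the tip station, and C is calibrated at the same station
  from the healthy run so estimate and truth are commensurate.
* During-insertion aggregates: P_d and Δp from the most distal tip reading;
  the CDP velocity is the across-position mean proximal velocity (early,
  less obstructive positions raise it above the full-position value).
* CDP is strict SI. Reported CDP *errors/ratios* are unit-convention
  invariant and are the quantities compared against the bundled reference
  cells.
* mmHg appears only at I/O boundaries (1 mmHg = 133.322 Pa).

## Known limitations

Severe-case absolute flows depend strongly on the 0.05-mm annular gap and
the lumped expansion loss, so they are qualitative (the model gives
~98.8% flow reduction with the wire vs the reference 95.57%). The Reynolds
guard warns above Re = 2000 but does not switch models; transitional
effects in the throat jet are outside scope. No hyperemia pharmacology is
modeled — distal resistances are simply held constant, which is the
assumption FFR itself requires.
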