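# ffrwire

A reduced-order, pulsatile hemodynamics model for studying how the pressure
guidewire used in invasive **fractional flow reserve (FFR)** measurement
distorts the very quantity it measures.

FFR is the gold-standard index of coronary stenosis severity: the ratio of
maximal blood flow through the stenosed artery to the flow the same artery
would carry if healthy, `FFR = Q_S / Q_H`, estimated clinically from the
distal-to-aortic mean pressure ratio. Measuring it requires advancing a
0.35-mm sensor-tipped wire through the lesion — and in a tight stenosis the
wire itself converts the throat into a narrow annular channel, reducing flow
and biasing the measurement toward *overestimating* severity. `ffrwire`
models this feedback with a quasi-steady nonlinear resistance network and
quantifies the error for mild (40%), moderate (60%) and severe (85%)
hydraulic-diameter reductions.

## Model

The idealized right coronary artery is a 3.0-mm circular trunk from the
inlet (x = −60 mm) to a bifurcation (x = +24 mm) into two lumped daughter
tubes, with a raised-cosine constriction whose throat realizes the target
severity (throat hydraulic diameters 1.8 / 1.2 / 0.45 mm). At each sample of
the pulsatile aortic inlet waveform (cycle mean 85.89 mmHg; outlets at zero
gauge) the trunk flow Q solves

```
p_in(t) = Σ_segments Δp_seg(Q) + Δp_branches(Q),
Δp_seg  = R(μ)·Q          (Poiseuille tube, or concentric-annulus closed
                           form where the wire is present)
Δp_lesion += K_t·(ρ/2)·Q|Q|·(1/A_throat − 1/A_upstream)²   (Borda–Carnot)
```

with blood viscosity from the Carreau law
`μ = μ∞ + (μ₀ − μ∞)[1 + (λγ̇)²]^((n−1)/2)`
(μ₀ = 0.055 Pa·s, μ∞ = 0.00339 Pa·s, λ = 9.56 s, n = 0.2, ρ = 1050 kg/m³)
evaluated at each segment's wall shear rate `γ̇ = 32|Q|/(πd³)`.

Diagnostics follow the clinical bookkeeping on cycle averages
(`P_mean = ∫₀ᵀ P dt / T`):

* `FFR_flow = Q_S/Q_H` — the actual flow ratio;
* `FFR_pressure = C·P_d/P_a` with `C = P_a/P_d'` calibrated on the healthy
  artery (an identity in the linear regime, an approximation otherwise);
* `CDP = Δp̄/(0.5 ρ ū_e²)` — trans-stenotic drop over proximal dynamic
  pressure (strict SI);
* flow-reduction and percent-error metrics comparing wire-free,
  full-position-wire and stepped during-insertion configurations.

## Worked example

```sh
$ ffrwire report --scenario moderate --out-dir results
            case  pa_mmHg   pd_mmHg   dp_mmHg  u_inlet_ms       cdp  cdp_error_pct      ffr  ffr_error_pct
         without    85.89 33.775463 52.114537    0.643392 31.970518            NaN 0.443339            NaN
during_insertion    85.89 29.119197 56.770803    0.609793 38.770606      21.269869 0.389306      11.916234
   full_position    85.89 29.119197 56.770803    0.572368 44.006430      37.646909 0.389306      11.916234
C = 1.1274; outputs in results
```

Reading the rows: without the wire the moderate (60%) lesion passes 44.2% of
the healthy flow (`FFR_flow = 0.443`; the reference CFD study reports 0.44).
Inserting the 0.35-mm wire drops the distal mean pressure from 33.8 to
29.1 mmHg and the estimated FFR to 0.389 — an 11.9% overestimation of
severity — while the CDP rises from 32.0 to 38.8 (during insertion) and 44.0
(wire fixed at full position), because the wire also lowers the proximal
velocity entering the denominator. `ffr_error_pct` is measured against the
wire-free actual flow ratio, `cdp_error_pct` against the wire-free CDP.

`ffrwire verify` recomputes every derived cell of the bundled
reference-table readings (error percentages, flow-ratio identities, the
composed severe-case reduction, the throat area→diameter identity) from
their printed inputs and confirms each matches at its printed precision.

Other entry points: `ffrwire generate` (geometry JSON + waveform CSV
fixtures), `ffrwire simulate`, `ffrwire sweep --schedule 0,5.3,8,9.4,10.7,13.5,24`.

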