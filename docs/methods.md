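# Methods

## Model

The dissected aortic segment is a zero-dimensional electrical analogue.
Each lumen (true lumen TL, false lumen FL) is an L-type RLC compartment:
Poiseuille resistance `R = 8μl/(πr⁴)`, inertance `L = ρl/(πr²)` and
thin-wall elastic compliance `C = 3πr³l/(2Eh)`, computed in SI from the
phantom geometry (TL: r = 8 mm, h = 2 mm; FL: r = 16.15 mm, h = 1 mm;
l = 160 mm; water at 25 °C, μ = 8.9·10⁻⁴ Pa·s, ρ = 997.0479 kg/m³) and
converted to clinical units (mmHg, ml, s; 1 mmHg = 133.322 Pa), in which
the simulator operates.  Tears are pure resistances whose values are
fitted constants, not orifice-formula outputs: 2.2200 mmHg·s/ml for a
4 mm tear, 0.1434 for 10 mm.  The peripheral bed is a pure resistance
draining to a fixed outlet pressure (default 0 mmHg, venous reference).

Four states carry derivatives — proximal TL pressure, TL outflow,
proximal FL pressure, FL axial flow — with the tear and junction signals
closed algebraically by Ohm's law and Kirchhoff's junction rule
(`Q_TLi = Q_i − Q_PT`, `Q_PH = Q_TLo + Q_FL`).  An absent tear is removed
structurally: its branch flow is identically zero and, for an absent
distal tear, the FL axial equation is dropped (the FL becomes a dead-end
side chamber; a one-tear circuit carries zero mean tear flow).  Zero
compliance is never placed inside the ODE; rigid walls are approached
through a finite elasticity multiplier (up to 10⁷).

The scenario catalogue carries a fitted TL compliance of
0.0016 ml/mmHg common to all scenarios and a per-scenario FL compliance
(0.1011–0.2813 ml/mmHg) with the corresponding FL wall moduli
(1.51–4.19 MPa), which are mutually consistent with the thin-wall formula
to within 0.5%.  The recorded TL modulus (1.07 MPa) is *not* consistent
with the fitted TL compliance under the same formula (it implies
≈ 0.026 ml/mmHg); the fitted compliance is treated as the operative value
and the modulus as descriptive metadata only.

## Integration and periodic steady state

The circuit is linear and time-invariant, `dx/dt = A x + b(t)`, forced by
a band-limited periodic inflow.  The default integrator is exact rather
than step-adaptive: the periodic particular solution is assembled per
inflow harmonic from `x_k = (iω_k I − A)⁻¹ g c_k` (the `c_k` being the
trigonometric-interpolant coefficients of the inflow samples), and the
decaying transient is advanced with `expm(A·h)` on the fixed 0.01 s
output grid.  The motivation is the near-rigid regime: at elasticity
factors ≥ 10⁵ the L–C pairs of the lumina become weakly damped
oscillators at 10⁵–10⁶ rad/s, and conventional variable-step stiff
solvers (LSODA/BDF/Radau) spend minutes per run resolving oscillations
that are irrelevant to the periodic response; the exact propagator costs
the same at every stiffness.  LSODA remains available through
`SolverSettings(method="LSODA")` and is used in the test suite as an
independent cross-check at factor 1 (agreement to the solver's own
tolerance, ~10⁻⁵ relative).

Whatever the integrator, the solver is iterated cycle by cycle from a
zero (or supplied) initial state.  Periodic steady state is declared when
the largest absolute change of any state series between consecutive
cycles falls below `10⁻⁶ × (peak-to-peak P_TL)`, floored at `10 × atol`;
a run exhausting `max_cycles` (default 100) is returned flagged
non-converged, never silently.  Typical runs converge in 3–15 cycles.

## Synthetic inflow (what it emulates, what it does not)

The experimental inflow driving the original bench circuit is not part of
any public record, so the generator synthesises a stand-in: a half-sine
ejection lobe over the systolic fraction of the cycle riding on a
constant baseline flow.  Defaults, chosen once as a realistic resting
condition for a descending aorta: period 1.0 s (this puts the tear
Womersley numbers near 5 for 4 mm and 13 for 10 mm tears), peak
250 ml/s, systolic fraction 0.35, baseline 10 ml/s (the pump never stops
flowing, so diastolic pressures stay well-defined), giving a mean of
65.7 ml/s ≈ 3.9 l/min.  The peripheral resistance is sized as (target
mean pressure − outlet pressure)/mean inflow with a 100 mmHg default
target.

The shape is realised as a truncated Fourier series with closed-form
harmonic coefficients and a Lanczos σ-taper.  This makes the waveform
smooth and exactly periodic and keeps the cycle mean *exactly* at its
closed form `(2/π)·peak·fraction + baseline` (the DC coefficient is
untouched by the taper).  The default truncation is 12 harmonics,
reflecting that pulsatile aortic signal power concentrates in the first
~10 harmonics; sharper waveforms are available via `n_harmonics`.

Not emulated: the retrograde (negative) end-systolic phase of real
aortic flow, beat-to-beat variability, and measurement artefacts other
than additive Gaussian pressure noise in the fixture generator.  Two
consequences matter for interpreting the trend tests.  First, with a
non-negative imposed inflow the TL inlet flow `Q_TLi = Q_i − Q_PT` never
reverses at low wall stiffness: the FL charging current is bounded by the
pulsatile part of the inflow and is in quadrature with it, so reversal of
the *lumen inlet* flow requires an inflow that itself reverses.  The
side-chamber transition is still fully expressed — the *tear* flow
reverses within each cycle at low stiffness (the FL fills and empties
through the same tear, ID ≈ 1) and becomes one-way in the rigid limit
(ID → 0).  Second, in the rigid limit the diastolic pressure minimum sits
on the end-systolic deceleration notch, where inertial redistribution
between the TL and FL branches (branch time constant ≈ 26 ms for large
tears) leaves the two lumina's minima a few mmHg apart while the minima
themselves are small (P_o = 0, resistive outlet); the diastolic FL/TL
pressure ratio for the large-tear scenario therefore saturates near 114%
rather than 100%.  Both are properties of the study conditions, not of
the circuit implementation, and both are documented red in the acceptance
suite.

## Calibration

The two-stage protocol mirrors the bench situation: the TL tube and tear
pieces are shared across phantoms, the FL piece is custom per scenario.
Stage 1 fits, simultaneously on the two distal-single-tear scenarios
(S_0,4 and S_0,10), the shared TL compliance and the small/large tear
resistances together with each scenario's FL compliance (five
parameters).  Stage 2 freezes the shared values and fits only the FL
compliance of each remaining scenario (one parameter).

The objective is the sum over the available pressure observables (a site
is observable only where its tear exists) of the raw RMSE between
predicted and measured waveforms; rRMSE — 100 × RMSE normalised by the
measured peak-to-peak — is computed for reporting only.  The search runs
in log-space (positivity by construction; the parameters span four
decades).  Start points come from a deterministic coarse log-grid scan
(three points per decade over 10⁻⁴–1 ml/mmHg for compliances and
0.05–10 mmHg·s/ml for resistances, one cyclic coordinate-descent pass
from thin-wall geometric guesses), followed by three Nelder–Mead starts
(the scan optimum and ±⅓ decade on all coordinates); each start is
restarted up to four times from its own endpoint, which escapes the
collapsed simplices that the strongly correlated (C_FL, R_tear) valley
produces; the best objective wins, ties broken by start order.
Convergence tolerances are 10⁻⁶ on parameters and objective.  Candidate
simulations warm-start from the DC operating point of the mean inflow and
use slightly relaxed tolerances; failed or non-finite candidates receive
a finite 10⁶ penalty.  On noise-free fixtures the protocol recovers all
five stage-1 parameters to ≤ 0.7% (most to < 10⁻³ %) and the stage-2
compliance to < 10⁻⁴ %; with 1 mmHg Gaussian pressure noise the FL
compliances stay within ~0.3%.

## Indices — numerical choices

* SP/DP are discrete extrema on the 0.01 s output grid, no sub-sample
  interpolation; PP = SP − DP.  Pressure observation mapping: proximal
  TL/FL = the two capacitor-node pressures; distal FL = upstream side of
  the distal tear; distal TL = junction pressure (the circuit's only four
  pressure nodes).
* TSF is the circular difference of the FL and TL peak times mapped to
  (−T/2, T/2], ties to the earliest sample; undefined for flat signals.
* ID uses the tear-flow convention positive TL→FL, i.e. `Q_DT = −Q_FL`,
  and aggregates over the cycle as a ratio of integrals
  `∫|Q_PT+Q_DT| / ∫(|Q_PT|+|Q_DT|)` — bounded in [0, 1] and robust at
  zero crossings (a mean of instantaneous ratios is not).  1 =
  side-chamber behaviour, 0 = parallel-vessel behaviour.
* Tear velocity divides the tear flow by the effective orifice area with
  an optional obstruction fraction (0.25 emulates the catheterised-bench
  convention; 0 is the pure model output).
* Input impedance is the ratio of DFT coefficients of one pressure and
  flow cycle, harmonics 0–10; harmonics whose flow coefficient is below
  10⁻¹² of the spectral peak are flagged undefined rather than infinite.
* The elasticity sweep scales both wall moduli by a common factor
  (compliances divide by it; R and L are unaffected) over
  {0.35, 1, 10, 10², …, 10⁷}, warm-starting each factor from the previous
  converged state.  Saturation between factors 10² and 10⁷ is measured
  relative to the rigid pulse pressure, since self-relative changes of a
  near-zero diastolic index are not meaningful.
* Monotonicity verdicts use small numerical slacks: 10⁻³ relative for
  pulse pressures, 0.01 absolute for ID (grid-sampled extrema and
  integral aggregation jitter at that scale).

## Known limitations

The model class omits wave travel and reflection, flap motion,
flow-dependent (nonlinear) tear resistance, and any local flow phenomena
(jets, turbulence, wall shear stress); tear resistances are fitted
constants, so the model cannot predict the haemodynamic effect of a tear
size it was not calibrated for.  The peripheral bed is a single
resistance with a fixed outlet pressure.  Passing tests demonstrate
internal consistency, oracle agreement and parameter recoverability under
the synthetic study conditions above — not agreement with any particular
patient's or bench's waveforms.
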