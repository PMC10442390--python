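# Methods

## The gating model

`navleak` represents a Nav channel population as a continuous-time Markov
chain over eight states arranged on a 2×4 grid:

| | activation gate closed | activation gate open |
|---|---|---|
| DIV VSD down | ① last closed state | ② open |
| DIV VSD up | ③ closed, pocket exposed | ④ open, pocket exposed |
| IFM bound | ⑤ closed | ⑥ open |
| S6 gate shut | ⑦ closed-inactivated | ⑧ open-inactivated |

Horizontal steps lump the multi-step activation of DI–DIII into one
voltage-dependent transition; ①→③/②→④ is the DIV voltage-sensor movement
that exposes the IFM binding pocket; IFM binding (③→⑤/④→⑥) and the final
closure of the two-tier S6 gate (⑤→⑦/⑥→⑧) are voltage independent. The
DIII VSD is lumped into the activation step — the same simplification the
scheme itself makes. In the wild type ⑦/⑧ are non-conducting; in the S6
double/quadruple alanine variants they keep a scaled permeability with a
reduced Na⁺:K⁺ ratio (the leaky inactivated state).

Rates follow a single-barrier Eyring form,
`k_fwd = k₀f·exp(z δ F V/RT)`, `k_bwd = k₀b·exp(−z(1−δ) F V/RT)` with
δ = 0.5 throughout. Model construction enforces microscopic reversibility:
around every cycle the product of equilibrium constants at 0 mV must be 1 and
the net rate-law charge and gating charge must vanish (checked to 1e−9;
violating overrides are rejected with the offending cycle). Because charges
are cycle-consistent, a per-state charge coordinate exists and is used for
exact on/off charge bookkeeping.

## Calibration of the shipped parameterizations

The experimental record pins equilibria and a handful of time constants, not
individual rate constants; every shipped rate is therefore a calibration
artifact chosen once so that the full simulate→analyze loop reproduces the
study's summary statistics, and frozen:

- activation: z = 2.5, K₀ = 12.8 (half-activation ≈ −25 mV), forward
  0.75 ms⁻¹ — sets the ~0.3 ms open-state deactivation at −80 mV and
  sub-0.1 ms activation at +60 mV;
- DIV VSD: z = 3.0, K₀ = 31.2, forward 2.0 ms⁻¹ — fast sensor movement and,
  with the IFM/closure equilibria, a WT availability midpoint near −45 mV;
- IFM binding 0.7 ms⁻¹ (the ~1.5 ms fast-inactivation time constant at
  +60 mV), unbinding 14 ms⁻¹;
- S6 closure: strongly committed in the open column (K = 1250) — this makes
  WT inactivation essentially complete (steady/peak ≈ 2% at +60 mV) — and
  weak in the closed column (K = 25), which sets the recovery route; cycle
  closure then fixes the inactivated-row activation equilibrium (K₀ = 640)
  whose rate scale (k₀b = 0.055) gives the leaky state's ~0.8 ms shut-off
  at −80 mV;
- gating charge: 3.0 e₀ on the DIV step (immobilizable), 2.0 e₀ on
  activation, total 5 e₀ — realizing the ~60% immobilization plateau
  structurally;
- leak permeabilities (relative to open-state Na⁺): DIIIAA 0.158
  (P_Na/P_K 4.3), DIVAA 0.093 (ratio 2), DIII_IVAA 0.30 (ratio 1.5), with
  the closed-inactivated state ⑦ conducting at 3% of ⑧. The open-state
  selectivity is 11 for WT-like variants, 13 for DIVAA and 2.7 for
  DIII_IVAA; these microscopic ratios are calibrated so that the
  *pipeline-measured* onset/steady values land on the reported 13→2 and
  2.4→1.5 courses (the measured onset mixes a growing inactivated fraction
  into the open-state value);
- mutant overrides: the S6 mutants scale the DIV backward rate ×6.6
  (equilibrium-only change producing the ~+10 mV availability shift while
  leaving the forward-dominated entry kinetics at +60 mV untouched); IQM
  variants zero the IFM-binding forward rates; DIIAA scales all opening
  rates ×0.05 (reduced VSD–PD coupling); DIA adds a small leak and a +15 mV
  activation shift;
- absolute scale: 0.0664 µA per unit GHK flux factor, putting the WT peak at
  +60 mV at 1 µA magnitude (arbitrary; oocyte expression levels are not a
  model quantity). Under the study's solutions the +60 mV current sits above
  the Na⁺ reversal (≈ +38 mV) and is therefore outward.

One deliberate consequence of the topology: with voltage-independent IFM and
closure steps, exit from the inactivated manifold is fastest at the most
hyperpolarized voltages. The leaky conductance therefore shuts at −80 mV
mainly through the ⑧→⑦ activation-gate step (whose rate scale was
calibrated to the printed tail constants) rather than through full recovery.

## Synthetic voltage-clamp stage

Protocols are ordered epochs of (duration, voltage) with one optional sweep
axis (an epoch's voltage or duration varying across sweeps) and an optional
P/N subtraction block. Command steps are low-pass filtered with the clamp
settling constant (default 75 µs); within each sample interval the membrane
voltage is treated as constant at the interval midpoint and the master
equation advanced by a cached matrix exponential (a stiff-ODE backend using
the same voltage discretization is provided and agrees to 1e−6). The initial
condition is always the stationary distribution at the holding potential.

Ionic current uses the GHK flux equation per species and state, with the
V→0 singularity handled by series expansion; gating current is the
charge-weighted net transition flux, whose exact time integral is available
as a cumulative charge trace. Acquisition emulation applies linear leak and
single-exponential capacitive transients (amplitude ∝ step size, the minimal
model P/N cancels exactly), a 4-pole Bessel filter (default 20 kHz at 100 kHz
sampling), seeded Gaussian noise (σ = 0 by default; a seed is mandatory when
σ > 0), and online P/N subtraction implemented by actually simulating the
scaled sub-sweeps from the subtraction holding and summing, followed by
pre-step baseline removal — so linear components cancel exactly in the
noiseless case while nonlinear gating charge survives when the subtraction
holding sits on the Q–V plateau.

What the generator does *not* emulate: series-resistance error, single-channel
stochasticity, slow inactivation, temperature drift, endogenous oocyte
conductances and P/N artifacts from incompletely settled sub-sweeps. Passing
tests therefore demonstrate that the analysis pipelines recover the
generative truth under idealized recording conditions, not that they are
robust to every artifact of a real rig.

## Analysis conventions and numerical choices

- Fit windows open 0.3 ms (≈4 clamp constants) after a step; the
  instantaneous I–V tail fit opens at 0.45 ms with a fitted-τ floor of 4
  clamp constants, since a fit that locks onto the residual settling edge
  back-extrapolates to the pre-step current rather than the tail response.
  Windows exclude the sample on the next epoch's boundary.
- Exponential fits: nonlinear least squares on (A, log τ) with peeling-based
  initial guesses plus three log-spaced τ multistarts; components reported in
  ascending τ, collapsed when τ's agree to 1e−3; uncertainties from the
  Jacobian covariance. Tail fits choose one versus two components by AIC.
- The weighted time constant is implemented as the amplitude-weighted *sum*
  (A₁τ₁ + A₂τ₂)/(A₁ + A₂). The product form sometimes printed for this
  quantity is dimensionally inconsistent (time²·current/current) and is
  treated as a typographical slip; the reported tail values are consistent
  with the weighted sum.
- Charge immobilization: the off-gating current is fitted (two components,
  no offset) from 3 clamp constants after the return step; the fraction is
  A_slow·τ_slow over the off-charge integral taken from the return-step
  onset plus the fitted tail beyond the window. The alternative denominator
  (sum of both fitted components) is reported alongside; points whose τ's
  separate by less than 3× are flagged, and a vanished fast component is
  treated as "no distinct slow fraction".
- h∞ curves normalize to the most hyperpolarized conditioning point (not a
  fitted maximum); the steady-state averaging window is the final 10% of the
  pulse. Conditioning epochs are long enough (≈10× the slowest local
  relaxation) that the availability matches the stationary distribution to
  within 1 mV in the fitted midpoint.
- Reversal potentials come from an ordinary least-squares line through the
  instantaneous I–V, refitted once within ±40 mV of the first-pass crossing
  to guard against GHK curvature; the bias stays below 1.5–2 mV for
  permeability ratios between 1 and 15 under the study's solutions. The
  bi-ionic conversion ignores the 12 mM internal Na⁺ by construction of the
  potassium internal solution; RT/F defaults to 24.53 mV (11.5 °C).
- G–V curves divide peak (or, for the leaky variants, steady-state) current
  by the linear driving force V − V_rev, exclude sweeps within 2 mV of the
  reversal, and fit the two-state curve; Q–V integrates baseline-subtracted
  on-gating currents and flags unsettled sweeps.

## Pore profiler

The profiler is a deterministic simplification of the classic
largest-inscribed-sphere pore tracer: per 0.25 Å axial slab it maximizes
min_i(|c − x_i| − vdW_i) over in-plane centers by a 0.5 Å coarse grid plus
Nelder–Mead refinement, with ≤1 Å center drift per step, a 15 Å unbounded-slab
cutoff, Bondi radii, hetero records excluded by default (detergents lodged in
the pore confound the profile) and highest-occupancy altloc conformers kept.
Axis choice is the principal axis unless supplied. Local radius minima with
≥0.2 Å prominence whose separation is one α-helix turn (5.4 ± 1.5 Å) are
reported as two-tier constriction candidates with their nearest residues.
The deterministic search trades the annealed wobble of the original tool for
reproducibility; on near-cylindrical pores at this step size the difference
is below the grid tolerance. Deposited-structure runs require files on disk;
the shipped tests exercise the profiler on constructed geometries with known
answers.

## Problem sizes

Shipped protocols digitize at 100 kHz (10 µs sampling, sufficient at 20 kHz
bandwidth) with sweep families of 10–19 sweeps and 20–250 ms per sweep;
availability protocols use 40 ms conditioning and Q–V 60 ms pulses so that
the measured curves sit at their stationary values. The full reproduction
script runs in well under a minute on a single core.

## Known limitations

- Recovery from inactivation is not separately calibrated (recovery
  protocols are out of scope); its voltage dependence is constrained by the
  topology as noted above.
- DIIAA is parameterized only as a reduced opening rate; the mechanism of
  its VSD–PD uncoupling is deliberately left open.
- Whether ⑦ and ⑧ conduct equally is not experimentally determined; the
  shipped 3% ratio for ⑦ is a modelling choice that keeps the leak
  accessible from closed states while preserving the printed tail kinetics.
- The Q10/temperature dependence of rates is not modelled; all rates are
  implicitly at 11.5 °C.
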