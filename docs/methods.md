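# Methods

## Model and assumptions

The channel is a continuous-time Markov chain over nine conformational
states: three closed (C1, C2, C3), one open (O), two closed-inactivated
(IC1, IC2), two fast-inactivated (IF1, IF2) and one slowly populated
inactivated state (IS). The activation backbone C1–C2–C3–O carries
forward rates a11, a12, a13 and backward rates b11, b12, b13; the
closed-inactivated row IC1–IC2–IF1 reuses the backbone rates a11/a12
(forward) and b11/b12 (backward); vertical transitions between the rows
use a3 (toward the non-inactivated row) and b3 (toward the inactivated
row); open-state fast inactivation is O–IF1 (a2/b2) with a deeper state
IF1–IF2 (a6/b6); the parallel slow pathway is O–IS (a2s/b2s) with
IS–C3 recovery (a3s/b3s).

This arrangement is the unique placement consistent with the two
reversibility constraints the rate table carries: b2 and b3s are not
free parameters but are computed as

    b2  = a13·a2·a3   / (b13·b3)
    b3s = a2s·a3s·a13 / (b2s·b13)

which are exactly the detailed-balance solutions of the C3–O–IF1 and
C3–O–IS triangles. The two square loops of the inactivated row
(C1–C2–IC2–IC1 and C2–C3–IF1–IC2) then balance automatically because
they reuse the backbone rates. Both shipped parameter sets satisfy both
loop conditions to relative 1e-12 at every voltage tested.

Every free rate is a single exponential in membrane potential,
`A·exp(±V/k)` (or `1/(A·exp(∓V/k))` for the backbone), multiplied by a
common temperature factor `1/Q10^((37 − T°C)/10)` with Q10 = 3 at
295 K (22 °C, the recording temperature); at 37 °C the factor is 1.
Units are mV, ms and ms⁻¹ throughout. Several fitted slope factors sit
near 1000 mV — effectively voltage-independent rates, a signature of the
optimizer having pushed them to a bound; they are kept exactly as
tabulated.

Current is ohmic through the open state only, `I = g_max·P_O·(V −
E_rev)`, with `g_max = 1`: the model reproduces normalized currents, and
every measured quantity (ratios, time constants, argmax voltages) is
independent of `g_max`. `E_rev` defaults to +75 mV, the Nernst potential
of the standard 151/8 mM Na⁺ condition at 295 K; the low-sodium
condition (50/15 mM, ≈ +30 mV) is available through
`CurrentModel.from_concentrations`.

What the model does *not* contain: liquid-junction or series-resistance
artifacts, capacitive transients, space-clamp error, stochastic channel
noise, or more than one channel population. The last point matters: the
experimentally observed differential recovery of the transient and
resurgent components after a brief gap is *not* reproduced — a
single-population model recovers both together (the sequential-recovery
ratios come out equal, ≈1.0, rather than 0.95 vs 0.63) — and the tests
assert this equality as model behavior, not as an experimental match.

## Propagation

Occupancies advance by the matrix-exponential rule
`p(t+dt) = p(t)·expm(Q(V)·dt)`, with one `scipy.linalg.expm` call per
constant-voltage segment applied repeatedly at the sample interval
(default 0.005 ms; depolarizing segments use 0.001–0.002 ms because the
transient peaks ~0.03 ms after a strong step). A spectral
(eigendecomposition) evaluation was tried and rejected: the generator's
rates span ~1e-5 to ~1e4 ms⁻¹ and the eigenvector systems are too
ill-conditioned. Ramps are discretized into piecewise-constant sub-steps
of ≤ 0.25 mV held at the midpoint voltage; halving the sub-step changes
measured peaks by < 0.5% (asserted in tests). Steady states come from
the null space of the transposed generator (fallback: propagation over
1e6 ms if the null space is degenerate).

Accuracy cross-checks: the semigroup property holds to 1e-10; forward
Euler at dt = 1e-5 ms agrees with the matrix exponential to 1e-6 in
L∞ (at dt = 1e-4 ms Euler's own first-order error is ~1e-5 on this
stiff system, and the tests verify the ~10× error ratio between the two
step sizes); occupancy rows sum to 1 within 1e-9 over every protocol.

## Measurement conventions

Peaks are the extremum of |I| in a segment window, sign preserved. The
persistent level of a segment is the mean current over its trailing 5%
(robust to sampling; a warning is issued for segments under 10 ms) and
is subtracted before resurgent peak and time-constant measurements,
mirroring the digital I_NaP subtraction applied to experimental records.
For brief (≈5 ms) depolarizing steps the transient peak is measured raw —
the persistent level is a few percent of the transient peak, so
subtracted and raw peaks are indistinguishable for these records. Decay
time constants use the exact 1/e crossing after the peak, linearly
interpolated between samples (1/e retention is 63.2% decay; the
conventional "64% decay" is the same measure, rounded). Exponential
(`A·exp(−x/τ)` ± offset) and Boltzmann (`1/(1+exp((V_h−V)/k))`) fits use
deterministic initialization so repeated runs are bit-identical; in the
Boltzmann form the sign of k distinguishes activation (rising, k > 0)
from availability (falling, k < 0). Both Boltzmann applications use the
`/k` (divided) slope form.

## Protocol battery

The nine optimization protocols start from the steady state at −90 mV
unless stated otherwise: steady-state availability (conditioning −120…
−10 mV, test step to 0 mV, normalized at −120); activation (hold −80,
steps −77…0 mV in 3 mV increments — the grid appends the 0 mV
normalization anchor, which 3 mV steps from −77 do not reach);
inactivation tau (−50…0 mV, 1/e); recovery at −90 mV (20 ms conditioning
pulse, intervals 1–500 ms); persistent fraction (current at the end of
100 ms at −45 mV over the transient peak); resurgent/transient ratio
(repolarizations −80…−5 mV after 5 ms at 0 mV); duration dependence
(+20 mV prepulses, 2–36 ms in 2 ms steps, repolarization to −45 mV,
normalized at 2 ms); resurgent decay taus (−45…−5 mV); and prepulse
independence (−35…−5 mV prepulses, reported with the coefficient of
variation of the peaks). Repolarization windows default to 100 ms, long
enough to capture the peak and most of the decay everywhere tested.
Figure-level paradigms add the three-component trace, the
resurgent-voltage sweep from −80 mV, sequential recovery, the envelope
test and 0.12 mV/ms ramps.

Envelope test convention: each 2 ms repolarization's peak is compared
with the sustained −45 mV trace at the same absolute time after the
first repolarization onset (the superposition the experiment shows is in
absolute time), and the deviation is reported relative to the peak
sustained current. For the wild-type parameters the first ~8 repetitions
agree within 5%; late in the 80 ms train the repetitive envelope decays
a few percent deeper (extra slow inactivation accumulates during the
interspersed 0 mV steps), bringing the worst-case deviation to ~7%.

Small non-idealities of the fitted model, asserted as such in the tests:
the availability curve carries a <3% non-monotonic ripple around
−80/−75 mV (conditioning changes the closed-state distribution and hence
the speed of the activation/inactivation race); the conductance curve
droops ~4% above −15 mV; recovery overshoots 1.0 by ~1e-4 before
settling.

## Fitting

The cost of a protocol is the sum of squared differences between
simulated and target summary curves on a shared grid; for the
prepulse-independence protocol it is the dispersion of the simulated
peaks around their own mean, which drives the fit toward a
voltage-independent resurgent peak without prescribing its amplitude —
this term is an intrinsic property of the parameter set (~1e-3 for the
shipped wild type) and does not vanish at self-consistency, unlike every
data-matching term. The total cost is a weighted sum (default weights 1,
exposed because curve lengths differ).

Positivity of the rate constants is enforced by optimizing log
parameters with an otherwise standard Nelder–Mead simplex; every simplex
vertex maps to strictly positive rates by construction. The simplex is
restarted from the best point whenever it collapses without further
improvement, while the evaluation budget (default 5000) lasts. Default
convergence tolerances are 0.01 on the cost change and 0.01 on the
(log-)parameter change — appropriate for experimental-data cost
magnitudes; recovery experiments against noiseless synthetic targets
tighten them (1e-10 / 1e-6) because the attainable cost floor is ~1e-12.
A `free=` subset restricts the fit to chosen parameters, the practical
mode given the model's limited identifiability: recovery is therefore
always judged in curve space (pointwise deviation relative to each
curve's amplitude scale), never as parameter identity.

Experimental target curves are not shipped; `synthesize_targets` runs
the protocols for a parameter set and optionally adds seeded Gaussian
noise to the y values. This emulates the *shape and grid* of the
experimental mean curves, with independent homoscedastic noise — it does
not emulate cross-cell variability, correlated sweep noise, or
instrumentation artifacts, so passing recovery tests show that the
optimizer can invert the model's own curve map, not that fits to real
recordings are unique. Problem sizes for the recovery experiments (a
4-protocol battery on coarsened grids — 7-point availability, 6-point
inactivation-tau, 6-point ratio, 6-point duration, with 0.02 ms
repolarization sampling and 60 ms windows; ×1.3 perturbations of 5
parameters; ≤2000 evaluations; seeds 1–3) were chosen so the experiment
completes in minutes while leaving the outcome unchanged relative to the
full battery.

The Scn4b⁻/⁻ refit procedure restarts from the wild-type optimum with
the resurgent/transient ratio protocol pointed at a reduced-amplitude
target while all other protocols keep their wild-type targets. Against
noiseless self-generated wild-type targets the compromise optimum stays
essentially at wild type: the resurgent peak amplitude is set by the
recovery-through-open flux, which the slow-pathway rates barely touch
(scaling a2s ×1.5–×3 moves the peak ratio < 4% while speeding the decay
taus 25–54%), so amplitude cannot be traded without breaking the
kinetics targets. The shipped (tabulated) Scn4b⁻/⁻ set — obtained by the
original optimization against experimental data — reduces the resurgent
peak to ~73% of wild type with < 10% change in decay tau, via reduced
IF2 and increased IS occupancy during the depolarization.

## Open-channel-block comparison

The competing mechanism is shipped as a 13-state topology: backbone
C1–…–C5–O, inactivated row I1–…–I6 with verticals C_i–I_i and O–I6, and
an open-blocked state OB connected *only* to O (enforced structurally:
rate tables with any other OB edge are rejected). The published numeric
rates for this scheme are not reproduced; the module ships a synthetic
placeholder set (so labelled) that is qualitatively reasonable —
activation favored by depolarization, block favored at positive
potentials, unblock and deactivation on hyperpolarization, no slowly
absorbing state — sufficient to demonstrate the structural contrast: the
nine-state model attenuates the resurgent peak by ~61% as the prepulse
grows from 2 to 36 ms, the placeholder OB scheme by ~0%, and the OB
scheme regenerates full-sized transients on each re-depolarization of
the envelope protocol. Users with the published rate constants can load
them via the flat `FROM.TO.amp` / `FROM.TO.vslope` file format.

## Known limitations

- The printed parameter tables do not reproduce two quantitative
  experimental anchors: the simulated duration-dependence time constant
  is ~36–43 ms against the measured 15.5 ± 0.5 ms (the slow eigenmode of
  the generator at +20 mV is 43.6 ms, fully pinned by the tabulated
  rates and the reversibility constraints), and the Scn4b⁻/⁻ resurgent
  amplitude is ~73% of wild type against the reported ~50%. The voltage
  of maximal resurgent current (−45 mV), the prepulse independence
  (CV ~1%), the near-superposed envelope, and the <10% Scn4b⁻/⁻ kinetics
  shift all reproduce.
- Model non-uniqueness: many parameter sets (and topologies) fit the
  same protocol outputs; nothing here is an identifiability analysis.
- Single channel population; no differential transient/resurgent
  recovery.
- Temperature enters only through the common Q10 factor; no
  rate-specific temperature dependence.
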