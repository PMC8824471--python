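# navresurge

Markov kinetic modelling of the voltage-gated sodium (Nav) currents of
cerebellar Purkinje neurons: a voltage-clamp protocol simulator and
rate-constant fitting toolkit for the nine-state gating scheme with
parallel fast and slow inactivation pathways that reproduces the
transient (I<sub>NaT</sub>), persistent (I<sub>NaP</sub>) and resurgent
(I<sub>NaR</sub>) current components.

## Who this is for

Computational neurophysiologists and ion-channel biophysicists who want
to simulate voltage-clamp experiments on this class of gating models,
measure the simulated currents with the conventions used for
experimental records (persistent-current subtraction, 1/e decay time
constants, Boltzmann fits), refit rate constants to summary curves, or
contrast the parallel-inactivation mechanism with the competing
open-channel-block (OB) account of the resurgent current.

## The model

Nine states — closed C1, C2, C3; open O; closed-inactivated IC1, IC2;
fast-inactivated IF1, IF2; slow-inactivated IS — connected by
voltage-dependent rates (ms⁻¹, voltage in mV):

```
   C1 ⇄ C2 ⇄ C3 ⇄ O            activation backbone  (a11/b11, a12/b12, a13/b13)
   ↕     ↕     ↕    ↕
  IC1 ⇄ IC2 ⇄ IF1 ⇄ IF2        inactivated row      (verticals a3/b3; O–IF1 a2/b2; IF1–IF2 a6/b6)
               ↑
   O ⇄ IS ⇄ C3                 slow pathway          (a2s/b2s; a3s/b3s)
```

Each rate is a single exponential in voltage scaled by a common
temperature factor, Tfactor = 1/Q10^((37−T°C)/10) with Q10 = 3 at 295 K.
Two rates are not free: `b2 = a13·a2·a3/(b13·b3)` and
`b3s = a2s·a3s·a13/(b2s·b13)` close the C3–O–IF1 and C3–O–IS loops under
microscopic reversibility. Occupancy evolves by the matrix-exponential
rule `p(t+dt) = p(t)·exp(Q(V)·dt)`; open-channel current is ohmic,
`I = g_max·P_O·(V − E_rev)` with `g_max = 1` (normalized units) and
`E_rev` from the Nernst relation (+75 mV for 151/8 mM Na⁺ at 295 K).

Fast inactivation (O → IF1 → IF2) terminates I<sub>NaT</sub>; re-opening
from IF1 on repolarization produces I<sub>NaR</sub>, whose decay reflects
slow accumulation into IS. Two optimized parameter sets ship with the
package: wild type and Scn4b⁻/⁻ (Navβ4-null).

## Worked example

```bash
python examples/01_three_current_components.py
```

prints

```
I_NaT peak: -6.906 at t = 0.010 ms   (fast inward transient)
I_NaR peak: -1.362 at t = 5.92 ms  (slow hump on repolarization)
I_NaR decay tau (1/e): 12.1 ms             (slow accumulation into IS)
I_NaP level at -45 mV: -0.309         (non-inactivating plateau)
I_NaR / I_NaT = 0.197; I_NaP / I_NaT = 0.045
Currents are in normalized units (g_max = 1); negative = inward.
```

i.e. a 5 ms step to 0 mV from −80 mV evokes a fast inward transient
that decays to a small persistent plateau; the repolarization to −45 mV
reveals the slower resurgent hump (~20% of the transient peak) that
decays with a ~12 ms time constant as channels accumulate in IS. The
other scripts in `examples/` cover the duration dependence and voltage
dependence of I<sub>NaR</sub>, the Scn4b⁻/⁻ comparison, the envelope
test, slow ramps, fit recovery, and the OB-mechanism contrast.

From the shell, the same machinery is available as a thin CLI:

```bash
navresurge protocol duration --model wt --out duration.csv
navresurge simulate --hold -90 --step 0:5 --step -45:100 --out trace.csv
navresurge compare --out mechanisms.csv
```

## Library tour

- `navresurge.parameters` — the 24-parameter rate tables
  (`wild_type()`, `scn4b_null()`, flat-text parameter files)
- `navresurge.kinetics` — rate laws, temperature scaling, the nine-state
  scheme, generator assembly, reversibility residuals
- `navresurge.propagation` — steady states, matrix-exponential
  propagation, step/ramp protocol simulation, Nernst potentials
- `navresurge.analysis` — peak and persistent-current measurement, 1/e
  time constants, exponential and Boltzmann fits
- `navresurge.protocols` — the nine optimization protocols (availability,
  activation, inactivation tau, recovery, persistent fraction,
  resurgent/transient ratio, duration dependence, resurgent decay taus,
  prepulse independence) plus the figure-level paradigms (sequential
  recovery, envelope test, slow ramps)
- `navresurge.optimize` — sum-of-squares protocol costs, synthetic
  target generation, constrained (log-space) Nelder–Mead fitting, the
  Scn4b⁻/⁻ refit procedure
- `navresurge.ob` — the 13-state open-channel-block topology as a
  pluggable scheme, with structural invariants and a synthetic
  placeholder rate set for mechanism comparison

See `docs/methods.md` for the model assumptions, measurement
conventions, numerical choices and known limitations.

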