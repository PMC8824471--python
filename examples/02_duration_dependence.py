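"""Attenuation of the resurgent current with prepulse duration.

Longer depolarizations to +20 mV drive more channels into the slowly
populated inactivated state (IS), so less resurgent current is available
on the subsequent repolarization to -45 mV.
"""
import navresurge as nv

model = nv.NavModel(nv.wild_type())
curve = nv.duration_dependence(model)  # prepulses 2-36 ms in 2 ms steps
fit = nv.fit_single_exponential(curve.x, curve.y, with_offset=True)

for d, y in zip(curve.x, curve.y):
    if d in (2.0, 10.0, 20.0, 36.0):
        print(f"prepulse {d:5.1f} ms -> normalized peak I_NaR {y:.3f}")
print(f"single-exponential fit: tau = {fit.tau_ms:.1f} ms (time constant of the")
print("attenuation, i.e. of slow-inactivated-state entry at +20 mV)")
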