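"""Simulate the classic paradigm that reveals all three Nav current components.

A brief depolarization to 0 mV evokes the fast transient current (I_NaT),
which decays to the small persistent plateau (I_NaP); the repolarization
to -45 mV reveals the slow resurgent current (I_NaR).
"""
import navresurge as nv

model = nv.NavModel(nv.wild_type())
trace = nv.three_component_trace(model)  # hold -80, 5 ms at 0 mV, 100 ms at -45 mV

inat, t_inat = nv.measure_peak(trace, trace.segment_window(0))
t, adj, persistent = nv.subtract_persistent(trace, trace.segment_window(1))
inar = min(adj)
t_inar = t[list(adj).index(inar)]
tau = nv.tau_one_over_e(t, adj)

print(f"I_NaT peak: {inat:+.3f} at t = {t_inat:.3f} ms   (fast inward transient)")
print(f"I_NaR peak: {inar:+.3f} at t = {t_inar:.2f} ms  (slow hump on repolarization)")
print(f"I_NaR decay tau (1/e): {tau:.1f} ms             (slow accumulation into IS)")
print(f"I_NaP level at -45 mV: {persistent:+.3f}         (non-inactivating plateau)")
print(f"I_NaR / I_NaT = {abs(inar) / abs(inat):.3f}; I_NaP / I_NaT = {abs(persistent) / abs(inat):.3f}")
print("Currents are in normalized units (g_max = 1); negative = inward.")
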