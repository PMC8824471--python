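"""Voltage dependence of the peak resurgent current.

After a 5 ms step to 0 mV from -80 mV, the repolarization voltage is
swept from -70 to -10 mV; the resurgent current is largest near -45 mV,
where re-opening from the fast-inactivated state and the inward driving
force trade off best.
"""
import numpy as np
import navresurge as nv

model = nv.NavModel(nv.wild_type())
curve = nv.resurgent_ratio_curve(
    model, repol_mV=tuple(np.arange(-70.0, -9.0, 5.0)),
    holding_mV=-80.0, normalize=False,
)
for v, y in zip(curve.x, curve.y):
    marker = "  <-- max" if y == curve.y.max() else ""
    print(f"repolarization {v:6.0f} mV -> peak I_NaR {y:.3f}{marker}")
print(f"\npeak resurgent current is maximal at {curve.x[np.argmax(curve.y)]:.0f} mV")
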