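"""Envelope test: repetitive brief repolarizations vs one sustained step.

If the slow inactivation that terminates the resurgent current competed
with fast inactivation, interrupting the repolarization repeatedly would
change the envelope of the peaks. Here the peaks of successive 2 ms steps
to -45 mV trace the decay of the sustained current, showing a common,
non-competing slow-inactivation trajectory.
"""
import navresurge as nv

model = nv.NavModel(nv.wild_type())
sustained, repetitive, deviation = nv.envelope_comparison(model)

print("peaks of successive 2 ms repolarizations (normalized units):")
for seg in range(1, len(repetitive.segment_bounds), 2):
    amp, t_peak = nv.measure_peak(repetitive, repetitive.segment_window(seg))
    print(f"  t = {t_peak - repetitive.segment_window(1)[0]:5.1f} ms after first "
          f"repolarization: |I| = {abs(amp):.3f}")
print(f"\nmax deviation from the sustained-trace envelope: {100 * deviation:.1f}% "
      "(relative to the peak sustained current)")
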