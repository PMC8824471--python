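"""Parallel-inactivation vs open-channel-block mechanisms.

The duration-dependence protocol discriminates the two accounts of the
resurgent current: a slowly absorbing inactivated state (9-state model)
strongly attenuates the resurgent peak as the prepulse lengthens, while
an open-channel-block scheme with no such state shows little attenuation.
The OB rates used here are a synthetic placeholder (the topology, not the
published numbers, is what matters for the contrast).
"""
import navresurge as nv

nav = nv.NavModel(nv.wild_type())
ob = nv.build_ob_scheme(nv.synthetic_ob_rates())
rep_nav, rep_ob = nv.discriminate_mechanism(nav, ob)

for rep in (rep_nav, rep_ob):
    tau = f"{rep.duration_tau_ms:.1f} ms" if rep.duration_tau_ms != float("inf") else "n/a"
    print(f"{rep.label}:")
    print(f"  duration-dependence attenuation: {100 * rep.attenuation_fraction:.1f}% "
          f"(2 -> 36 ms prepulse), fitted tau {tau}")
    print(f"  envelope deviation: {100 * rep.envelope_deviation:.1f}%")
print("\nStrong attenuation marks the slowly absorbing inactivated state;")
print("the open-channel-block scheme lacks it.")
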