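"""Build the three thermal stimulus conditions and inspect them.

Constructs the conventional offset-analgesia (OA) stimulus, the two
noise variants (3 Hz disturbance during the T3 return-to-plateau
phase), and the constant familiarization stimulus, then prints phase
statistics and the rating-beep schedule.
"""

import oabayes as oa

protocol = oa.Protocol()
traces = oa.build_condition_traces(protocol)
schedule = oa.rating_schedule(protocol)

print("phase bounds (s):")
for phase, (on, off) in protocol.phase_bounds().items():
    print(f"  {phase:10s} {on:6.2f} -> {off:6.2f}")

print("\ntemperature during T3 (mean ± SD, °C):")
for cond, trace in traces.items():
    stats = oa.phase_stats(trace, "T3")
    print(f"  {cond:12s} {stats['mean']:6.2f} ± {stats['sd']:.2f}")

print("\nrating beeps (s from trial onset):")
for label, t in schedule.rating_times.items():
    print(f"  {label}: {t:.2f}")
print(f"  (reference beep at {schedule.ref_time:.2f})")

# The noise conditions match the conventional stimulus everywhere
# outside T3 and fluctuate within 44-46 °C inside it; the constant
# condition never leaves the 45 °C plateau.
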