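"""Detect oculomotor events in one simulated drive.

Generates a ten-minute drive on the easy ("field") course, runs the full
detection pass, and prints what the detector found: saccade/fixation/head
movement counts, the blink and VOR exclusions, and main-sequence summary
numbers.  The curved-saccade fraction is the share of saccades whose
traversed arc exceeds their chord by more than 15 deg.
"""

import numpy as np

from drivegaze import (
    DetectionConfig,
    GeneratorConfig,
    ScreenGeometry,
    detect_events,
    generate_subject,
    main_sequence,
    write_events,
)

cfg = GeneratorConfig(seed=7)
trace, scenario, truth = generate_subject(cfg)
print(f"trace: {trace.n} samples at {1 / trace.dt:.0f} Hz, {trace.duration:.0f} s")

events = detect_events(trace, DetectionConfig(), ScreenGeometry())
print(f"saccades retained:      {len(events.saccades)}")
print(f"blinks excluded:        {len(events.blinks)}")
print(f"fixations:              {len(events.fixations)}")
print(f"head movements:         {len(events.head_movements)} detected, "
      f"{len(events.head_movements_filtered)} after VOR exclusion")

ms = main_sequence(events.saccades)
amp = ms.table["amplitude"]
print(f"median saccade amplitude: {amp.median():.2f} deg "
      f"(90% between {amp.quantile(0.05):.1f} and {amp.quantile(0.95):.1f} deg)")
print(f"peak velocity at median amplitude: "
      f"{ms.table['peak_velocity'][amp.between(amp.median() - 1, amp.median() + 1)].mean():.0f} deg/s")
print(f"curved saccade fraction: {ms.curved_fraction:.3f}")

mean_fix = np.mean([f.duration for f in events.fixations]) * 1000
print(f"mean fixation duration: {mean_fix:.0f} ms")

write_events(events.saccades + events.head_movements, "scratch_events.tsv")
print("event table written to scratch_events.tsv")
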