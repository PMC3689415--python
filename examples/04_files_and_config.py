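"""Round-trip the plain-text file dialects and the YAML configuration.

Writes one simulated subject's trace and scenario to disk, reads them back,
re-runs detection on the loaded copy, and shows that a saved configuration
reproduces the thresholds.
"""

import tempfile
from pathlib import Path

from drivegaze import (
    DetectionConfig,
    GeneratorConfig,
    ScreenGeometry,
    detect_events,
    generate_subject,
    load_config,
    load_scenario,
    load_trace,
    save_config,
    save_scenario,
    save_trace,
)

out = Path(tempfile.mkdtemp(prefix="drivegaze_"))
cfg = GeneratorConfig(seed=5, duration_s=60.0, n_hazard_events=4, n_signs_cars=0)
trace, scenario, _ = generate_subject(cfg)

save_trace(trace, out / "subject01_trace.csv")
save_scenario(scenario, out / "subject01")
save_config(out / "analysis.yaml", DetectionConfig(), ScreenGeometry())
print("wrote:", *sorted(p.name for p in out.iterdir()), sep="\n  ")

geom, det = load_config(out / "analysis.yaml")
trace2 = load_trace(out / "subject01_trace.csv")
scen2 = load_scenario(out / "subject01")
events = detect_events(trace2, det, geom)
print(f"\nreloaded trace: {trace2.n} samples; scenario: {len(scen2.objects)} objects "
      f"({scen2.n_hazardous} hazardous)")
print(f"detection on the reloaded copy: {len(events.saccades)} saccades, "
      f"{len(events.fixations)} fixations")
print(f"saccade threshold from YAML: {det.saccade_vel_thresh} deg/s")
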