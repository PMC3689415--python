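"""drivegaze: oculomotor event detection, reaction times, and cohort models
for head-unrestrained driving-simulator experiments.

The pipeline runs raw eye/head traces and a scenario event log through
velocity-threshold saccade detection (with blink, curved-saccade and
off-screen classification and vestibulo-ocular exclusion of head movements),
matches fixations to target objects to obtain manual and first-detection
reaction times, aggregates per-subject metrics, and codes/fits the study's
linear mixed-effects and logistic designs.  A synthetic-data generator with
full ground truth makes every stage testable at desk scale.
"""

from .config import DetectionConfig, load_config, save_config
from .design import (
    CodedDesign,
    FitResult,
    code_design,
    fit_lmm,
    fit_logistic,
)
from .events import (
    EventSet,
    Fixation,
    HeadMovement,
    Saccade,
    VORSegment,
    classify_saccade,
    classify_saccades,
    compute_velocity,
    detect_events,
    detect_head_movements,
    detect_saccades,
    detect_vor,
    filter_head_movements,
    main_sequence,
    segment_fixations,
)
from .exceptions import (
    AmbiguityWarning,
    CodingError,
    ConfigError,
    DriveGazeError,
    FormatError,
    GeometryError,
    InsufficientDataError,
    RankDeficiencyError,
    TrackCoverageError,
)
from .geometry import ScreenGeometry, angular_extent, deg_per_px
from .io import (
    load_events,
    load_scenario,
    load_trace,
    save_scenario,
    save_trace,
    write_events,
)
from .reactions import (
    ReactionRecord,
    detection_rate,
    match_object_fixations,
    reaction_times,
)
from .scenario import ManualResponse, ScenarioLog, TargetObject
from .simulate import (
    GeneratorConfig,
    GroundTruth,
    SubjectAttributes,
    evaluate_detection,
    generate_cohort,
    generate_cohort_table,
    generate_scenario,
    generate_subject,
)
from .summaries import subject_summary, summaries_table
from .trace import GazeTrace

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def process_subject(trace, scenario, cfg=None, geom=None, window: float = 10.0):
    """Run detection and reaction-time extraction for one drive.

    Returns ``(events, records)``: the :class:`EventSet` and the per-object
    :class:`ReactionRecord` list.
    """
    cfg = cfg or DetectionConfig()
    geom = geom or ScreenGeometry()
    events = detect_events(trace, cfg, geom)
    matches = match_object_fixations(events.fixations, scenario.objects, cfg)
    records = reaction_times(scenario.objects, matches, scenario.responses, window=window)
    return events, records
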