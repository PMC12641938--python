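"""Shared cohort construction for the numbered analysis scripts.

Every script regenerates the same deterministic cohort (5 training levels
x 5 sessions of 120 s at 200 Hz, base seed 42) rather than passing bulky
gaze streams between processes; generation takes seconds and the manifest
written by 01_simulate_cohort.py records the exact seeds.
"""

from __future__ import annotations

from pathlib import Path

import surgaze as sg

BASE_SEED = 42
N_PER_GROUP = 5
SESSION_S = 120.0
MODEL_CIRCLE = ((960.0, 216.0), 120.0)  # capsulorhexis model in the scene

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_cohort():
    """(records, manifest, geometry, surfaces) for the study cohort."""
    geometry = sg.ViewGeometry()
    surfaces = sg.generate_surfaces(geometry)
    profiles = [sg.STUDY_PROFILES[g] for g in sg.GROUP_ORDER]
    records, manifest = sg.generate_cohort(
        profiles, N_PER_GROUP, BASE_SEED, geometry, surfaces, SESSION_S
    )
    return records, manifest, geometry, surfaces


def detect(record, geometry):
    """Confidence-filter and classify one session's events."""
    from surgaze import events as ev

    filtered = ev.filter_by_confidence(record.stream, 0.6)
    fixations = ev.detect_fixations(filtered)
    saccades = ev.extract_saccades(fixations)
    blinks = ev.detect_blinks(record.stream)
    return fixations, saccades, blinks
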