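"""Shared fixtures: simulated sessions are expensive enough to build once."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gaitsync as g


@pytest.fixture(scope="session")
def checker_bundle() -> g.StreamBundle:
    """Default checkerboard session, single-script display chain."""
    return g.simulate_session("checkerboard", seed=42)


@pytest.fixture(scope="session")
def checker_decoded(checker_bundle) -> list[g.MarkerEvent]:
    digital = g.digitize_schmitt(checker_bundle.stream("photodiode"))
    return g.decode_events(digital)


@pytest.fixture(scope="session")
def checker_vep(checker_bundle, checker_decoded):
    """Grand-average VEP and peak measures of the checkerboard session."""
    lock = g.compensate_display_delay(
        checker_decoded, checker_bundle.metadata["acquisition_delay_eeg"]
    )
    lock = [dataclasses.replace(e, clock_id="eeg") for e in lock]
    with np.errstate(all="ignore"):
        evoked, peaks, epochs = g.vep_pipeline(checker_bundle, lock)
    return evoked, peaks, epochs


@pytest.fixture(scope="session")
def stg_bundle() -> g.StreamBundle:
    """Default start-to-go session (50 cycles)."""
    return g.simulate_session("start_to_go", seed=7)


@pytest.fixture(scope="session")
def stg_detection(stg_bundle):
    """COP-derived onsets, raw detections and QC flags for the session."""
    return g.detect_onsets_bundle(stg_bundle)
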