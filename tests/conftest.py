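import warnings

import numpy as np
import pytest

from tuwave.delineate import locate_fiducials
from tuwave.preprocess import average_beats, detect_beats, wavelet_denoise
from tuwave.synthetic import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", message="FastICA did not converge")


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject cohort (4 per group) at the default study conditions."""
    return generate_cohort(CohortConfig(n_per_group=4, seed=11))


@pytest.fixture(scope="session")
def processed(small_cohort):
    """(beat, fiducials, truth) per subject, delineated on the truth lead."""
    out = []
    for rec, truth in small_cohort:
        beat = wavelet_denoise(average_beats(rec, detect_beats(rec)))
        try:
            fid = locate_fiducials(beat, lead=truth.analysis_lead)
        except ValueError:
            continue
        out.append((beat, fid, truth))
    assert len(out) >= 6
    return out


@pytest.fixture(scope="session")
def one_beat(processed):
    """A single denoised ATS1-like beat with its fiducials."""
    for beat, fid, truth in processed:
        if truth.group == "ATS1":
            return beat, fid, truth
    raise RuntimeError("no ATS1 subject in fixture cohort")
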