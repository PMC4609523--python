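import numpy as np
import pytest

from ctcnoise import (
    AnnotationMatrix,
    calibrate_difficulty,
    default_profiles,
)

#: Published per-observer CTC counts over the 617-cutout study panel,
#: with the corresponding counts restricted to the 502-point consensus
#: subset.  MB and MTF are the two conservative (false-positive-avoiding)
#: observers.
OBSERVER_IDS = ("SD", "MP", "TL", "ST", "MB", "BH", "MTF", "CMS", "SB", "JP", "RH")
COUNTS_ALL = (307, 281, 303, 354, 223, 327, 221, 347, 318, 330, 294)
COUNTS_CONSENSUS = (244, 244, 248, 258, 206, 257, 210, 260, 255, 250, 245)
CONSERVATIVE_IDS = ("MB", "MTF")


@pytest.fixture(scope="session")
def observer_counts():
    return OBSERVER_IDS, COUNTS_ALL, COUNTS_CONSENSUS


@pytest.fixture
def tiny_ann():
    """Hand-built 6 x 3 annotation matrix with known statistics."""
    labels = np.array(
        [
            [1, 1, 1],
            [1, 1, 0],
            [0, 0, 0],
            [1, 0, 1],
            [0, 0, 0],
            [1, 1, 1],
        ]
    )
    return AnnotationMatrix(labels, ("A", "B", "C"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def calibrated_distribution():
    """Difficulty mixture calibrated once per session to the study's
    aggregate targets (mean agreement 0.85, consensus fraction 0.81)."""
    return calibrate_difficulty(0.85, 0.81, default_profiles(), seed=1)
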