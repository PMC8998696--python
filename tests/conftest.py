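import numpy as np
import pytest
from scipy.spatial import cKDTree

from myoquant import SectionParams, generate_section
from myoquant.morphometry import analyze_section


@pytest.fixture(scope="session")
def section_and_truth():
    """One mixed-type synthetic section shared by recovery tests."""
    return generate_section(SectionParams(n_fibers=16, seed=11))


@pytest.fixture(scope="session")
def analyzed(section_and_truth):
    section, _truth = section_and_truth
    lab, fibers = analyze_section(section)
    return lab, fibers


def match_truth(fibers, truth_fibers):
    """Align measured fibers with truth rows by nearest centroid.

    Returns the truth fiber ids in the row order of `fibers`.
    """
    tree = cKDTree(truth_fibers[["centroid_y", "centroid_x"]])
    _, idx = tree.query(fibers[["centroid_y", "centroid_x"]])
    return np.asarray(truth_fibers["fiber_id"])[idx]
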