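import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nasalmorph.synthetic import SynthParams, make_population, make_section
from nasalmorph.template import build_template


@pytest.fixture(scope="session")
def base_section():
    """One default synthetic section (mid-airway) plus its ground truth."""
    return make_section(SynthParams(), 30.0)


@pytest.fixture(scope="session")
def single_template(base_section):
    sec, _ = base_section
    return build_template([sec])[0]


@pytest.fixture(scope="session")
def small_population():
    """A small two-slice population for pipeline-level tests."""
    params = SynthParams(population_size=6, y_positions=(24.0, 30.0))
    return params, make_population(params)


def random_blob(rng, shape=(36, 36), n_disks=5) -> np.ndarray:
    """Random blobby test shape: union of disks and bars.

    Feature radii start at 3 px (~1.3 mm at scan resolution), matching the
    minimum passage width of real sections.
    """
    img = np.zeros(shape, bool)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for _ in range(n_disks):
        r0, c0 = rng.uniform(6, shape[0] - 6), rng.uniform(6, shape[1] - 6)
        rad = rng.uniform(3, 6)
        img |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    if rng.random() < 0.5:
        r0 = int(rng.integers(4, shape[0] - 8))
        img[r0 : r0 + int(rng.integers(2, 4)), 4:-4] = True
    return img
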