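import logging

import numpy as np
import pytest

from ramanfp.io import CohortDataset, RamanSpectrum, SubjectRecord, assemble_cohort
from ramanfp.synthetic import SyntheticConfig, simulate_cohort

logging.getLogger("ramanfp").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return np.linspace(400.0, 1600.0, 1501)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-effect cohort shared by fast integration tests."""
    cfg = SyntheticConfig(n_ctrl=5, n_pd=4, n_ad=3,
                          spectra_per_subject=(5, 5), seed=99)
    return simulate_cohort(cfg)


def make_gaussian_dataset(rng, groups, n_spectra=5, n_features=40,
                          shift_by_group=None):
    """Featureless (or group-shifted) Gaussian dataset on a fake grid."""
    grid = np.linspace(400, 1600, n_features)
    subjects, spectra = {}, []
    for i, g in enumerate(groups):
        sid = f"S{i:02d}"
        subjects[sid] = SubjectRecord(sid, g, 60.0, "M")
        offset = (shift_by_group or {}).get(g, 0.0)
        for j in range(n_spectra):
            y = rng.normal(size=n_features) + offset
            spectra.append(RamanSpectrum(grid, y, sid, f"{sid}_{j}"))
    return assemble_cohort(spectra, subjects)
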