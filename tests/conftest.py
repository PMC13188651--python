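"""Shared fixtures: a deterministic, synthetic study-structured cohort.

The ``study_cohort`` fixture is a constructed stand-in for a study data
file (synthetic; the real raw data are not redistributable): 46
experienced participants whose times sit exactly at log-normal quantiles
(median 2.18 min, CV 19.7%) with heavy-tailed experience counts >= 5
(one of them exactly 5), plus 6 inexperienced participants (counts < 5)
with clearly slower times.  Every structural fact the analyses rely on
(52 records, 6 below the experience threshold, a clean log-normal core,
all times under 5 minutes) holds by construction.
"""

import math

import numpy as np
import pytest
from scipy.special import ndtri

from proctol import Cohort, ParticipantRecord

MU_LOG = math.log(2.18)
SIGMA_LOG = math.sqrt(math.log1p(0.197**2))


def build_study_cohort() -> Cohort:
    n_exp = 46
    positions = (np.arange(1, n_exp + 1) - 0.375) / (n_exp + 0.25)
    exp_times = np.exp(MU_LOG + SIGMA_LOG * ndtri(positions))

    rng = np.random.default_rng(20250815)
    exp_counts = 5 + np.rint(np.exp(4.0 + 1.3 * rng.standard_normal(n_exp))).astype(int)
    exp_counts[0] = 5  # guarantee the threshold value itself is observed
    rng.shuffle(exp_counts)

    inexp_counts = [0, 1, 2, 3, 4, 4]
    inexp_times = [3.8, 4.1, 4.3, 4.5, 4.7, 4.9]

    records = [
        ParticipantRecord(f"S{i + 1:02d}", float(t), int(c), int(d), True)
        for i, (t, c, d) in enumerate(
            zip(
                np.concatenate([exp_times, inexp_times]),
                np.concatenate([exp_counts, inexp_counts]),
                rng.choice([0, 0, 0, 1, 2, 5, 8], size=52),
            )
        )
    ]
    return Cohort(records=tuple(records), provenance="synthetic study-structured")


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    return build_study_cohort()


@pytest.fixture()
def study_csv(study_cohort, tmp_path):
    from proctol import write_cohort

    path = tmp_path / "study.csv"
    write_cohort(study_cohort, path)
    return path
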