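"""Shared fixtures: small seeded cohorts generated in memory.

Everything is synthesized at test time; no data files ship with the
package.  The module-scoped fixtures keep the expensive simulate+extract
steps to one run per session.
"""

import numpy as np
import pytest

from laughdx.laughsim import CohortConfig, simulate_cohort
from laughdx.cli import extract_data_matrix

FS = 22_050


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x ~4 laughs with the default class effects."""
    cfg = CohortConfig(n_patients=6, n_controls=6, laughs_per_patient_mean=4,
                       laughs_per_control_mean=4, seed=42)
    subjects, laughs = simulate_cohort(cfg)
    return cfg, subjects, laughs


@pytest.fixture(scope="session")
def small_data_matrix(small_cohort):
    _, _, laughs = small_cohort
    matrix, log = extract_data_matrix([sl.record for sl in laughs])
    return matrix, log


def sine(freq_hz: float, duration_s: float = 0.5, fs: int = FS,
         amplitude: float = 0.5) -> np.ndarray:
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
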