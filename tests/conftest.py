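"""Shared fixtures: digital phantoms and a small synthetic cohort.

Everything is generated programmatically; the session-scoped cohort is
reused across test modules to keep the suite fast.
"""
from __future__ import annotations

import numpy as np
import pytest

from deltarad.grid import BinaryMask, VoxelGrid
from deltarad.synth import CohortConfig, simulate_cohort


def digital_sphere(radius_vox: int, spacing: float = 1.0, margin: int = 16) -> BinaryMask:
    n = 2 * (radius_vox + margin)
    c = n // 2
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    values = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    return BinaryMask(values=values, spacing_mm=np.full(3, spacing))


@pytest.fixture(scope="session")
def sphere10() -> BinaryMask:
    """Digital ball of radius 10 mm on a 1 mm grid."""
    return digital_sphere(10)


@pytest.fixture(scope="session")
def full_lung(sphere10) -> BinaryMask:
    return BinaryMask(
        values=np.ones(sphere10.shape, dtype=bool), spacing_mm=sphere10.spacing_mm
    )


@pytest.fixture(scope="session")
def noise_grid(sphere10) -> VoxelGrid:
    rng = np.random.default_rng(42)
    return VoxelGrid(
        values=rng.normal(0.0, 50.0, sphere10.shape), spacing_mm=sphere10.spacing_mm
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 + 10 patients at the default imaging conditions (smaller n only)."""
    cfg = CohortConfig(n_train=12, n_valid=10, retest_n=6)
    return simulate_cohort(cfg, seed=505)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """Extracted F0/F1/retest tables and outcomes for the small cohort."""
    import pandas as pd

    from deltarad.pipeline import extract_patient_features

    retest_ids = {p.patient_id for p in small_cohort[:6]}
    rows0, rows1, rowsr = {}, {}, {}
    for p in small_cohort:
        feats = extract_patient_features(p, with_retest=p.patient_id in retest_ids)
        rows0[p.patient_id] = feats["F0"]
        rows1[p.patient_id] = feats["F1"]
        if "retest" in feats:
            rowsr[p.patient_id] = feats["retest"]
    return {
        "F0": pd.DataFrame.from_dict(rows0, orient="index").sort_index(),
        "F1": pd.DataFrame.from_dict(rows1, orient="index").sort_index(),
        "retest": pd.DataFrame.from_dict(rowsr, orient="index").sort_index(),
        "intervals": pd.Series(
            {p.patient_id: p.scan_pair.interval_days for p in small_cohort}
        ),
        "outcomes": {
            p.patient_id: (p.outcome.time_months, p.outcome.event) for p in small_cohort
        },
    }
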