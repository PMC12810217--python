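"""Shared fixtures: oracles and a session-wide synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_partition(ijk: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Independent per-voxel oracle for the shell/centre split.

    A voxel is shell when it lies on the extreme k slices, or when some
    background cell (not in the voxel set) sits within in-plane Chebyshev
    distance ``thickness`` on its own slice.  O(n * thickness^2) scan.
    """
    vox = set(map(tuple, np.asarray(ijk)))
    ks = [k for _, _, k in vox]
    kmin, kmax = min(ks), max(ks)
    is_shell = []
    offsets = [
        (di, dj)
        for di in range(-thickness, thickness + 1)
        for dj in range(-thickness, thickness + 1)
        if (di, dj) != (0, 0)
    ]
    for i, j, k in np.asarray(ijk):
        if k in (kmin, kmax):
            is_shell.append(True)
            continue
        is_shell.append(
            any((i + di, j + dj, k) not in vox for di, dj in offsets)
        )
    return np.asarray(is_shell, dtype=bool)


@pytest.fixture(scope="session")
def full_cohort():
    """The default 43-subject cohort on the coarse demo grid (generated once)."""
    from myomet.synthetic import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
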