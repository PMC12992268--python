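"""Shared fixtures: small synthetic cohorts and physics fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from tdnirs.physics import GatedSeries, GateSet, OpticalProperties, _reflectance_raw
from tdnirs.protocol import TaskProtocol
from tdnirs.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def protocol() -> TaskProtocol:
    return TaskProtocol()


@pytest.fixture(scope="session")
def short_protocol() -> TaskProtocol:
    return TaskProtocol(rest_pre_s=10.0, task_s=20.0, rest_post_s=20.0, fs_hz=1.0)


@pytest.fixture(scope="session")
def direct_cohort():
    """Default-condition cohort, direct ratio rendering (one fixed seed)."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def small_tpsf_cohort():
    """Small photon-level cohort for physics-path tests."""
    spec = CohortSpec(seed=7, n_per_group=2, sessions_per_subject=1, mode="tpsf")
    return generate_cohort(spec)


def make_forward_gated(
    mua: float,
    gate_set: GateSet,
    musp: float = 1.0,
    n_tissue: float = 1.4,
    rho: float = 30.0,
    n_frames: int = 2,
    wavelengths=(760.0, 850.0),
) -> GatedSeries:
    """Noise-free gate-integrated intensities of the diffusion model."""
    v = OpticalProperties(mua=mua, musp=musp, n_tissue=n_tissue, rho=rho).v_mm_per_ps
    vals = np.zeros((1, len(wavelengths), len(gate_set.gates), n_frames))
    for g, (a, b) in enumerate(gate_set.gates):
        t = np.linspace(a, b, 2001)
        m = _reflectance_raw(t, 0.0, musp, n_tissue, rho, "extrapolated")
        vals[0, :, g, :] = np.trapezoid(m * np.exp(-mua * v * t), t)
    return GatedSeries(
        values=vals,
        channel_ids=(1,),
        wavelengths_nm=tuple(wavelengths),
        gate_set=gate_set,
        frame_times_s=np.arange(n_frames, dtype=float),
    )
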