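import numpy as np
import pytest

from turnmetry.skeleton import SkeletonSequence
from turnmetry.synthetic import SyntheticTurnSpec, _build_body


def body_from_yaw(yaw_deg, fps=50.0, **spec_kwargs):
    """Noise-free articulated body following an explicit pelvis-yaw track."""
    yaw = np.asarray(yaw_deg, dtype=float)
    spec = SyntheticTurnSpec(
        total_angle_deg=0.0, duration_s=yaw.size / fps, fps=fps, **spec_kwargs
    )
    coords, mask = _build_body(spec, yaw, np.random.default_rng(spec.seed))
    return SkeletonSequence(coords=coords, fps=fps, valid_mask=mask)


@pytest.fixture
def rigid_rotation():
    """Factory: rigid body turning at a constant rate (deg per frame pair)."""

    def _make(step_deg=10.0, n_steps=10, fps=50.0, start_yaw=0.0):
        yaw = start_yaw + step_deg * np.arange(n_steps + 1)
        return body_from_yaw(yaw, fps=fps)

    return _make


@pytest.fixture
def static_body():
    def _make(n_frames=50, fps=50.0):
        return body_from_yaw(np.zeros(n_frames), fps=fps)

    return _make
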