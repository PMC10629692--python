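"""Shared fixtures: rigs, fly models, and pre-rendered short sequences.

Expensive renders are session-scoped so multiple test modules reuse them.
"""

import warnings

import numpy as np
import pytest

from flyhull.cameras import make_rig
from flyhull.synthetic_fly import (
    build_fly_model,
    generate_wingbeat_sequence,
    pose_model,
    render_silhouettes,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def rig():
    """Default hybrid four-camera rig at 30 um pixel pitch."""
    return make_rig("hybrid4", pixel_pitch=30e-6)


@pytest.fixture(scope="session")
def model():
    return build_fly_model()


@pytest.fixture(scope="session")
def one_wingbeat(model):
    """A one-wingbeat hovering sequence (73 frames)."""
    return generate_wingbeat_sequence(model, n_wingbeats=1, seed=0)


@pytest.fixture(scope="session")
def rendered_frame(model, rig, one_wingbeat):
    """A mid-stroke posed fly with its rendered views (frame 18)."""
    seq = one_wingbeat
    f = 18
    posed = pose_model(model, seq.body[f], seq.left[f], seq.right[f])
    views = render_silhouettes(posed, rig)
    return posed, views, f, seq


@pytest.fixture(scope="session")
def rendered_stacks(model, rig, one_wingbeat):
    """Binary stacks of the one-wingbeat sequence, all cameras."""
    from flyhull.synthetic_fly import render_stacks

    full, body = render_stacks(model, one_wingbeat, rig, with_body_masks=True)
    return full, body
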