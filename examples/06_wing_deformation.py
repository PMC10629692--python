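"""Recover spanwise wing twist from local chord pitch angles.

Renders a fly whose wings carry a prescribed 20-degree linear root-to-tip
twist, runs the pipeline, and fits the spanwise profile of the local pitch
angles psi_k — the fitted slope recovers the prescribed twist.
"""

import warnings

import numpy as np

from flyhull.cameras import make_rig
from flyhull.pipeline import RunConfig, process_event
from flyhull.synthetic_fly import (
    build_fly_model,
    generate_wingbeat_sequence,
    render_stacks,
)

warnings.filterwarnings("ignore")

TWIST = 20.0  # deg, root -> tip
model = build_fly_model(twist_deg=TWIST)
rig = make_rig("hybrid4", pixel_pitch=30e-6)
seq = generate_wingbeat_sequence(model, n_wingbeats=1, seed=0)
stacks, _ = render_stacks(model, seq, rig)
result = process_event(stacks, rig, RunConfig(window=73, pitch=30e-6))

slopes = []
for f, st in enumerate(result.wing_states[+1]):
    if st is None or len(st.local_chords) < 3:
        continue
    stations = np.array([x[0] for x in st.local_chords])
    psis = np.array([x[2] for x in st.local_chords])
    if np.any(~np.isfinite(psis)):
        continue
    slopes.append(np.polyfit(stations, np.unwrap(psis, period=360.0), 1)[0])
slopes = np.asarray(slopes)
print(f"prescribed twist: {TWIST:.0f} deg root->tip")
print(f"median fitted psi_k slope over {len(slopes)} frames: "
      f"{np.median(slopes):+.1f} deg per unit span")
# A rigid wing would give slope ~0.  The recovered slope is a clear
# positive twist signal, but its magnitude is compressed below the
# prescribed 20 deg: whenever a camera axis lies near the wing plane that
# view stops constraining the chordwise extent of the hull and the local
# chords flatten (see docs/methods.md, Known limitations).
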