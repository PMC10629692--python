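"""End-to-end orchestration: silhouettes in, kinematics table out.

``process_event`` runs the full chain on synchronized per-camera binary
(or grayscale) stacks:

1. motion-based segmentation into body/wing masks per view;
2. per-frame voxel-grid construction, hull reconstruction (body, expanded,
   combined wing hulls) and the k-means wing split, with temporal identity
   tracking;
3. the per-wing refinement ladder (strip, tip cone, span, chord,
   reprojection, LE/TE edge hulls, local chords);
4. lateral-axis estimation from the span vectors, stroke-plane wing Euler
   angles, body angles and rates.

``validate_on_synthetic`` renders a ground-truth sequence with the
synthetic fly model, runs the pipeline on the rendered silhouettes and
reports per-angle error standard deviations after removing each angle's
median error (which absorbs convention offsets only).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hulls as hl
from . import kinematics as kin
from . import segmentation as seg
from . import wing_geometry as wg
from .cameras import CameraRig
from .conventions import chord_reference_frame, stroke_plane_normal, unit
from .synthetic_fly import (
    BodyTrajectorySpec,
    FlyModel,
    WingbeatSpec,
    build_fly_model,
    generate_wingbeat_sequence,
    render_stacks,
)


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run (serialized with outputs)."""

    binarize_threshold: float = 0.5
    fly_dark: bool = True
    occupancy_fraction: float = 0.85
    window: int | str = "auto"  # wingbeat window (frames) or "auto"
    pitch: float = 40e-6  # voxel pitch (m); ~one pixel footprint
    extent_in_wing_lengths: float = 2.8
    wing_length: float | None = None  # None: estimate from the event
    strip_bounds: tuple[float, float] = wg.STRIP_BOUNDS
    cone_half_angle_deg: float = wg.CONE_HALF_ANGLE_DEG
    cone_base_fraction: float = wg.CONE_BASE_FRACTION
    n_sections: int = 5
    seed: int = 0
    mask_dilation_px: int = 0  # pre-carve full/part mask dilation
    edge_dilation_px: int = 2
    initial_flight_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    # the visual hull is fatter along rig-fixed directions, pulling the
    # body axis toward a lab-anchored attractor (a gain-like error that
    # grows with body angles); when enabled, a reference-spheroid
    # simulation through the same carve measures and removes it
    axis_bias_correction: bool = True
    axis_bias_stride: int = 36  # frames between bias evaluations

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("strip_bounds", "initial_flight_direction"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EventResult:
    """Pipeline output: kinematics table, summaries and per-frame state."""

    table: pd.DataFrame
    summaries: list[kin.WingbeatSummary]
    wing_states: dict[int, list[wg.WingState]]
    body_cm: np.ndarray  # (T, 3)
    x_b: np.ndarray  # (T, 3)
    flagged_frames: int = 0
    failed: bool = False


def _binarize_stacks(stacks, config) -> dict[int, np.ndarray]:
    out = {}
    for cid, stack in stacks.items():
        stack = np.asarray(stack)
        if stack.dtype == bool:
            out[cid] = stack
        else:
            out[cid] = np.stack(
                [seg.binarize(f, config.binarize_threshold, config.fly_dark)
                 for f in stack]
            )
    return out


def process_event(
    stacks: dict[int, np.ndarray],
    rig: CameraRig,
    config: RunConfig | None = None,
    segmentations: dict[int, list] | None = None,
) -> EventResult:
    """Run the full pose-estimation pipeline on one flight event.

    ``stacks`` maps camera id to a (T, H, W) image stack (bool or
    grayscale), synchronized across cameras.  ``segmentations`` optionally
    substitutes precomputed :class:`~flyhull.segmentation.SegmentedFrame`
    lists per camera (e.g. ground-truth masks for ablation studies).
    Frames any stage cannot resolve are carried with NaN angles and a
    flag; the run is marked failed when more than half the frames are
    flagged.
    """
    config = config or RunConfig()
    rig_ids = {cam.id for cam in rig}
    missing = rig_ids - set(stacks)
    if missing:
        raise ValueError(f"no image stack for camera(s) {sorted(missing)}")
    stacks = _binarize_stacks(stacks, config)
    t_n = len(next(iter(stacks.values())))
    if any(len(s) != t_n for s in stacks.values()):
        raise ValueError("camera stacks have different lengths")

    # --- segmentation --------------------------------------------------
    segs = segmentations or {
        cid: seg.segment_body(
            stacks[cid], camera_id=cid, window=config.window,
            occupancy_fraction=config.occupancy_fraction,
        )
        for cid in sorted(stacks)
    }

    # --- per-frame hull reconstruction ---------------------------------
    fpw = seg.estimate_wingbeat_window(next(iter(stacks.values()))) \
        if config.window == "auto" else int(config.window)
    nominal_lw = config.wing_length or 2.5e-3  # provisional grid scale
    carver = None
    grid = None
    # only the split wing hulls are carried between stages; the full
    # per-frame bundles (15 hulls each) would dominate memory on long events
    wing_hulls: dict[int, list] = {+1: [], -1: []}
    body_eigs: list[np.ndarray] = []  # body-hull PCA spectra (sampled)
    body_axes = []
    body_cms = []
    frame_flags: list[set[str]] = [set() for _ in range(t_n)]
    prev_xb = None
    prev_cms = None
    dil = config.mask_dilation_px
    for f in range(t_n):
        cm2d = {cid: segs[cid][f].body_cm_2d for cid in segs
                if np.all(np.isfinite(segs[cid][f].body_cm_2d))}
        try:
            new_grid, cm3d = hl.build_voxel_grid(
                cm2d, rig, wing_length=nominal_lw,
                extent_in_wing_lengths=config.extent_in_wing_lengths,
                pitch=config.pitch,
            )
        except ValueError:
            frame_flags[f].add("no_body_cm")
            wing_hulls[+1].append(None)
            wing_hulls[-1].append(None)
            body_axes.append(np.full(3, np.nan))
            body_cms.append(np.full(3, np.nan))
            continue
        if grid is None or new_grid != grid:
            grid = new_grid
            carver = hl.HullCarver(grid, rig)
        full = {cid: segs[cid][f].full_mask for cid in segs}
        body = {cid: segs[cid][f].body_mask for cid in segs}
        wing = {cid: segs[cid][f].wing_mask for cid in segs}
        if dil > 0:
            from scipy.ndimage import binary_dilation

            full = {c: binary_dilation(m, iterations=dil) for c, m in full.items()}
            body = {c: binary_dilation(m, iterations=dil) for c, m in body.items()}
            wing = {c: binary_dilation(m, iterations=dil) for c, m in wing.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = hl.reconstruct_frame(carver, full, body, wing)
        if len(bundle.body) == 0 or len(bundle.two_wings) == 0:
            frame_flags[f].add("empty_hull")
            wing_hulls[+1].append(None)
            wing_hulls[-1].append(None)
            body_axes.append(prev_xb if prev_xb is not None else np.full(3, np.nan))
            body_cms.append(np.full(3, np.nan))
            continue
        rb, xb, _, _ = wg.head_tail_refine(
            bundle.body, prev_x_b=prev_xb,
            flight_direction=np.asarray(config.initial_flight_direction),
        )
        if f % 10 == 0:
            pts = bundle.body.points
            body_eigs.append(np.sort(np.linalg.eigvalsh(
                np.cov((pts - pts.mean(0)).T))))
        # provisional lateral axis for the first wing split (upright fly)
        if prev_cms is None:
            zlab = np.array([0.0, 0.0, 1.0])
            y_prov = np.cross(zlab, xb)
            if np.linalg.norm(y_prov) < 1e-6:
                y_prov = np.array([0.0, 1.0, 0.0])
            y_prov = unit(y_prov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                left, right, merged = hl.split_wings(
                    bundle.two_wings,
                    prev_wing_cms=prev_cms,
                    body_y_axis=None if prev_cms is not None else y_prov,
                    body_cm=rb,
                    seed=config.seed,
                )
                bundle.wing_left, bundle.wing_right = left, right
                bundle.wings_merged_3d = merged
                if merged:
                    frame_flags[f].add("wings_merged_3d")
                prev_cms = (left.centroid(), right.centroid())
            except ValueError:
                frame_flags[f].add("wing_split_failed")
        wing_hulls[+1].append(bundle.wing_left)
        wing_hulls[-1].append(bundle.wing_right)
        body_axes.append(xb)
        body_cms.append(rb)
        prev_xb = xb
        del bundle

    body_axes = np.asarray(body_axes)
    body_cms = np.asarray(body_cms)

    # hull-anisotropy correction of the body axis (see RunConfig)
    if config.axis_bias_correction and carver is not None and body_eigs:
        # reference-spheroid semi-axes from the hull PCA spectrum of a
        # uniform ellipsoid (variance along a principal axis = a^2 / 5)
        eig = np.median(np.asarray(body_eigs), axis=0)
        semi = np.sqrt(5.0 * eig)[::-1]  # (a, b, c), a = long axis
        semi = (float(semi[0]), float(np.mean(semi[1:])),
                float(np.mean(semi[1:])))
        good = np.flatnonzero(np.all(np.isfinite(body_axes), axis=1))
        samples = good[:: max(1, config.axis_bias_stride)]
        if good.size and samples.size:
            if samples[-1] != good[-1]:
                samples = np.append(samples, good[-1])
            bias_at = {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for f in samples:
                    bias_at[f] = wg.body_axis_carve_bias(
                        carver, body_axes[f], semi)
            sf = np.asarray(sorted(bias_at))
            bv = np.asarray([bias_at[f] for f in sf])
            for k in range(3):
                comp = np.interp(np.arange(t_n, dtype=float), sf, bv[:, k])
                body_axes[good, k] -= comp[good]
            body_axes[good] = body_axes[good] / np.linalg.norm(
                body_axes[good], axis=1, keepdims=True)

    # --- wing length (97.5th percentile of tip distances, first 2 beats)
    if config.wing_length is not None:
        wing_length = config.wing_length
    else:
        dists = []
        for f in range(min(t_n, 2 * fpw)):
            for side in (+1, -1):
                hull = wing_hulls[side][f]
                if hull is not None and len(hull):
                    d = np.linalg.norm(hull.points - body_cms[f], axis=1)
                    dists.append(d.max())
        if not dists:
            raise RuntimeError("could not estimate the wing length")
        wing_length = float(np.percentile(dists, 97.5))

    # --- per-wing ladder ------------------------------------------------
    wing_states: dict[int, list[wg.WingState]] = {+1: [], -1: []}
    prev_state = {+1: None, -1: None}
    prev_tips = {+1: [], -1: []}  # recent tip positions for velocity
    max_speed = {+1: 0.0, -1: 0.0}
    for f in range(t_n):
        for side in (+1, -1):
            hull = wing_hulls[side][f]
            if hull is None or len(hull) == 0 or np.any(~np.isfinite(body_cms[f])):
                wing_states[side].append(None)
                frame_flags[f].add("wing_L_missing" if side > 0 else
                                   "wing_R_missing")
                continue
            # tip velocity from the last two tips, held (None) near stroke
            # reversal (speed < 10% of the running maximum)
            tip_v = None
            tips = prev_tips[side]
            if len(tips) >= 2:
                v = tips[-1] - tips[-2]
                speed = float(np.linalg.norm(v))
                if speed >= 0.1 * max(max_speed[side], 1e-12):
                    tip_v = v
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    prev_chord = (
                        prev_state[side].chord
                        if prev_state[side] is not None
                        and np.all(np.isfinite(prev_state[side].chord))
                        else None
                    )
                    state = wg.analyze_wing(
                        hull, side, body_cms[f], wing_length, rig, carver,
                        chord_frame=None,
                        tip_velocity=tip_v,
                        prev=prev_state[side],
                        n_sections=config.n_sections,
                        seed=config.seed,
                        chord_init=prev_chord,
                    )
                except ValueError:
                    wing_states[side].append(None)
                    frame_flags[f].add("wing_unresolvable")
                    continue
            state._tip_velocity = tip_v  # type: ignore[attr-defined]
            if np.all(np.isfinite(state.tip)):
                if prev_tips[side]:
                    speed = float(np.linalg.norm(state.tip - prev_tips[side][-1]))
                    max_speed[side] = max(max_speed[side], speed)
                prev_tips[side] = (prev_tips[side] + [state.tip])[-2:]
            wing_states[side].append(state)
            prev_state[side] = state

    # chord orientation: enforce temporal continuity within segments, then
    # set each segment's absolute sign by a speed-weighted majority vote of
    # the frames where the tip velocity clearly indicates the leading edge
    # (LE leads, c . v > 0).  Per-frame velocity flips are unreliable near
    # stroke reversal, where tip motion is pitch-dominated.
    for side in (+1, -1):
        _orient_chords(wing_states[side])

    # objective per-frame quality flags (computed without ground truth):
    # a chord rotating faster than any physiological pitch rate, or a wing
    # hull whose size departs grossly from the event median, marks a frame
    # whose wing estimates are untrustworthy (typically wing-wing
    # contamination near stroke reversal)
    for side, tag in ((+1, "L"), (-1, "R")):
        states = wing_states[side]
        sizes = np.array([len(st.hull) if st is not None and st.hull is not None
                          else 0 for st in states], dtype=float)
        med = np.median(sizes[sizes > 0]) if np.any(sizes > 0) else 0.0
        prev_c = None
        for f, st in enumerate(states):
            if st is None:
                continue
            if med > 0 and sizes[f] > 0 and not (
                    0.3 * med <= sizes[f] <= 1.8 * med):
                # the two wing hulls are one partition of the combined
                # hull; an anomalous half means the partition itself broke
                frame_flags[f].add("hull_anomalous_L")
                frame_flags[f].add("hull_anomalous_R")
            if np.all(np.isfinite(st.chord)):
                if prev_c is not None:
                    rot = np.rad2deg(np.arccos(
                        np.clip(float(st.chord @ prev_c), -1.0, 1.0)))
                    if rot > 30.0:
                        frame_flags[f].add(f"chord_jump_{tag}")
                        if f > 0:
                            frame_flags[f - 1].add(f"chord_jump_{tag}")
                prev_c = st.chord
        # a slip excursion is bounded by two jump events a few frames
        # apart; the short interval between them is equally suspect
        jumps = sorted(f for f in range(t_n)
                       if f"chord_jump_{tag}" in frame_flags[f])
        for a, b in zip(jumps[:-1], jumps[1:]):
            if b - a <= max(4, fpw // 8):
                for f in range(a + 1, b):
                    frame_flags[f].add(f"chord_jump_{tag}")

    # --- kinematics ------------------------------------------------------
    times = np.arange(t_n, dtype=float)  # frame units; dt set by caller
    spans = {}
    chords = {}
    for side in (+1, -1):
        s_arr = np.full((t_n, 3), np.nan)
        c_arr = np.full((t_n, 3), np.nan)
        for f, st in enumerate(wing_states[side]):
            if st is None:
                continue
            if np.all(np.isfinite(st.span)):
                s_arr[f] = st.span
            if np.all(np.isfinite(st.chord)):
                c_arr[f] = st.chord
        spans[side] = s_arr
        chords[side] = c_arr

    # the lateral axis must not be built from frames whose wing partition
    # broke
    yb_valid = np.array(
        [not ({"hull_anomalous_L", "hull_anomalous_R", "wings_merged_3d"}
              & frame_flags[f]) for f in range(t_n)]
    )
    y_b, yb_info = kin.estimate_yb(
        times, body_axes, spans[+1], spans[-1], valid=yb_valid,
        return_info=True,
    )
    # outside the sampled back-stroke range y_b is held constant: body
    # roll is structurally unresolved there
    st0, st1 = yb_info["sample_times"][0], yb_info["sample_times"][-1]
    for f in range(t_n):
        if times[f] < st0 or times[f] > st1:
            frame_flags[f].add("yb_extrapolated")
    table = kin.assemble_kinematics(
        times, body_cms, body_axes, spans, chords, flags=frame_flags,
        y_b=y_b,
    )
    psi_cols: dict[str, np.ndarray] = {}
    for side, tag in ((+1, "L"), (-1, "R")):
        per_frame = []
        for f, st in enumerate(wing_states[side]):
            if st is None or not st.local_chords:
                per_frame.append([])
                continue
            n_sp = stroke_plane_normal(body_axes[f], y_b[f])
            try:
                c0, w = chord_reference_frame(st.span, n_sp, side)
            except ValueError:
                per_frame.append([])
                continue
            per_frame.append(
                [(stn, ch, float(np.rad2deg(np.arctan2(ch @ w, ch @ c0))))
                 for stn, ch, _ in st.local_chords]
            )
        n_sec = config.n_sections
        for k_sec in range(n_sec):
            col = np.full(t_n, np.nan)
            for f, lst in enumerate(per_frame):
                if k_sec < len(lst):
                    col[f] = lst[k_sec][2]
            psi_cols[f"psi{k_sec + 1}_{tag}"] = col
        for f, lst in enumerate(per_frame):
            if wing_states[side][f] is not None and lst:
                wing_states[side][f].local_chords = lst
    for col, v in psi_cols.items():
        table[col] = v

    summaries = kin.wingbeat_summaries(table)
    # yb_extrapolated is informational (it limits only roll); it does not
    # count toward run failure
    flagged = sum(1 for fl in frame_flags if fl - {"yb_extrapolated"})
    failed = flagged > t_n // 2
    if failed:
        warnings.warn(f"{flagged}/{t_n} frames flagged: run marked failed")
    return EventResult(
        table=table,
        summaries=summaries,
        wing_states=wing_states,
        body_cm=body_cms,
        x_b=body_axes,
        flagged_frames=flagged,
        failed=failed,
    )


def _orient_chords(
    states: list,
    speed_frac: float = 0.3, min_align: float = 0.5,
) -> None:
    """Resolve the global 180-deg sign ambiguity of a chord time series.

    The chord direction estimate is sign-ambiguous per frame.  Frames whose
    consecutive chords are clearly parallel or antiparallel form
    continuity segments; within a segment signs follow the dot-product
    chain.  Each segment's absolute sign then comes from a weighted vote
    of its frames where the wing translates fast enough for the leading
    edge to lead unambiguously (speed >= ``speed_frac`` of a robust speed
    scale — the 90th percentile, since a single tip-tracking glitch can
    make the raw maximum arbitrarily large — and |c . v| >= ``min_align``);
    segments without such frames inherit the sign of the nearest decided
    segment.  Mutates the states.
    """
    idx = [k for k, st in enumerate(states)
           if st is not None and np.all(np.isfinite(st.chord))]
    if not idx:
        return
    # continuity chain and segment boundaries; a rotation beyond what wing
    # pitching can do in one frame (~35 deg) breaks the chain, so a
    # gradual 180-deg estimation walk cannot silently tie the two sides of
    # the event to one sign
    cont = np.cos(np.deg2rad(35.0))
    rel_sign = np.ones(len(idx))
    seg_id = np.zeros(len(idx), dtype=int)
    for j in range(1, len(idx)):
        d = float(states[idx[j]].chord @ states[idx[j - 1]].chord)
        if abs(d) >= cont:
            seg_id[j] = seg_id[j - 1]
            rel_sign[j] = rel_sign[j - 1] * np.sign(d)
        else:
            seg_id[j] = seg_id[j - 1] + 1
            rel_sign[j] = 1.0
    speeds = []
    for k in idx:
        v = getattr(states[k], "_tip_velocity", None)
        if v is not None:
            speeds.append(float(np.linalg.norm(v)))
    if not speeds:
        return
    scale = float(np.percentile(speeds, 90))
    seg_sign: dict[int, float] = {}
    for sid in range(seg_id.max() + 1):
        votes = 0.0
        for j in np.flatnonzero(seg_id == sid):
            st = states[idx[j]]
            v = getattr(st, "_tip_velocity", None)
            if v is None:
                continue
            speed = float(np.linalg.norm(v))
            if speed < speed_frac * max(scale, 1e-12):
                continue
            align = float(st.chord @ v) / speed
            if abs(align) < min_align:
                continue
            st.velocity_oriented = True
            votes += min(speed, scale) * align * rel_sign[j]
        seg_sign[sid] = np.sign(votes) if votes != 0 else 0.0
    # segments without votes inherit from the nearest decided neighbor
    decided = [sid for sid, sg in seg_sign.items() if sg != 0]
    if not decided:
        return  # nothing to anchor on; keep raw orientation
    for sid in seg_sign:
        if seg_sign[sid] == 0:
            nearest = min(decided, key=lambda d: abs(d - sid))
            seg_sign[sid] = seg_sign[nearest]
    for j, k in enumerate(idx):
        if rel_sign[j] * seg_sign[seg_id[j]] < 0:
            _flip_chord(states[k])


def _flip_chord(state: wg.WingState) -> None:
    """Reverse a wing state's chord orientation (and dependent vectors)."""
    state.chord = -state.chord
    if state.plane_normal is not None:
        state.plane_normal = -state.plane_normal
    state.local_chords = [
        (stn, -ch, np.nan) for stn, ch, _ in state.local_chords
    ]


# ---------------------------------------------------------------------------
# synthetic validation
# ---------------------------------------------------------------------------

#: study conditions of the reference synthetic-validation experiment: the
#: hybrid rig with the optics sized to the tracking volume, a hovering fly
#: with gentle maneuvering body oscillations (peak rates ~1000 deg/s, the
#: scale of free-flight saccades), default wingbeat kinematics.
VALIDATION_PIXEL_PITCH = 30e-6
VALIDATION_BODY_OSCILLATION = {
    "yaw_amp_deg": 8.0, "yaw_period_beats": 10.0,
    "pitch_mean_deg": 45.0, "pitch_amp_deg": 5.0, "pitch_period_beats": 8.0,
    "roll_amp_deg": 4.0, "roll_period_beats": 12.0,
}


def validation_setup(seed: int = 0):
    """Rig, config and body-trajectory spec of the reference validation.

    Returns ``(rig, config, body_spec)`` for
    :func:`validate_on_synthetic`; kept in one place so tests and scripts
    reproduce identical study conditions.
    """
    from .cameras import make_rig

    rig = make_rig("hybrid4", pixel_pitch=VALIDATION_PIXEL_PITCH)
    config = RunConfig(window=73, pitch=VALIDATION_PIXEL_PITCH, seed=seed)
    o = VALIDATION_BODY_OSCILLATION
    fwb = 220.0  # default wingbeat frequency (Hz)

    body_spec = BodyTrajectorySpec(
        position=(0.0, 0.0, 0.0),
        yaw=lambda t: o["yaw_amp_deg"] * np.sin(
            2 * np.pi * t * fwb / o["yaw_period_beats"]),
        pitch=lambda t: o["pitch_mean_deg"] + o["pitch_amp_deg"] * np.sin(
            2 * np.pi * t * fwb / o["pitch_period_beats"] + 1.0),
        roll=lambda t: o["roll_amp_deg"] * np.sin(
            2 * np.pi * t * fwb / o["roll_period_beats"] + 2.0),
    )
    return rig, config, body_spec

@dataclass
class ValidationReport:
    """Per-angle estimation errors against synthetic ground truth.

    ``errors`` holds estimate-minus-truth series after median-offset
    removal (the offset absorbs convention differences only); ``sds`` their
    standard deviations in degrees.
    """

    errors: dict[str, np.ndarray]
    sds: dict[str, float]
    offsets: dict[str, float]
    n_frames: int
    n_flagged: int
    table: pd.DataFrame
    truth: pd.DataFrame
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def wing_angle_sds(self) -> dict[str, float]:
        return {k: v for k, v in self.sds.items()
                if k.split("_")[0] in ("phi", "theta", "psi")}


def _circ_err(est: np.ndarray, tru: np.ndarray) -> np.ndarray:
    """Angular difference wrapped to (-180, 180]."""
    d = est - tru
    return (d + 180.0) % 360.0 - 180.0


def _remove_circular_offset(err: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the circular median error and re-wrap.

    A convention offset near +/-180 deg (e.g. an opposite chord-sign
    convention) makes wrapped errors straddle the boundary; centering on
    the circular mean direction first keeps the median well defined.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rad = np.deg2rad(err)
        center = np.rad2deg(np.arctan2(np.nanmean(np.sin(rad)),
                                       np.nanmean(np.cos(rad))))
        shifted = (err - center + 180.0) % 360.0 - 180.0
        off = center + float(np.nanmedian(shifted))
    out = (err - off + 180.0) % 360.0 - 180.0
    return out, float(off)


def validate_on_synthetic(
    model: FlyModel | None = None,
    rig: CameraRig | None = None,
    config: RunConfig | None = None,
    body_spec: BodyTrajectorySpec | None = None,
    wing_spec: WingbeatSpec | None = None,
    n_wingbeats: int = 10,
    frames_per_wingbeat: int = 73,
    seed: int = 0,
    use_ground_truth_masks: bool = False,
) -> ValidationReport:
    """Render a known-pose sequence, run the pipeline, report error SDs.

    With ``use_ground_truth_masks`` the renderer's per-part masks bypass
    the motion-based segmentation (ablation of segmentation errors).
    """
    from .cameras import make_rig

    model = model or build_fly_model()
    rig = rig or make_rig("hybrid4")
    config = config or RunConfig(window=frames_per_wingbeat,
                                 wing_length=None, seed=seed)
    sequence = generate_wingbeat_sequence(
        model, body_spec=body_spec, wing_spec=wing_spec,
        n_wingbeats=n_wingbeats, frames_per_wingbeat=frames_per_wingbeat,
        seed=seed,
    )
    stacks, body_stacks = render_stacks(
        model, sequence, rig, with_body_masks=use_ground_truth_masks
    )
    segmentations = None
    if use_ground_truth_masks:
        segmentations = {
            cid: [
                _truth_segmented_frame(stacks[cid][f], body_stacks[cid][f],
                                       cid, f)
                for f in range(len(sequence))
            ]
            for cid in stacks
        }
    result = process_event(stacks, rig, config, segmentations=segmentations)
    truth = sequence.truth_table()
    est = result.table
    flags = est["flags"].fillna("").to_list()
    # frames whose objective quality flags touch an angle are excluded from
    # that angle's error SD (and counted); the flags carry no ground-truth
    # information
    wing_bad = {
        tag: np.array(
            [any(k in fl for k in (
                f"wing_{tag}_missing", f"chord_jump_{tag}",
                f"hull_anomalous_{tag}", f"gimbal_{tag}",
                "wings_merged_3d", "wing_unresolvable", "empty_hull",
            )) for fl in flags]
        )
        for tag in ("L", "R")
    }
    body_bad = np.array(
        [any(k in fl for k in ("empty_hull", "no_body_cm")) for fl in flags]
    )
    # roll additionally requires a resolved lateral axis
    roll_bad = body_bad | np.array(
        ["yb_extrapolated" in fl for fl in flags]
    )
    errors: dict[str, np.ndarray] = {}
    offsets: dict[str, float] = {}
    sds: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for col in ("phi_L", "phi_R", "theta_L", "theta_R", "psi_L", "psi_R",
                "yaw", "pitch", "roll"):
        e = _circ_err(est[col].to_numpy(), truth[col].to_numpy())
        if col[-1] in ("L", "R"):
            bad = wing_bad[col[-1]]
        elif col == "roll":
            bad = roll_bad
        else:
            bad = body_bad
        e = np.where(bad, np.nan, e)
        e, off = _remove_circular_offset(e)
        errors[col] = e
        offsets[col] = off
        sds[col] = float(np.nanstd(e))
        excluded[col] = int(np.sum(bad))
    for base in ("phi", "theta", "psi"):
        both = np.concatenate([errors[f"{base}_L"], errors[f"{base}_R"]])
        sds[base] = float(np.nanstd(both))
    return ValidationReport(
        errors=errors,
        sds=sds,
        offsets=offsets,
        n_frames=len(est),
        n_flagged=result.flagged_frames,
        n_excluded=excluded,
        table=est,
        truth=truth,
    )


def _truth_segmented_frame(
    full: np.ndarray, body: np.ndarray, cid: int, f: int
) -> seg.SegmentedFrame:
    """Ground-truth part masks packaged as a segmentation result."""
    return seg.SegmentedFrame(
        camera_id=cid,
        frame=f,
        full_mask=full,
        body_mask=body,
        wing_mask=full & ~body,
        body_cm_2d=seg.mask_centroid(body),
    )
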