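"""Event-level behavioural analyses on long clips.

Covers four behaviours:

* turning — detected from the smoothed hindbody (anus->chest) heading
  change, categorised per frame into left/right/none and aggregated into
  events with turning angle, duration and angular velocity;
* rearing — annotation-driven; 11 descriptors of the chest vertical
  excursion and its ascending/descending velocities;
* gait — strides between consecutive foot strikes derived from annotated
  swing phases, with a 28-descriptor registry per stride (rearing periods
  are excluded);
* axial bending — the interior angle at the hindlimb midpoint between
  vectors to the nose and the anus, with sustained low-angle episodes cut
  into 60-frame clips; and hind-foot placement densities in the anus-origin
  body frame (foot trailing = positions behind the anus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import interior_angle
from .pose import EventAnnotation, NodeId, PoseSequence, body_frame_xy
from .segmentation import node_speed

__all__ = [
    "TurningEvent",
    "Stride",
    "BendingClip",
    "detect_turning",
    "rearing_features",
    "REARING_FEATURES",
    "detect_strides",
    "gait_features",
    "gait_feature_table",
    "GAIT_FEATURES",
    "axial_bending_angle",
    "axial_bending_clips",
    "feet_placement_stats",
]

TURN_RATE_THRESHOLD = 0.5   # deg/frame on the smoothed heading rate
TURN_MIN_FRAMES = 5
BEND_ANGLE_THRESHOLD = 75.0  # deg
BEND_WINDOW = 60
BEND_FRACTION = 0.7
DRAG_HEIGHT_CM = 0.2


@dataclass(frozen=True)
class TurningEvent:
    start_frame: int
    end_frame: int
    direction: int            # +1 left, -1 right
    turning_angle: float      # deg, max cumulative heading change
    turning_duration: float   # s, onset to peak
    turning_velocity: float   # deg/s


@dataclass(frozen=True)
class Stride:
    foot: NodeId
    start_frame: int          # foot strike opening the stride
    end_frame: int            # next strike of the same foot
    swing_start: int
    swing_end: int            # == end_frame (strike = swing end)

    @property
    def stance(self) -> tuple[int, int]:
        return (self.start_frame, self.swing_start)


@dataclass(frozen=True)
class BendingClip:
    start_frame: int
    end_frame: int
    mean_angle: float         # deg


def _heading_deg(seq: PoseSequence) -> np.ndarray:
    """Hindbody heading: direction angle of the anus->chest xy vector, deg
    in (-180, 180]; degenerate frames are NaN."""
    d = seq.node(NodeId.chest)[:, :2] - seq.node(NodeId.anus)[:, :2]
    norm = np.hypot(d[:, 0], d[:, 1])
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang[norm < 1e-6] = np.nan
    return ang


def _wrap180(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def detect_turning(seq: PoseSequence,
                   rate_threshold: float = TURN_RATE_THRESHOLD,
                   min_frames: int = TURN_MIN_FRAMES) -> list[TurningEvent]:
    """Detect turning events from the hindbody heading.

    Heading change is taken at a lag of two frames, wrapped to (-180, 180];
    abrupt changes (>= 90 deg) are zeroed, a 5-frame trailing rolling mean
    smooths the rest, and frames whose smoothed rate exceeds 0.5 deg/frame
    are categorised by sign (+1 left / counterclockwise). Maximal
    same-category runs of at least 5 frames become events.
    """
    if seq.n_frames < 7:
        raise ValueError("need at least 7 frames for turning analysis")
    heading = _heading_deg(seq)
    n = seq.n_frames
    dh = np.full(n, 0.0)
    dh[2:] = _wrap180(heading[2:] - heading[:-2])
    dh[np.isnan(dh)] = 0.0
    dh[np.abs(dh) >= 90.0] = 0.0
    smoothed = pd.Series(dh).rolling(5, min_periods=1).mean().to_numpy()
    rate = smoothed / 2.0  # lag-2 difference -> per-frame rate
    cat = np.where(np.abs(rate) > rate_threshold, np.sign(rate), 0.0)

    # continuous heading for angle integration within events
    steps = np.concatenate(([0.0], _wrap180(np.diff(heading))))
    steps[np.isnan(steps)] = 0.0
    cum = np.cumsum(steps)

    events = []
    i = 0
    while i < n:
        if cat[i] == 0:
            i += 1
            continue
        j = i
        while j < n and cat[j] == cat[i]:
            j += 1
        if j - i >= min_frames:
            rel = (cum[i:j] - cum[i]) * cat[i]  # progress in the turn direction
            peak = int(np.argmax(rel))
            angle = float(rel[peak])
            if angle > 0 and peak > 0:
                dur = peak / seq.fs
                events.append(TurningEvent(
                    start_frame=i, end_frame=j, direction=int(cat[i]),
                    turning_angle=angle, turning_duration=dur,
                    turning_velocity=angle / dur))
        i = j
    return events


REARING_FEATURES = [
    "up_displacement_cm", "down_displacement_cm", "up_duration_s",
    "down_duration_s", "total_duration_s",
    "up_vz_mean", "up_vz_max", "up_vz_std",
    "down_vz_mean", "down_vz_max", "down_vz_std",
]


def rearing_features(seq: PoseSequence, event: EventAnnotation) -> pd.Series:
    """The 11 rearing descriptors of one annotated event.

    Displacements are chest z differences start->peak and peak->end; the
    ascending/descending velocity statistics use the signed per-interval
    chest vertical velocity (finite differences scaled by fs).
    """
    if event.kind != "rearing":
        raise ValueError("annotation must be a rearing event")
    s, p, e = event.start_frame, event.peak_frame, event.end_frame
    if not 0 <= s <= p <= e < seq.n_frames:
        raise ValueError("rearing event outside the session")
    z = seq.node(NodeId.chest)[:, 2]
    fs = seq.fs

    def phase_stats(a, b):
        if b <= a:
            return 0.0, 0.0, 0.0
        vz = np.diff(z[a:b + 1]) * fs
        sd = float(np.std(vz, ddof=1)) if vz.size > 1 else 0.0
        return float(vz.mean()), float(vz.max()), sd

    um, ux, us = phase_stats(s, p)
    dm, dx, ds = phase_stats(p, e)
    return pd.Series({
        "up_displacement_cm": float(z[p] - z[s]),
        "down_displacement_cm": float(z[p] - z[e]),
        "up_duration_s": (p - s) / fs,
        "down_duration_s": (e - p) / fs,
        "total_duration_s": (e - s) / fs,
        "up_vz_mean": um, "up_vz_max": ux, "up_vz_std": us,
        "down_vz_mean": dm, "down_vz_max": dx, "down_vz_std": ds,
    }, index=REARING_FEATURES)


def detect_strides(events: list[EventAnnotation],
                   rearing: list[EventAnnotation] | None = None) -> list[Stride]:
    """Build strides from annotated swing phases.

    A foot strike is a swing end; a stride spans consecutive strikes of the
    same foot and carries the swing ending the stride. Strides overlapping a
    rearing annotation are removed.
    """
    rearing = [ev for ev in (rearing or []) if ev.kind == "rearing"]
    by_foot: dict[NodeId, list[EventAnnotation]] = {}
    for ev in events:
        if ev.kind == "swing":
            by_foot.setdefault(ev.foot, []).append(ev)
    strides = []
    for foot, swings in by_foot.items():
        swings = sorted(swings, key=lambda ev: ev.start_frame)
        for prev, cur in zip(swings, swings[1:]):
            st = Stride(foot=foot, start_frame=prev.end_frame,
                        end_frame=cur.end_frame, swing_start=cur.start_frame,
                        swing_end=cur.end_frame)
            if any(r.start_frame < st.end_frame and st.start_frame < r.end_frame
                   for r in rearing):
                continue
            strides.append(st)
    strides.sort(key=lambda st: (st.start_frame, st.foot))
    return strides


GAIT_FEATURES = [
    "stride_duration_s", "swing_duration_s", "stance_duration_s",
    "duty_factor", "cadence_hz", "stride_length_cm", "swing_peak_speed",
    "swing_mean_speed", "step_height_cm", "toe_off_speed", "strike_speed",
    "foot_vz_std", "feet_dist_mean", "feet_dist_max", "feet_dist_std",
    "stance_width_mean", "leg_angle_range", "leg_angle_std",
    "contralateral_leg_corr", "phase_lag", "foot_behind_anus_frac",
    "drag_duration_s", "body_speed_mean", "body_speed_std",
    "body_length_mean", "body_angle_mean", "straightness", "regularity",
]

_CONTRA = {NodeId.r_foot: NodeId.l_foot, NodeId.l_foot: NodeId.r_foot,
           NodeId.r_hand: NodeId.l_hand, NodeId.l_hand: NodeId.r_hand}


def gait_features(stride: Stride, seq: PoseSequence,
                  all_strides: list[Stride] | None = None) -> pd.Series:
    """The 28-descriptor gait registry for one stride."""
    fs = seq.fs
    s, e = stride.start_frame, min(stride.end_frame, seq.n_frames)
    ss, se = stride.swing_start, min(stride.swing_end, seq.n_frames)
    dur = (stride.end_frame - stride.start_frame) / fs
    swing = (stride.swing_end - stride.swing_start) / fs
    stance = (stride.swing_start - stride.start_frame) / fs

    foot_xy = seq.node(stride.foot)[:, :2]
    foot_z = seq.node(stride.foot)[:, 2]
    speed = node_speed(seq, stride.foot, "3D")
    vz = np.concatenate(([0.0], np.diff(foot_z))) * fs

    last = min(stride.end_frame, seq.n_frames - 1)
    length = float(np.linalg.norm(foot_xy[last] - foot_xy[s]))

    contra = _CONTRA[stride.foot]
    feet_d = np.linalg.norm(foot_xy[s:e] - seq.node(contra)[s:e, :2], axis=1)

    bf_self = body_frame_xy(seq, foot_xy)[s:e]
    bf_contra = body_frame_xy(seq, seq.node(contra)[:, :2])[s:e]
    width = np.abs(bf_self[:, 1] - bf_contra[:, 1])

    side = "r" if stride.foot in (NodeId.r_foot, NodeId.r_hand) else "l"
    leg = interior_angle(seq.node(NodeId.chest), seq.node(NodeId.anus),
                         seq.node(NodeId.r_foot if side == "r" else NodeId.l_foot))
    leg_c = interior_angle(seq.node(NodeId.chest), seq.node(NodeId.anus),
                           seq.node(NodeId.l_foot if side == "r" else NodeId.r_foot))
    li, lc = leg[s:e], leg_c[s:e]
    ok = np.isfinite(li) & np.isfinite(lc)
    if ok.sum() >= 3 and np.std(li[ok]) > 0 and np.std(lc[ok]) > 0:
        corr = float(np.corrcoef(li[ok], lc[ok])[0, 1])
    else:
        corr = 0.0

    # phase lag: first strike of the contralateral foot within this stride
    lag = 0.5
    if all_strides:
        contra_strikes = [st.end_frame for st in all_strides
                          if st.foot == contra
                          and stride.start_frame <= st.end_frame < stride.end_frame]
        if contra_strikes and dur > 0:
            lag = (contra_strikes[0] - stride.start_frame) / fs / dur

    chest_sp = node_speed(seq, NodeId.chest, "2D")[s:e]
    chest_xy = seq.node(NodeId.chest)[s:e, :2]
    path = float(np.sum(np.linalg.norm(np.diff(chest_xy, axis=0), axis=1)))
    net = float(np.linalg.norm(chest_xy[-1] - chest_xy[0])) if e > s else 0.0

    body_len = np.linalg.norm(
        seq.node(NodeId.neck)[s:e, :2] - seq.node(NodeId.anus)[s:e, :2], axis=1)
    body_ang = interior_angle(seq.node(NodeId.neck), seq.node(NodeId.chest),
                              seq.node(NodeId.anus))[s:e]

    regularity = 0.0
    if all_strides:
        durs = np.array([st.end_frame - st.start_frame
                         for st in all_strides if st.foot == stride.foot], float)
        if durs.size >= 3 and durs.std() > 0:
            regularity = float(np.corrcoef(durs[:-1], durs[1:])[0, 1])

    swing_speed = speed[ss:se]
    return pd.Series({
        "stride_duration_s": dur,
        "swing_duration_s": swing,
        "stance_duration_s": stance,
        "duty_factor": stance / dur if dur > 0 else 0.0,
        "cadence_hz": 1.0 / dur if dur > 0 else 0.0,
        "stride_length_cm": length,
        "swing_peak_speed": float(swing_speed.max()) if swing_speed.size else 0.0,
        "swing_mean_speed": float(swing_speed.mean()) if swing_speed.size else 0.0,
        "step_height_cm": float(foot_z[ss:se].max()) if se > ss else 0.0,
        "toe_off_speed": float(speed[ss]) if ss < seq.n_frames else 0.0,
        "strike_speed": float(speed[min(se, seq.n_frames - 1)]),
        "foot_vz_std": float(np.std(vz[s:e], ddof=1)) if e - s > 1 else 0.0,
        "feet_dist_mean": float(np.mean(feet_d)),
        "feet_dist_max": float(np.max(feet_d)),
        "feet_dist_std": float(np.std(feet_d, ddof=1)) if feet_d.size > 1 else 0.0,
        "stance_width_mean": float(np.nanmean(width)),
        "leg_angle_range": float(np.nanmax(li) - np.nanmin(li)),
        "leg_angle_std": float(np.nanstd(li, ddof=1)),
        "contralateral_leg_corr": corr,
        "phase_lag": float(lag),
        "foot_behind_anus_frac": float(np.nanmean(bf_self[:, 0] < 0)),
        "drag_duration_s": float(np.sum(foot_z[ss:se] < DRAG_HEIGHT_CM)) / fs,
        "body_speed_mean": float(chest_sp.mean()),
        "body_speed_std": float(np.std(chest_sp, ddof=1)) if chest_sp.size > 1 else 0.0,
        "body_length_mean": float(body_len.mean()),
        "body_angle_mean": float(np.nanmean(body_ang)),
        "straightness": net / path if path > 0 else 0.0,
        "regularity": regularity,
    }, index=GAIT_FEATURES)


def gait_feature_table(seq: PoseSequence,
                       events: list[EventAnnotation]) -> pd.DataFrame:
    """Per-stride gait feature table for one session (hind feet).

    Swing annotations define strides; rearing annotations exclude strides.
    """
    rearing = [ev for ev in events if ev.kind == "rearing"]
    feet_events = [ev for ev in events if ev.kind == "swing"
                   and ev.foot in (NodeId.r_foot, NodeId.l_foot)]
    strides = detect_strides(feet_events, rearing)
    rows = []
    for st in strides:
        if st.end_frame > seq.n_frames:
            continue
        rec = gait_features(st, seq, strides).to_dict()
        rec.update(mouse_id=seq.mouse_id, group=seq.group, week=seq.week,
                   foot=st.foot.name, start_frame=st.start_frame,
                   end_frame=st.end_frame)
        rows.append(rec)
    meta = ["mouse_id", "group", "week", "foot", "start_frame", "end_frame"]
    return pd.DataFrame(rows, columns=meta + GAIT_FEATURES)


def axial_bending_angle(seq: PoseSequence) -> np.ndarray:
    """Per-frame axial bending angle theta (deg, in [0, 180]).

    The interior angle at the hindlimb midpoint (xy) between the vectors to
    the nose and to the anus; degenerate frames are NaN.
    """
    mid = 0.5 * (seq.node(NodeId.r_foot)[:, :2] + seq.node(NodeId.l_foot)[:, :2])
    nose = seq.node(NodeId.nose)[:, :2]
    anus = seq.node(NodeId.anus)[:, :2]
    return interior_angle(nose, mid, anus)


def axial_bending_clips(seq: PoseSequence,
                        threshold: float = BEND_ANGLE_THRESHOLD,
                        window: int = BEND_WINDOW,
                        frac: float = BEND_FRACTION) -> list[BendingClip]:
    """Sustained low-angle (dystonia-like) bending clips.

    Frames with theta < 75 deg are flagged; a 60-frame trailing rolling mean
    >= 0.7 marks a bending period, whose start is extended 60 frames
    backward; periods are cut into consecutive 60-frame clips carrying the
    mean angle.
    """
    theta = axial_bending_angle(seq)
    flag = (theta < threshold).astype(float)
    flag[np.isnan(theta)] = 0.0
    roll = pd.Series(flag).rolling(window).mean().to_numpy()
    qual = np.flatnonzero(roll >= frac)
    clips = []
    if qual.size == 0:
        return clips
    brk = np.flatnonzero(np.diff(qual) > 1)
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [qual.size - 1]))
    for a, b in zip(starts, ends):
        span_s = max(0, int(qual[a]) - window)
        span_e = int(qual[b]) + 1
        for s in range(span_s, span_e - window + 1, window):
            seg = theta[s:s + window]
            clips.append(BendingClip(start_frame=s, end_frame=s + window,
                                     mean_angle=float(np.nanmean(seg))))
    return clips


def feet_placement_stats(seq: PoseSequence, frames: np.ndarray | None = None,
                         bins: int = 40, extent: float = 4.0):
    """Hind-feet xy densities in the anus-origin body frame.

    Returns ``(grid, xedges, yedges, behind_pct)`` where ``behind_pct`` is
    the percentage of foot positions with body-frame x < 0 (feet behind the
    anus, the foot-trailing signature).
    """
    pts = []
    for foot in (NodeId.r_foot, NodeId.l_foot):
        bf = body_frame_xy(seq, seq.node(foot)[:, :2])
        if frames is not None:
            bf = bf[frames]
        pts.append(bf)
    xy = np.concatenate(pts, axis=0)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if xy.size == 0:
        raise ValueError("no valid foot positions")
    edges = np.linspace(-extent, extent, bins + 1)
    grid, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=(edges, edges))
    behind_pct = 100.0 * float(np.mean(xy[:, 0] < 0))
    return grid, xe, ye, behind_pct
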