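"""Generative simulator of control-like and PD-like mouse open-field sessions.

The generator plants every phenotype the downstream pipeline measures:
movement-bout structure, a smoothed random-walk locomotion path, quadrupedal
stride oscillators with left-right anti-phase limbs, a chest vertical
oscillation band whose dominant frequency is the tremor phenotype, rearing
bouts with vertical chest excursions, posture geometry (body length / body
angle), hand-distance and stance-width distributions, and hind-foot
trailing. Every session comes with ground truth: true movement-bout
intervals, rearing annotations and per-foot swing phases defined directly by
the oscillator phase, so segmentation and stride detection have exact
oracles.

Presets pin the published phenotype anchors: control hands-distance ~2.5 cm
and chest oscillation 2.8 Hz; severe PD hands-distance ~1.1 cm, wider stance
(4.2 cm), longer body (5.0 cm), 6.0 Hz chest oscillation and a 0.3
per-stride foot-trailing probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .pose import EventAnnotation, NodeId, PoseSequence

__all__ = [
    "PhenotypeParams",
    "GroundTruth",
    "GroupSpec",
    "CohortSpec",
    "preset",
    "interpolate_params",
    "generate_session",
    "generate_cohort",
]

REAR_HEIGHT_CM = 3.0   # chest vertical excursion of a rearing event
REST_OSC_AMP = 0.01    # residual chest oscillation amplitude at rest, cm


@dataclass(frozen=True)
class PhenotypeParams:
    """Phenotype parameters of one simulated group.

    Rates are per minute, durations/intervals in seconds, lengths in cm,
    speeds in cm/s, angles in degrees, frequencies in Hz.
    """

    bout_rate: float = 3.0                # movement episodes / min (0 disables)
    bout_duration_mean: float = 10.0
    bout_duration_sd: float = 3.0
    rest_interval_mean: float = 45.0
    rest_interval_sd: float = 15.0
    locomotion_speed_mean: float = 8.0
    locomotion_speed_sd: float = 2.0
    hand_distance_mean: float = 2.5
    hand_distance_sd: float = 0.4
    stance_width_mean: float = 2.8
    stance_width_sd: float = 0.4
    body_length_mean: float = 4.2
    body_length_sd: float = 0.3
    body_angle_mean: float = 150.0
    body_angle_sd: float = 8.0
    chest_osc_freq: float = 2.8
    chest_osc_amp: float = 0.15
    rearing_rate: float = 1.5             # events / min
    rearing_peak_vz: float = 8.0          # peak chest vertical speed in rearing
    limb_phase_jitter: float = 0.2        # radians
    foot_trail_prob: float = 0.0          # per-stride trailing probability
    tail_persistence: float = 0.6         # lag-1 autocorrelation of tail wiggle

    def validate(self, fs: float = 30.0) -> None:
        for name in ("bout_duration_sd", "rest_interval_sd", "locomotion_speed_sd",
                     "hand_distance_sd", "stance_width_sd", "body_length_sd",
                     "body_angle_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bout_rate < 0 or self.rearing_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.foot_trail_prob <= 1:
            raise ValueError("foot_trail_prob must be in [0, 1]")
        if not 0 <= self.tail_persistence < 1:
            raise ValueError("tail_persistence must be in [0, 1)")
        if not self.chest_osc_freq < fs / 2:
            raise ValueError("chest_osc_freq must be below the Nyquist frequency")


_PRESET_CONTROL = PhenotypeParams()
_PRESET_SEVERE = PhenotypeParams(
    bout_rate=2.5,
    bout_duration_mean=28.0, bout_duration_sd=8.0,
    rest_interval_mean=25.0, rest_interval_sd=8.0,
    locomotion_speed_mean=4.5, locomotion_speed_sd=1.5,
    hand_distance_mean=1.1, hand_distance_sd=0.3,
    stance_width_mean=4.2, stance_width_sd=0.5,
    body_length_mean=5.0, body_length_sd=0.3,
    body_angle_mean=165.0, body_angle_sd=6.0,
    chest_osc_freq=6.0, chest_osc_amp=0.05,
    rearing_rate=0.6, rearing_peak_vz=3.5,
    limb_phase_jitter=0.8, foot_trail_prob=0.3,
    tail_persistence=0.9,
)


def interpolate_params(a: PhenotypeParams, b: PhenotypeParams,
                       frac: float) -> PhenotypeParams:
    """Linear interpolation between two parameter sets (frac=0 -> a)."""
    kw = {
        f.name: (1 - frac) * getattr(a, f.name) + frac * getattr(b, f.name)
        for f in dataclasses.fields(PhenotypeParams)
    }
    return PhenotypeParams(**kw)


def preset(name: str) -> PhenotypeParams:
    """Named phenotype presets: control, pd_mild, pd_severe, treated."""
    presets = {
        "control": _PRESET_CONTROL,
        "pd_severe": _PRESET_SEVERE,
        "pd_mild": interpolate_params(_PRESET_CONTROL, _PRESET_SEVERE, 0.5),
        "treated": interpolate_params(_PRESET_CONTROL, _PRESET_SEVERE, 0.25),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


@dataclass
class GroundTruth:
    """Planted truth for one generated session (frame units, half-open)."""

    episodes: list[tuple[int, int]]
    events: list[EventAnnotation]
    params: PhenotypeParams
    seed: object = None
    group: str = ""


@dataclass(frozen=True)
class GroupSpec:
    label: str
    params: PhenotypeParams
    n_mice: int
    progresses: bool = False  # drift params toward pd_severe across weeks

    def __post_init__(self):
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    weeks: tuple = (0,)
    seed: int = 0
    duration_s: float = 1200.0
    fs: float = 30.0


def _smooth_noise(rng, n, sd, sigma):
    """Gaussian noise low-passed to be frame-to-frame smooth, unit-variance preserved."""
    x = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma, mode="nearest")
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _draw_bouts(rng, params: PhenotypeParams, n_frames: int, fs: float):
    """Alternating rest/move timeline; returns list of (start, end) move bouts."""
    if params.bout_rate <= 0:
        return []
    bouts = []
    t = max(0.0, rng.normal(params.rest_interval_mean / 2,
                            params.rest_interval_sd / 2))
    while True:
        dur = max(6.0, rng.normal(params.bout_duration_mean,
                                  params.bout_duration_sd))
        s, e = int(round(t * fs)), int(round((t + dur) * fs))
        if s >= n_frames - int(2 * fs):
            break
        bouts.append((s, min(e, n_frames)))
        t += dur + max(8.0, rng.normal(params.rest_interval_mean,
                                       params.rest_interval_sd))
    return bouts


def generate_session(params: PhenotypeParams, duration_s: float = 1200.0,
                     fs: float = 30.0, seed=0, *, mouse_id: str = "m0",
                     group: str = "", week: int = 0):
    """Simulate one open-field session.

    Returns ``(PoseSequence, GroundTruth)``. Bit-identical under a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    params.validate(fs)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    bouts = _draw_bouts(rng, params, n, fs)
    move = np.zeros(n)
    for s, e in bouts:
        move[s:e] = 1.0
    env = gaussian_filter1d(move, 3.0, mode="nearest")  # soft bout edges

    # --- locomotion: per-bout speed, smoothed-heading random walk ---
    speed = np.zeros(n)
    stride_freq = np.zeros(n)
    for s, e in bouts:
        v = max(2.0, rng.normal(params.locomotion_speed_mean,
                                params.locomotion_speed_sd))
        speed[s:e] = v
        stride_freq[s:e] = np.clip(v / 4.0, 1.5, 3.5)
    speed = speed * env

    dphi = _smooth_noise(rng, n, 0.012, 8.0) * env  # rad/frame baseline meander
    # injected turn segments so turning events exist in every group
    for s, e in bouts:
        n_turns = rng.poisson(2.0 * (e - s) / fs / 60.0)
        for _ in range(n_turns):
            tl = int(rng.uniform(0.8, 1.6) * fs)
            ts = rng.integers(s, max(s + 1, e - tl))
            rate = rng.choice([-1.0, 1.0]) * np.deg2rad(rng.uniform(2.0, 3.5))
            dphi[ts:ts + tl] += rate
    heading = np.cumsum(dphi)
    ux, uy = np.cos(heading), np.sin(heading)
    cx = np.cumsum(speed * ux) / fs
    cy = np.cumsum(speed * uy) / fs

    # --- posture geometry (slow AR-like processes) ---
    body_len = params.body_length_mean + _smooth_noise(
        rng, n, params.body_length_sd, 30.0)
    body_ang = np.deg2rad(np.clip(
        params.body_angle_mean + _smooth_noise(rng, n, params.body_angle_sd, 30.0),
        90.0, 179.0))

    # --- stride oscillators: trot (diagonal limbs in phase) ---
    psi = np.cumsum(2 * np.pi * stride_freq * env) / fs
    offsets = {NodeId.r_foot: 0.0, NodeId.l_foot: np.pi,
               NodeId.r_hand: np.pi, NodeId.l_hand: 0.0}
    phase = {}
    for node, off in offsets.items():
        jit = _smooth_noise(rng, n, params.limb_phase_jitter, 10.0)
        phase[node] = psi + off + jit

    stride_amp = np.where(stride_freq > 0, speed / (4.0 * np.maximum(stride_freq, 1e-9)), 0.0)

    # per-stride-cycle hind-foot trailing draws
    trail = {}
    for node in (NodeId.r_foot, NodeId.l_foot):
        cyc = np.floor(phase[node] / (2 * np.pi)).astype(int)
        cyc -= cyc.min()
        draws = rng.random(cyc.max() + 1) < params.foot_trail_prob
        trail[node] = draws[cyc] & (move > 0)

    # --- chest vertical oscillation band (tremor) ---
    osc_amp = REST_OSC_AMP + (params.chest_osc_amp - REST_OSC_AMP) * env
    osc = osc_amp * np.sin(2 * np.pi * params.chest_osc_freq * t
                           + rng.uniform(0, 2 * np.pi))

    # --- rearing events ---
    rear_z = np.zeros(n)
    events: list[EventAnnotation] = []
    vz = max(1.0, params.rearing_peak_vz)
    t_up = min(1.2, np.pi * REAR_HEIGHT_CM / (2 * vz))
    f_up, f_dn = int(round(t_up * fs)), int(round(1.3 * t_up * fs))
    n_rear = rng.poisson(params.rearing_rate * duration_s / 60.0)
    taken: list[tuple[int, int]] = []
    for _ in range(n_rear):
        eligible = [(s, e) for s, e in bouts if e - s > f_up + f_dn + 10]
        if not eligible:
            break
        s, e = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(s, e - f_up - f_dn - 1))
        span = (start, start + f_up + f_dn)
        if any(a < span[1] and span[0] < b for a, b in taken):
            continue
        taken.append(span)
        peak = start + f_up
        up = REAR_HEIGHT_CM / 2 * (1 - np.cos(np.pi * np.arange(f_up) / f_up))
        dn = REAR_HEIGHT_CM / 2 * (1 + np.cos(np.pi * np.arange(f_dn + 1) / f_dn))
        prof = np.concatenate([up, dn])  # peak value = height, once
        rear_z[start:start + len(prof)] += prof
        events.append(EventAnnotation("rearing", start_frame=start,
                                      peak_frame=peak, end_frame=peak + f_dn))

    # --- assemble node coordinates ---
    coords = np.zeros((n, 9, 3))
    jitter = np.stack([_smooth_noise(rng, n, 0.015, 4.0)
                       for _ in range(27)], axis=1).reshape(n, 9, 3)

    anus_xy = np.stack([cx, cy], axis=1)
    coords[:, NodeId.anus, 0] = cx
    coords[:, NodeId.anus, 1] = cy
    coords[:, NodeId.anus, 2] = 0.8

    # tremor has a fore-aft component so the oscillation band appears at its
    # true frequency in the 3D speed/acceleration magnitude (a purely
    # vertical oscillation would rectify to twice the frequency there)
    chest_xy = anus_xy + (0.55 * body_len[:, None] + 0.5 * osc[:, None]) \
        * np.stack([ux, uy], axis=1)
    coords[:, NodeId.chest, 0] = chest_xy[:, 0]
    coords[:, NodeId.chest, 1] = chest_xy[:, 1]
    coords[:, NodeId.chest, 2] = 1.2 + osc + rear_z

    # neck: interior angle at chest between chest->neck and chest->anus
    horiz = -np.cos(body_ang)       # along +heading when angle ~180 deg
    vert = np.sin(body_ang)
    neck_xy = chest_xy + 0.45 * body_len[:, None] * horiz[:, None] \
        * np.stack([ux, uy], axis=1)
    coords[:, NodeId.neck, 0] = neck_xy[:, 0]
    coords[:, NodeId.neck, 1] = neck_xy[:, 1]
    coords[:, NodeId.neck, 2] = 1.2 + 0.45 * body_len * vert + 0.5 * (osc + rear_z)

    nose_dir = coords[:, NodeId.neck] - coords[:, NodeId.chest]
    nose_norm = np.linalg.norm(nose_dir, axis=1, keepdims=True)
    nose_dir = nose_dir / np.maximum(nose_norm, 1e-9)
    coords[:, NodeId.nose] = coords[:, NodeId.neck] + 1.0 * nose_dir

    # tail tip: behind the anus with persistent lateral wiggle
    wig = np.empty(n)
    wig[0] = 0.0
    innov = rng.normal(0.0, 0.35, n)
    rho = params.tail_persistence
    for i in range(1, n):
        wig[i] = rho * wig[i - 1] + innov[i]
    lat = np.stack([-uy, ux], axis=1)
    tip_xy = anus_xy - 2.5 * np.stack([ux, uy], axis=1) + wig[:, None] * lat
    coords[:, NodeId.tip, 0] = tip_xy[:, 0]
    coords[:, NodeId.tip, 1] = tip_xy[:, 1]
    coords[:, NodeId.tip, 2] = 0.6 + 0.1 * np.tanh(wig)

    # hands: attached ahead of the chest, anti-phase stride oscillation
    hand_half = np.maximum(
        0.2, params.hand_distance_mean / 2
        + _smooth_noise(rng, n, params.hand_distance_sd / 2, 12.0))
    for node, sign in ((NodeId.r_hand, -1.0), (NodeId.l_hand, 1.0)):
        ph = phase[node]
        fwd = 0.5 - 0.7 * stride_amp * np.cos(ph)
        lift = 0.4 * np.maximum(np.sin(ph), 0.0) * env
        xy = chest_xy + fwd[:, None] * np.stack([ux, uy], axis=1) \
            + sign * hand_half[:, None] * lat
        coords[:, node, 0] = xy[:, 0]
        coords[:, node, 1] = xy[:, 1]
        coords[:, node, 2] = 0.4 + lift + 0.3 * rear_z

    # hind feet: attached near the anus; trailing strides stay flat and behind
    stance_half = np.maximum(
        0.3, params.stance_width_mean / 2
        + _smooth_noise(rng, n, params.stance_width_sd / 2, 12.0))
    swing_truth: dict[NodeId, np.ndarray] = {}
    for node, sign in ((NodeId.r_foot, -1.0), (NodeId.l_foot, 1.0)):
        ph = phase[node]
        tr = trail[node]
        amp = stride_amp * (~tr)
        fwd = 0.3 - amp * np.cos(ph) - 0.8 * tr
        lift = 0.6 * np.maximum(np.sin(ph), 0.0) * env * (~tr)
        xy = anus_xy + fwd[:, None] * np.stack([ux, uy], axis=1) \
            + sign * stance_half[:, None] * lat
        coords[:, node, 0] = xy[:, 0]
        coords[:, node, 1] = xy[:, 1]
        coords[:, node, 2] = 0.15 + lift
        swing_truth[node] = (np.mod(ph, 2 * np.pi) < np.pi) & (move > 0) & (~tr)

    coords += jitter

    # swing-phase annotations from the oscillator phase (exact stride oracle)
    for node in (NodeId.r_foot, NodeId.l_foot, NodeId.r_hand, NodeId.l_hand):
        mask = swing_truth.get(node)
        if mask is None:
            continue
        m = np.concatenate(([0], mask.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(m))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= 3:
                events.append(EventAnnotation("swing", start_frame=int(s),
                                              end_frame=int(e), foot=node))

    events.sort(key=lambda ev: ev.start_frame)
    seq = PoseSequence(coords, fs=fs, mouse_id=mouse_id, group=group, week=week)
    truth = GroundTruth(episodes=list(bouts), events=events, params=params,
                        seed=seed, group=group)
    return seq, truth


def generate_cohort(spec: CohortSpec):
    """Generate per-mouse per-week sessions for every group in the spec.

    Returns a list of ``(PoseSequence, GroundTruth)``. PD-progressing groups
    drift linearly toward the severe preset with week (frac = week/10).
    """
    out = []
    max_week = 10.0
    for gi, grp in enumerate(spec.groups):
        for mi in range(grp.n_mice):
            for week in spec.weeks:
                params = grp.params
                if grp.progresses and week > 0:
                    params = interpolate_params(
                        params, _PRESET_SEVERE, min(1.0, week / max_week))
                seed = np.random.SeedSequence(
                    [int(spec.seed), gi, mi, int(week)])
                seq, truth = generate_session(
                    params, spec.duration_s, spec.fs, seed,
                    mouse_id=f"{grp.label}_{mi}", group=grp.label, week=week)
                out.append((seq, truth))
    return out
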