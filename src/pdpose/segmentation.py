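"""Moving-episode detection and clip fragmentation.

Movement is detected from the chest 3D speed: frames above 1.5 cm/s are
flagged, and any trailing 100-frame window in which more than 80% of frames
are flagged is a Moving window. Maximal unions of overlapping Moving windows
form Episodes, which are cut into fixed-length clips (60 frames = 2 s short
clips, 120 frames = 4 s long clips); remainder frames are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pose import NodeId, PoseSequence

__all__ = [
    "Episode",
    "MotionClip",
    "node_speed",
    "detect_motion_episodes",
    "fragment_clips",
    "episode_temporal_params",
    "segment_session",
    "SPEED_THRESHOLD",
    "WINDOW_FRAMES",
    "WINDOW_FRACTION",
]

SPEED_THRESHOLD = 1.5   # cm/s
WINDOW_FRAMES = 100
WINDOW_FRACTION = 0.8

_SPACE_AXES = {"1D": (2,), "2D": (0, 1), "3D": (0, 1, 2)}


@dataclass(frozen=True)
class Episode:
    """A maximal moving period, frames half-open [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    fs: float
    interval_s: float  # since previous episode end (session start for first)
    ordinal: int       # 1-based position within the session

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fs

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class MotionClip:
    episode_ordinal: int
    clip_index: int
    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def node_speed(seq: PoseSequence, node: NodeId | str, space: str = "3D") -> np.ndarray:
    """Per-frame unsigned speed of a node (cm/s) over the chosen axes.

    Forward difference scaled by fs; the first element duplicates the second
    so the series has one value per frame.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    axes = _SPACE_AXES[space]
    traj = seq.node(node)[:, axes]
    d = np.diff(traj, axis=0)
    sp = np.linalg.norm(d, axis=1) * seq.fs
    return np.concatenate(([sp[0]], sp))


def detect_motion_episodes(speed: np.ndarray, fs: float,
                           threshold: float = SPEED_THRESHOLD,
                           window: int = WINDOW_FRAMES,
                           frac: float = WINDOW_FRACTION) -> list[Episode]:
    """Detect moving episodes from a speed series.

    A trailing window [t, t+window) is Moving when the count of
    above-threshold frames exceeds window*frac; episodes are maximal unions
    of overlapping Moving windows.
    """
    speed = np.asarray(speed, float)
    n = len(speed)
    if n < window:
        warnings.warn("speed series shorter than the rolling window; "
                      "no episodes detected", stacklevel=2)
        return []
    above = (speed > threshold).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(above)))
    counts = csum[window:] - csum[:-window]          # counts[t] for window [t, t+window)
    moving_start = np.flatnonzero(counts > window * frac)
    if moving_start.size == 0:
        return []
    covered = np.zeros(n, bool)
    # windows starting at consecutive qualifying t overlap; mark union
    for s in _runs(moving_start):
        covered[s[0]:s[1] - 1 + window] = True
    episodes = []
    prev_end = 0
    for i, (s, e) in enumerate(_bool_runs(covered)):
        episodes.append(Episode(start_frame=int(s), end_frame=int(e), fs=fs,
                                interval_s=(s - prev_end) / fs, ordinal=i + 1))
        prev_end = e
    return episodes


def _runs(idx: np.ndarray):
    """Split a sorted integer array into maximal consecutive runs [lo, hi+1)."""
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [len(idx) - 1]))
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def _bool_runs(mask: np.ndarray):
    m = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(m))
    return list(zip(edges[::2], edges[1::2]))


def fragment_clips(episode: Episode, clip_len: int = 60) -> list[MotionClip]:
    """Cut an episode into consecutive non-overlapping fixed-length clips.

    Remainder frames at the episode end are dropped; an episode shorter than
    ``clip_len`` yields no clips.
    """
    out = []
    k = episode.n_frames // clip_len
    for i in range(k):
        s = episode.start_frame + i * clip_len
        out.append(MotionClip(episode_ordinal=episode.ordinal, clip_index=i,
                              start_frame=s, end_frame=s + clip_len))
    return out


TEMPORAL_FEATURES = [
    "motion_duration_s", "motion_interval_s", "clip_count", "onset_time_s",
    "chest_path_length_cm", "mean_chest_speed_2d", "rest_ratio",
    "episode_ordinal",
]


def episode_temporal_params(episodes: list[Episode], seq: PoseSequence,
                            clip_len: int = 60) -> pd.DataFrame:
    """Per-episode record of the 8 temporal parameters.

    These are broadcast to every clip of the episode when the feature table
    is assembled. The first episode's interval is the time since session
    start (keeps the feature defined everywhere).
    """
    if not episodes:
        return pd.DataFrame(columns=["episode_ordinal"] + TEMPORAL_FEATURES[:-1])
    sp2d = node_speed(seq, NodeId.chest, "2D")
    rows = []
    for ep in episodes:
        # one speed sample per episode frame; constant speed v over T s -> v*T
        path = float(np.sum(sp2d[ep.start_frame:ep.end_frame])) / seq.fs
        dur = ep.duration_s
        rows.append({
            "motion_duration_s": dur,
            "motion_interval_s": ep.interval_s,
            "clip_count": ep.n_frames // clip_len,
            "onset_time_s": ep.start_frame / seq.fs,
            "chest_path_length_cm": path,
            "mean_chest_speed_2d": path / dur if dur > 0 else 0.0,
            "rest_ratio": ep.interval_s / (ep.interval_s + dur)
            if ep.interval_s + dur > 0 else 0.0,
            "episode_ordinal": ep.ordinal,
        })
    return pd.DataFrame(rows)


def segment_session(seq: PoseSequence, clip_len: int = 60,
                    threshold: float = SPEED_THRESHOLD,
                    window: int = WINDOW_FRAMES,
                    frac: float = WINDOW_FRACTION):
    """Detect episodes from chest 3D speed and fragment into clips.

    Returns ``(episodes, clips)``.
    """
    speed = node_speed(seq, NodeId.chest, "3D")
    episodes = detect_motion_episodes(speed, seq.fs, threshold, window, frac)
    clips = [c for ep in episodes for c in fragment_clips(ep, clip_len)]
    return episodes, clips
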