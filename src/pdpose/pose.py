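"""Data model and I/O for 3D mouse keypoint time series.

A recording session is a :class:`PoseSequence`: the 3D trajectories (cm) of
nine body nodes sampled at a fixed rate (30 Hz by default, ~36000 frames for
a 20-min open-field session). Eight body segments connect anatomically
adjacent nodes; per-frame segment vectors and an anus-origin body frame are
derived here and consumed by every downstream feature module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NodeId",
    "SegmentId",
    "SEGMENT_ENDPOINTS",
    "PoseSequence",
    "EventAnnotation",
    "read_pose",
    "write_pose",
    "read_annotations",
    "write_annotations",
    "segment_vectors",
    "body_frame",
    "coordinate_columns",
]

AXES = ("x", "y", "z")
MAX_GAP_FRAMES = 5  # longest NaN run repaired by linear interpolation


class NodeId(enum.IntEnum):
    """The nine tracked body nodes, in pinned order."""

    nose = 0
    neck = 1
    chest = 2
    r_hand = 3
    l_hand = 4
    r_foot = 5
    l_foot = 6
    anus = 7
    tip = 8


class SegmentId(enum.IntEnum):
    """The eight body segments (action skeletons)."""

    head = 0
    f_body = 1
    h_body = 2
    tail = 3
    r_arm = 4
    l_arm = 5
    r_leg = 6
    l_leg = 7


# start node -> end node; segment vector = end - start
SEGMENT_ENDPOINTS: dict[SegmentId, tuple[NodeId, NodeId]] = {
    SegmentId.head: (NodeId.nose, NodeId.neck),
    SegmentId.f_body: (NodeId.neck, NodeId.chest),
    SegmentId.h_body: (NodeId.chest, NodeId.anus),
    SegmentId.tail: (NodeId.anus, NodeId.tip),
    SegmentId.r_arm: (NodeId.chest, NodeId.r_hand),
    SegmentId.l_arm: (NodeId.chest, NodeId.l_hand),
    SegmentId.r_leg: (NodeId.anus, NodeId.r_foot),
    SegmentId.l_leg: (NodeId.anus, NodeId.l_foot),
}


def coordinate_columns() -> list[str]:
    """The 27 pose coordinate column names, ``<node>_<axis>`` in pinned order."""
    return [f"{n.name}_{a}" for n in NodeId for a in AXES]


@dataclass
class PoseSequence:
    """One session of 3D keypoint trajectories.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, 9, 3)
        Node coordinates in cm; axis order x, y, z (z vertical).
    fs : float
        Sampling rate in Hz.
    mouse_id, group : str
        Animal identifier and experimental group label.
    week : int
        Weeks post-surgery (longitudinal index).
    """

    coords: np.ndarray
    fs: float = 30.0
    mouse_id: str = "m0"
    group: str = ""
    week: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (9, 3):
            raise ValueError(
                f"coords must have shape (n_frames, 9, 3), got {self.coords.shape}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values after validation")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def node(self, node: NodeId | str) -> np.ndarray:
        """(n_frames, 3) trajectory of one node."""
        node = NodeId[node] if isinstance(node, str) else NodeId(node)
        return self.coords[:, int(node), :]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords.reshape(self.n_frames, 27), columns=coordinate_columns()
        )
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "PoseSequence":
        """Apply a rigid world-frame transform (used by invariance tests)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, float).T
        if translation is not None:
            coords = coords + np.asarray(translation, float)
        return replace(self, coords=coords)


@dataclass
class EventAnnotation:
    """A manually/ground-truth annotated behavioural event.

    ``kind`` is ``"rearing"`` (requires peak_frame, start <= peak <= end) or
    ``"swing"`` (requires foot, start < end). Frame intervals are half-open.
    """

    kind: str
    start_frame: int
    end_frame: int
    peak_frame: int | None = None
    foot: NodeId | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rearing", "swing"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "rearing":
            if self.peak_frame is None:
                raise ValueError("rearing event requires peak_frame")
            if not (self.start_frame <= self.peak_frame <= self.end_frame):
                raise ValueError("rearing requires start <= peak <= end")
        else:
            if self.foot is None:
                raise ValueError("swing event requires foot")
            if not self.start_frame < self.end_frame:
                raise ValueError("swing requires start < end")


def read_pose(path, fs: float = 30.0, *, mouse_id: str = "m0", group: str = "",
              week: int = 0) -> PoseSequence:
    """Read a pose CSV (columns: frame, then the 27 ``<node>_<axis>``).

    NaN gaps of at most 5 frames per coordinate are linearly interpolated;
    longer gaps (or gaps touching the session ends) reject the file.
    """
    df = pd.read_csv(path)
    expected = coordinate_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"missing coordinate column(s): {missing}")
    extra = [c for c in df.columns if c not in expected and c != "frame"]
    if extra:
        raise ValueError(f"unexpected column(s): {extra}")
    if "frame" in df.columns and len(df) > 1:
        fr = df["frame"].to_numpy()
        if np.any(np.diff(fr) <= 0):
            raise ValueError("frame index must be strictly increasing")
    coords = df[expected].to_numpy(dtype=float)
    coords = _fill_gaps(coords)
    return PoseSequence(coords.reshape(len(df), 9, 3), fs=fs,
                        mouse_id=mouse_id, group=group, week=week)


def _fill_gaps(coords: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs of <= MAX_GAP_FRAMES per column."""
    if not np.isnan(coords).any():
        return coords
    out = coords.copy()
    n = len(out)
    idx = np.arange(n)
    for j in range(out.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        # locate maximal NaN runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], nan.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s > MAX_GAP_FRAMES:
                raise ValueError(
                    f"gap of {e - s} frames exceeds {MAX_GAP_FRAMES} in column {j}"
                )
            if s == 0 or e == n:
                raise ValueError("NaN gap at session boundary cannot be interpolated")
        col[nan] = np.interp(idx[nan], idx[~nan], col[~nan])
    return out


def write_pose(seq: PoseSequence, path) -> None:
    """Write a pose CSV; round-trips through :func:`read_pose` to 1e-6 cm."""
    seq.to_dataframe().to_csv(path, index=False, float_format="%.8g")


def read_annotations(path) -> list[EventAnnotation]:
    """Read an annotation CSV (kind, foot, start_frame, peak_frame, end_frame)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        foot = getattr(row, "foot", None)
        foot = NodeId[foot] if isinstance(foot, str) and foot else None
        peak = getattr(row, "peak_frame", None)
        peak = None if peak is None or (isinstance(peak, float) and np.isnan(peak)) else int(peak)
        out.append(EventAnnotation(kind=row.kind, start_frame=int(row.start_frame),
                                   end_frame=int(row.end_frame), peak_frame=peak,
                                   foot=foot))
    return out


def write_annotations(events: list[EventAnnotation], path) -> None:
    rows = [
        {
            "kind": ev.kind,
            "foot": ev.foot.name if ev.foot is not None else "",
            "start_frame": ev.start_frame,
            "peak_frame": ev.peak_frame if ev.peak_frame is not None else "",
            "end_frame": ev.end_frame,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["kind", "foot", "start_frame", "peak_frame",
                                "end_frame"]).to_csv(path, index=False)


def segment_vectors(seq: PoseSequence) -> np.ndarray:
    """Per-frame 3D vectors of the 8 segments, shape (n_frames, 8, 3).

    vector = coords[end node] - coords[start node]; invariant to rigid
    translation of the whole pose.
    """
    out = np.empty((seq.n_frames, 8, 3))
    for seg, (a, b) in SEGMENT_ENDPOINTS.items():
        out[:, int(seg), :] = seq.coords[:, int(b), :] - seq.coords[:, int(a), :]
    return out


def body_frame(seq: PoseSequence, frame: int):
    """Rotation + origin mapping world xy to a body-aligned frame at one frame.

    Origin at the anus; +x along the horizontal anus->chest direction; z
    unchanged. Returns ``(origin, rotation)`` where ``rotation`` is the 2x2
    world->body xy rotation matrix. Raises ValueError on a degenerate frame
    (anus and chest horizontally coincident within 1e-6 cm).
    """
    anus = seq.coords[frame, int(NodeId.anus), :2]
    chest = seq.coords[frame, int(NodeId.chest), :2]
    d = chest - anus
    norm = np.hypot(*d)
    if norm < 1e-6:
        raise ValueError(f"degenerate body frame at frame {frame}: anus ~ chest in xy")
    c, s = d / norm
    rot = np.array([[c, s], [-s, c]])
    return anus, rot


def body_frame_xy(seq: PoseSequence, points_xy: np.ndarray) -> np.ndarray:
    """Vectorised body-frame mapping of per-frame xy points.

    ``points_xy`` has shape (n_frames, 2) (one point per frame, e.g. a foot).
    Degenerate frames map to NaN. Returns (n_frames, 2).
    """
    anus = seq.coords[:, int(NodeId.anus), :2]
    chest = seq.coords[:, int(NodeId.chest), :2]
    d = chest - anus
    norm = np.hypot(d[:, 0], d[:, 1])
    ok = norm >= 1e-6
    rel = np.asarray(points_xy, float) - anus
    out = np.full_like(rel, np.nan)
    c = np.where(ok, d[:, 0] / np.where(ok, norm, 1.0), np.nan)
    s = np.where(ok, d[:, 1] / np.where(ok, norm, 1.0), np.nan)
    out[:, 0] = c * rel[:, 0] + s * rel[:, 1]
    out[:, 1] = -s * rel[:, 0] + c * rel[:, 1]
    return out
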