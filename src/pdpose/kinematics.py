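"""Clip-level kinematic feature engineering: the 340-column feature table.

The per-frame signal registry comprises 83 signals: 27 node speeds (9 nodes
x 1D/2D/3D), 7 interior/limb angles (degrees), 14 node-pair distances with
space tags (cm), 8 absolute angle differences (degrees), and the 27 raw
coordinates. Four clip statistics (min, max, mean, std with denominator
n-1) over 83 signals give 332 columns; 8 per-episode temporal parameters
broadcast to each clip complete the 340.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pose import AXES, NodeId, PoseSequence, coordinate_columns
from .segmentation import (Episode, MotionClip, episode_temporal_params,
                           node_speed, segment_session)

__all__ = [
    "ANGLES",
    "DISTANCES",
    "ANGLE_DIFFS",
    "signal_names",
    "compute_signals",
    "clip_statistics",
    "assemble_feature_table",
    "featurize_session",
    "quantile_trim",
    "METADATA_COLUMNS",
]

logger = logging.getLogger(__name__)

# interior angle at vertex between (vertex->a) and (vertex->b)
ANGLES: dict[str, tuple[NodeId, NodeId, NodeId]] = {
    # name: (a, vertex, b)
    "head_angle": (NodeId.nose, NodeId.neck, NodeId.chest),
    "body_angle": (NodeId.neck, NodeId.chest, NodeId.anus),
    "tail_angle": (NodeId.chest, NodeId.anus, NodeId.tip),
    "r_arm_angle": (NodeId.neck, NodeId.chest, NodeId.r_hand),
    "l_arm_angle": (NodeId.neck, NodeId.chest, NodeId.l_hand),
    "r_leg_angle": (NodeId.chest, NodeId.anus, NodeId.r_foot),
    "l_leg_angle": (NodeId.chest, NodeId.anus, NodeId.l_foot),
}

DISTANCES: list[tuple[str, NodeId, NodeId, str]] = [
    ("hands_dist_3d", NodeId.r_hand, NodeId.l_hand, "3D"),
    ("hands_dist_2d", NodeId.r_hand, NodeId.l_hand, "2D"),
    ("feet_dist_3d", NodeId.r_foot, NodeId.l_foot, "3D"),
    ("feet_dist_2d", NodeId.r_foot, NodeId.l_foot, "2D"),
    ("body_dist_3d", NodeId.neck, NodeId.anus, "3D"),
    ("body_dist_2d", NodeId.neck, NodeId.anus, "2D"),
    ("upper_body_dist_3d", NodeId.nose, NodeId.chest, "3D"),
    ("upper_body_dist_2d", NodeId.nose, NodeId.chest, "2D"),
    ("nose_tip_dist_3d", NodeId.nose, NodeId.tip, "3D"),
    ("nose_tip_dist_2d", NodeId.nose, NodeId.tip, "2D"),
    ("r_hand_r_foot_dist_3d", NodeId.r_hand, NodeId.r_foot, "3D"),
    ("l_hand_l_foot_dist_3d", NodeId.l_hand, NodeId.l_foot, "3D"),
    ("r_hand_l_foot_dist_3d", NodeId.r_hand, NodeId.l_foot, "3D"),
    ("l_hand_r_foot_dist_3d", NodeId.l_hand, NodeId.r_foot, "3D"),
]

ANGLE_DIFFS: list[tuple[str, str]] = [
    ("r_arm_angle", "l_arm_angle"),
    ("r_leg_angle", "l_leg_angle"),
    ("r_arm_angle", "r_leg_angle"),
    ("l_arm_angle", "l_leg_angle"),
    ("r_arm_angle", "l_leg_angle"),
    ("l_arm_angle", "r_leg_angle"),
    ("head_angle", "body_angle"),
    ("body_angle", "tail_angle"),
]

# episode_ordinal lives among the features (8th temporal parameter) and
# doubles as the episode reference
METADATA_COLUMNS = ["mouse_id", "group", "week", "clip_index"]

_SPACE_AXES = {"1D": (2,), "2D": (0, 1), "3D": (0, 1, 2)}


def signal_names() -> list[str]:
    """The 83 registry signal names in pinned order."""
    names = [f"{n.name}_speed_{sp.lower()}" for n in NodeId
             for sp in ("1D", "2D", "3D")]
    names += list(ANGLES)
    names += [d[0] for d in DISTANCES]
    names += [f"angle_diff_{a}_{b}" for a, b in ANGLE_DIFFS]
    names += coordinate_columns()
    return names


def interior_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame interior angle (degrees) at ``vertex``; NaN when degenerate."""
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    denom = n1 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", v1, v2) / denom
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[denom < 1e-12] = np.nan
    return ang


def compute_signals(seq: PoseSequence) -> pd.DataFrame:
    """All 83 per-frame registry signals for a whole session.

    Degenerate angle frames (coincident nodes) are NaN-masked and excluded
    from clip statistics downstream.
    """
    cols: dict[str, np.ndarray] = {}
    for node in NodeId:
        for sp in ("1D", "2D", "3D"):
            cols[f"{node.name}_speed_{sp.lower()}"] = node_speed(seq, node, sp)
    angle_vals: dict[str, np.ndarray] = {}
    for name, (a, v, b) in ANGLES.items():
        angle_vals[name] = interior_angle(seq.node(a), seq.node(v), seq.node(b))
        cols[name] = angle_vals[name]
    for name, n1, n2, sp in DISTANCES:
        axes = _SPACE_AXES[sp]
        d = seq.node(n1)[:, axes] - seq.node(n2)[:, axes]
        cols[name] = np.linalg.norm(d, axis=1)
    for a, b in ANGLE_DIFFS:
        cols[f"angle_diff_{a}_{b}"] = np.abs(angle_vals[a] - angle_vals[b])
    flat = seq.coords.reshape(seq.n_frames, 27)
    for i, c in enumerate(coordinate_columns()):
        cols[c] = flat[:, i]
    return pd.DataFrame(cols, columns=signal_names())


def clip_statistics(values: pd.DataFrame) -> pd.Series:
    """{min, max, mean, std} per signal over a clip's frames.

    NaN-masked frames are excluded per signal; std uses denominator n-1.
    Raises if any signal has fewer than 2 unmasked frames.
    """
    if (values.notna().sum() < 2).any():
        bad = values.columns[values.notna().sum() < 2].tolist()
        raise ValueError(f"fewer than 2 unmasked frames for signal(s) {bad}")
    out = {}
    for stat, fn in (("min", "min"), ("max", "max"),
                     ("mean", "mean"), ("std", "std")):
        agg = getattr(values, fn)()
        for sig, v in agg.items():
            out[f"{sig}_{stat}"] = v
    return pd.Series(out)


def assemble_feature_table(seq: PoseSequence, episodes: list[Episode],
                           clips: list[MotionClip],
                           clip_len: int = 60) -> pd.DataFrame:
    """Clips x 340 feature columns (+ metadata) for one session."""
    signals = compute_signals(seq)
    temporal = episode_temporal_params(episodes, seq, clip_len)
    temporal = temporal.set_index("episode_ordinal") if len(temporal) else temporal
    rows = []
    for clip in clips:
        if clip.n_frames != clip_len:
            raise ValueError("inconsistent clip length in input")
        window = signals.iloc[clip.start_frame:clip.end_frame]
        try:
            stats = clip_statistics(window)
        except ValueError:
            logger.warning("clip %s/%s dropped: all frames masked",
                           clip.episode_ordinal, clip.clip_index)
            continue
        rec = stats.to_dict()
        for name in temporal.columns:
            rec[name] = temporal.loc[clip.episode_ordinal, name]
        rec["episode_ordinal"] = float(clip.episode_ordinal)
        rec["clip_index"] = clip.clip_index
        rec["mouse_id"] = seq.mouse_id
        rec["group"] = seq.group
        rec["week"] = seq.week
        rows.append(rec)
    feat_cols = feature_columns()
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS + feat_cols)
    return df


def feature_columns() -> list[str]:
    """The 340 kinematic feature column names."""
    cols = [f"{sig}_{stat}" for sig in signal_names()
            for stat in ("min", "max", "mean", "std")]
    cols += ["motion_duration_s", "motion_interval_s", "clip_count",
             "onset_time_s", "chest_path_length_cm", "mean_chest_speed_2d",
             "rest_ratio", "episode_ordinal"]
    return cols


def featurize_session(seq: PoseSequence, clip_len: int = 60) -> pd.DataFrame:
    """Segment a session and build its kinematic feature table."""
    episodes, clips = segment_session(seq, clip_len=clip_len)
    df = assemble_feature_table(seq, episodes, clips, clip_len)
    return df


def quantile_trim(table: pd.DataFrame, lo: float = 0.01, hi: float = 0.99,
                  by_group: bool = True) -> pd.DataFrame:
    """Mask per-feature outliers outside the [lo, hi] quantiles.

    Quantiles are computed per group when a ``group`` column is present.
    Masked cells become NaN. The trim levels refer to the full sample:
    already-masked cells count toward the trimmed tail mass (half per
    tail), which makes the operation idempotent.
    """
    out = table.copy()
    feat_cols = [c for c in table.columns if c not in METADATA_COLUMNS
                 and pd.api.types.is_numeric_dtype(table[c])]
    if by_group and "group" in table.columns:
        groups = table.groupby("group", sort=False).groups
    else:
        groups = {"__all__": table.index}
    for _, idx in groups.items():
        block = out.loc[idx, feat_cols]
        n_total = len(block)
        if n_total == 0:
            continue
        masked = block.isna()
        for col in feat_cols:
            vals = block[col]
            m = int(masked[col].sum())
            nk = n_total - m
            if nk < 2:
                continue
            lo_eff = max(0.0, (lo * n_total - m / 2) / nk)
            hi_eff = min(1.0, 1.0 - ((1.0 - hi) * n_total - m / 2) / nk)
            ql = vals.quantile(lo_eff)
            qh = vals.quantile(hi_eff)
            out.loc[idx, col] = vals.where((vals >= ql) & (vals <= qh))
    return out
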