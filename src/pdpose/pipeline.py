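"""End-to-end pipeline orchestration with a serialisable run configuration.

Every threshold defaults to the published analysis constant (1.5 cm/s
movement threshold, 100-frame / 0.8 rolling window, 60/120-frame clips, 75
deg / 0.7 bending rule, APS bins 25/75, 7:3 and 6:4 splits, k = 30/20
selected features, alpha = 0.05). The config and seed are embedded in the
run manifest so any artefact can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .classify import ClipClassifierModel
from .kinematics import featurize_session

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "featurize", "train", "score")


@dataclass(frozen=True)
class RunConfig:
    fs: float = 30.0
    duration_s: float = 1200.0
    short_clip_frames: int = 60
    long_clip_frames: int = 120
    speed_threshold: float = 1.5
    window_frames: int = 100
    window_fraction: float = 0.8
    bend_angle_deg: float = 75.0
    bend_fraction: float = 0.7
    aps_bins: tuple = (25.0, 75.0)
    clip_split: tuple = (7, 3)
    gait_split: tuple = (6, 4)
    k_clip: int = 30
    k_gait: int = 20
    alpha: float = 0.05
    seed: int = 0
    n_mice: int = 5
    groups: tuple = ("control", "pd_severe")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, stages=STAGES, out_dir: str | Path | None = None):
    """Execute the requested stages in dependency order.

    Returns a manifest dict with stage artefacts (in memory) and counts.
    Raises when a stage is requested without its upstream dependency.
    """
    prereq = {"simulate": None, "segment": "simulate",
              "featurize": "simulate", "train": "featurize", "score": "train"}
    order = [s for s in STAGES if s in stages]
    for s in order:
        need = prereq[s]
        if need is not None and need not in order:
            raise ValueError(
                f"stage {s!r} requested without its upstream stage {need!r}")
    manifest = {"config": config.to_dict(), "config_hash": config.digest(),
                "seed": config.seed, "counts": {}}
    artefacts: dict[str, object] = {}

    if "simulate" in order:
        spec = simulate.CohortSpec(
            groups=tuple(simulate.GroupSpec(g, simulate.preset(g), config.n_mice)
                         for g in config.groups),
            weeks=(0,), seed=config.seed, duration_s=config.duration_s,
            fs=config.fs)
        artefacts["sessions"] = simulate.generate_cohort(spec)
        manifest["counts"]["sessions"] = len(artefacts["sessions"])
        logger.info("simulated %d sessions", len(artefacts["sessions"]))

    if "featurize" in order or "segment" in order:
        tables = []
        n_ep = 0
        for seq, truth in artefacts["sessions"]:
            df = featurize_session(seq, clip_len=config.short_clip_frames)
            n_ep += int(df["episode_ordinal"].nunique()) if len(df) else 0
            tables.append(df)
        features = pd.concat(tables, ignore_index=True)
        artefacts["features"] = features
        manifest["counts"]["episodes"] = n_ep
        manifest["counts"]["clips"] = int(len(features))
        manifest["counts"]["feature_columns"] = int(
            features.shape[1] - 4)  # minus metadata
        logger.info("featurized %d clips", len(features))

    if "train" in order:
        pd_groups = [g for g in config.groups if g.startswith("pd")]
        model = ClipClassifierModel.from_feature_table(
            artefacts["features"], pd_groups)
        artefacts["results"] = model.fit(seed=config.seed)
        manifest["counts"]["selected_features"] = len(
            artefacts["results"].selected_features)
        manifest["metrics"] = artefacts["results"].metrics

    if "score" in order:
        aps = artefacts["results"].score_aps(artefacts["features"])
        artefacts["aps"] = aps
        manifest["aps"] = [dataclasses.asdict(a) for a in aps]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        if "features" in artefacts:
            artefacts["features"].to_csv(out / "features.csv", index=False)
    manifest["artefacts"] = artefacts
    return manifest
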