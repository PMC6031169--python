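"""End-to-end orchestration: frames -> blobs -> layer features -> fusion
-> classification.

The stage order is fixed: per view, background modeling and subject
extraction; per blob, the layered feature profile; per synchronized
time step, cross-view fusion into one feature vector. Views with no
detected subject at a time step are dropped from the product for that
step (logged); a step where no view sees the subject yields no vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify, features, fusion, preprocess
from .io import DatasetManifest, ViewStream, load_sequence_views, read_labels
from .synthetic import SyntheticSample

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the frame-to-vector chain, with its default."""

    background_frames: int = 40
    threshold: float = 15.0
    denoise_radius: int = 1
    arm_strength: float = 0.05
    layers: int = features.DEFAULT_LAYERS
    alpha: float = features.DEFAULT_ALPHA
    alpha_convention: str = "printed"
    flavor: str = "depth"
    method: str = "ann"
    seed: int = 0
    test_size: float = 0.3

    def __post_init__(self) -> None:
        if self.layers % 2 == 0 or self.layers < 1:
            raise ValueError(f"layers must be odd and >= 1, got {self.layers}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.flavor not in fusion.FLAVORS:
            raise ValueError(f"flavor must be one of {fusion.FLAVORS}")
        if self.method not in classify.METHODS:
            raise ValueError(f"method must be one of {classify.METHODS}")


@dataclass
class FeatureTable:
    """Fused feature vectors with labels and provenance columns."""

    vectors: np.ndarray          # (n, 2N+2)
    labels: np.ndarray           # (n,)
    groups: np.ndarray           # (n,) sequence ids, for leak-free splits
    views_used: np.ndarray       # (n,)
    flavor: str

    def to_frame(self) -> pd.DataFrame:
        n_layers = self.vectors.shape[1] - 1
        half = (n_layers - 1) // 2
        cols = [f"layer_{k:+d}" for k in range(-half, half + 1)] + ["p_max"]
        df = pd.DataFrame(self.vectors, columns=cols)
        df.insert(0, "sequence_id", self.groups)
        df["views_used"] = self.views_used
        df["flavor"] = self.flavor
        df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        cols = [c for c in df.columns if c.startswith("layer_")] + ["p_max"]
        return cls(
            vectors=df[cols].to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(),
            groups=df["sequence_id"].to_numpy(),
            views_used=df["views_used"].to_numpy(),
            flavor=str(df["flavor"].iloc[0]),
        )


def extract_view_profiles(
    stream: ViewStream, config: PipelineConfig
) -> dict[int, features.LayerProfile]:
    """Per-frame layer profiles for one view; frames with no subject skipped."""
    bg_count = stream.background_count or config.background_frames
    model = preprocess.build_background_model(stream.frames[:bg_count])
    profiles: dict[int, features.LayerProfile] = {}
    for frame in stream.frames[bg_count:]:
        try:
            blob = preprocess.extract_blob(
                frame, model,
                threshold=config.threshold,
                denoise_radius=config.denoise_radius,
                arm_strength=config.arm_strength,
            )
            profiles[frame.frame_index] = features.compute_profile(
                blob, layers=config.layers, alpha=config.alpha,
                alpha_convention=config.alpha_convention,
            )
        except (preprocess.NoSubjectError, ValueError) as exc:
            log.info(
                "view %s frame %d skipped: %s", stream.view_id,
                frame.frame_index, exc,
            )
    return profiles


def fuse_sequence(
    streams: Sequence[ViewStream],
    config: PipelineConfig,
    label: Optional[str] = None,
    frame_labels: Optional[dict[int, str]] = None,
    sequence_id: str = "seq",
) -> list[tuple[np.ndarray, Optional[str], int]]:
    """Fuse one multiview sequence into per-time-step feature vectors.

    Returns ``(vector, label, views_used)`` per time step that had at
    least one detected subject.
    """
    per_view = [extract_view_profiles(s, config) for s in streams]
    all_indices = sorted(set().union(*[set(p) for p in per_view]))
    out = []
    for t in all_indices:
        profiles = [p[t] for p in per_view if t in p]
        if len(profiles) < len(per_view):
            log.info(
                "%s t=%d: fusing %d of %d views (missing detections dropped)",
                sequence_id, t, len(profiles), len(per_view),
            )
        fused = fusion.fuse(profiles)
        vec = fusion.make_vector(fused, flavor=config.flavor)
        lbl = frame_labels.get(t) if frame_labels else label
        out.append((vec.values, lbl, fused.views_used))
    return out


def build_feature_table(
    samples: Sequence[SyntheticSample], config: PipelineConfig
) -> FeatureTable:
    """Feature-extract and fuse an in-memory synthetic corpus."""
    rows, labels, groups, nviews = [], [], [], []
    for sample in samples:
        for vec, lbl, d in fuse_sequence(
            list(sample.streams.values()), config,
            label=sample.label, sequence_id=sample.sequence_id,
        ):
            rows.append(vec)
            labels.append(lbl)
            groups.append(sample.sequence_id)
            nviews.append(d)
    if not rows:
        raise ValueError("no feature vectors extracted from the corpus")
    return FeatureTable(
        vectors=np.stack(rows), labels=np.asarray(labels),
        groups=np.asarray(groups), views_used=np.asarray(nviews),
        flavor=config.flavor,
    )


def build_feature_table_from_disk(
    manifest: DatasetManifest, root: Path | str, config: PipelineConfig
) -> FeatureTable:
    """Feature-extract a corpus laid out on disk per its manifest."""
    root = Path(root)
    rows, labels, groups, nviews = [], [], [], []
    for entry in manifest.sequences:
        streams = load_sequence_views(manifest, entry, root)
        frame_labels = (
            read_labels(root / entry.labels_file) if entry.labels_file else None
        )
        for vec, lbl, d in fuse_sequence(
            streams, config, label=entry.label,
            frame_labels=frame_labels, sequence_id=entry.sequence_id,
        ):
            rows.append(vec)
            labels.append(lbl)
            groups.append(entry.sequence_id)
            nviews.append(d)
    if not rows:
        raise ValueError("no feature vectors extracted from the corpus")
    return FeatureTable(
        vectors=np.stack(rows), labels=np.asarray(labels),
        groups=np.asarray(groups), views_used=np.asarray(nviews),
        flavor=config.flavor,
    )


def train_and_evaluate(
    table: FeatureTable, config: PipelineConfig
) -> tuple[classify.TrainedModel, classify.EvalReport]:
    """Hold-out protocol on a feature table, split by sequence id."""
    return classify.train_eval_split(
        table.vectors, table.labels, method=config.method, seed=config.seed,
        test_size=config.test_size, groups=table.groups,
        layers=config.layers, alpha=config.alpha, flavor=config.flavor,
    )


def run_pipeline(
    manifest_path: Path | str,
    out_dir: Path | str,
    config: Optional[PipelineConfig] = None,
) -> classify.EvalReport:
    """Full run over an on-disk corpus; writes features CSV, model and report.

    Artifacts under ``out_dir``: ``features.csv``, ``model.joblib``,
    ``report.json``, ``run.log``.
    """
    import joblib

    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root_logger = logging.getLogger("layerfusion")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        log.info("pipeline config: %s", config)
        manifest = DatasetManifest.from_yaml(manifest_path)
        table = build_feature_table_from_disk(
            manifest, manifest_path.parent, config
        )
        table.to_frame().to_csv(out_dir / "features.csv", index=False)
        model, report = train_and_evaluate(table, config)
        joblib.dump(
            {"format_version": 1, "model": model}, out_dir / "model.joblib"
        )
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        log.info("average precision: %.2f%%", report.average_precision)
        return report
    finally:
        root_logger.removeHandler(handler)
        handler.close()
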