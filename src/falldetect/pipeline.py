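"""End-to-end orchestration: simulate/load -> segment -> extract -> evaluate.

A :class:`PipelineConfig` captures every stage's parameters and round-trips
losslessly through YAML, so a run is reproducible from its config file plus
the seeds it names.  Each stage failure is re-raised as a
:class:`PipelineError` naming the stage (and frame where known).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import MetricsReport, kfold_cv
from .features import (
    FEATURE_NAMES,
    WindowConfig,
    build_feature_vectors,
    compute_descriptors,
)
from .foreground import SegmentationParams, estimate_background, segment_sequence
from .synthetic import (
    FrameSequence,
    GroundTruth,
    ScenarioSpec,
    generate_dataset,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "load_frame_dataset",
    "extract_labeled_features",
    "dataset_to_feature_table",
    "smooth_predictions",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline."""

    n_sequences: int = 12
    class_mix: dict = field(default_factory=lambda: {"fall": 0.5, "walk": 0.5})
    scenario: dict = field(default_factory=dict)  # ScenarioSpec overrides
    seed: int = 1
    input_dir: str | None = None  # when set, frames are loaded, not simulated
    out_dir: str | None = None
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    window: dict = field(default_factory=dict)  # WindowConfig overrides
    classifier: dict = field(
        default_factory=lambda: {"base": "full_tree", "rounds": 10,
                                 "max_depth": None, "min_leaf": 1}
    )
    folds: int = 10
    smooth_window: int = 0  # 0 disables the majority-vote smoother

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(**self.scenario)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def window_config(self) -> WindowConfig:
        return WindowConfig(**self.window)


def extract_labeled_features(
    frames: np.ndarray,
    labels: list[str] | None,
    params: SegmentationParams,
    window: WindowConfig,
    background: np.ndarray | None = None,
):
    """Segment a sequence and build its labelled feature table.

    Returns (X, y, frame_indices); the label of a window is the label of the
    frame it ends at (``None`` labels give y of "unknown").
    """
    blobs = segment_sequence(frames, params, background)
    descs = compute_descriptors(blobs)
    if len(descs) < window.k:
        raise PipelineError(
            "features",
            f"sequence of {len(descs)} frames shorter than window k={window.k}",
        )
    vecs = build_feature_vectors(descs, window)
    X = np.array([v.as_array() for v in vecs]) if vecs else np.empty((0, 7))
    idx = [v.frame_index for v in vecs]
    if labels is None:
        y = np.array(["unknown"] * len(vecs))
    else:
        y = np.array([labels[i] for i in idx])
    return X, y, idx, descs


def dataset_to_feature_table(
    dataset: list[tuple[FrameSequence, GroundTruth]],
    params: SegmentationParams = SegmentationParams(),
    window: WindowConfig = WindowConfig(),
    use_true_background: bool = True,
) -> pd.DataFrame:
    """Pooled per-window feature table over simulated sequences.

    One row per emitted window: the seven variance features, the ground-truth
    label at the window's end frame, and sequence/frame bookkeeping columns.
    """
    rows = []
    for si, (seq, gt) in enumerate(dataset):
        bg = seq.background if use_true_background else None
        X, y, idx, _ = extract_labeled_features(
            seq.frames, gt.labels, params, window, bg
        )
        for xi, yi, fi in zip(X, y, idx):
            row = {"sequence": si, "frame_index": fi, "label": yi}
            row.update({name: v for name, v in zip(FEATURE_NAMES, xi)})
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> MetricsReport:
    """Execute every stage and write intermediate artifacts to ``out_dir``."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # -- data ------------------------------------------------------------
    try:
        if config.input_dir:
            loaded = load_frame_dataset(config.input_dir)
            dataset = []
            for frames, labels, background in loaded:
                seq = FrameSequence(
                    frames=frames,
                    fps=30.0,
                    background=background
                    if background is not None
                    else estimate_background(frames, min(60, len(frames))),
                )
                gt = GroundTruth(
                    labels=labels if labels is not None else ["unknown"] * len(frames),
                    centers=np.zeros((len(frames), 2)),
                    angles=np.zeros(len(frames)),
                    extents=np.zeros((len(frames), 2)),
                )
                dataset.append((seq, gt))
        else:
            dataset = generate_dataset(
                config.n_sequences, config.class_mix,
                config.scenario_spec(), config.seed,
            )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("simulate" if not config.input_dir else "load", str(e))

    # -- segment + extract ------------------------------------------------
    try:
        params = config.segmentation_params()
        window = config.window_config()
        table = dataset_to_feature_table(dataset, params, window)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("features", str(e))
    if table.empty:
        raise PipelineError("features", "no feature windows were produced")
    if out:
        table.to_csv(out / "features.csv", index=False)

    # -- evaluate ----------------------------------------------------------
    try:
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table["label"].to_numpy()
        report = kfold_cv(
            X, y, folds=config.folds, seed=config.seed,
            base=config.classifier.get("base", "full_tree"),
            rounds=config.classifier.get("rounds", 10),
            max_depth=config.classifier.get("max_depth"),
            min_leaf=config.classifier.get("min_leaf", 1),
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate", str(e))

    if out:
        report.save(out / "report.json")
        meta = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "version": __version__,
            "n_sequences": len(dataset),
            "n_windows": int(len(table)),
            "class_counts": table["label"].value_counts().to_dict(),
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return report


def smooth_predictions(labels, window: int = 15) -> np.ndarray:
    """Centered majority-vote smoother over per-frame labels (optional
    post-processing; ties keep the original frame label)."""
    labels = np.asarray(labels)
    if window < 2:
        return labels.copy()
    half = window // 2
    out = labels.copy()
    for i in range(len(labels)):
        seg = labels[max(0, i - half) : i + half + 1]
        vals, counts = np.unique(seg, return_counts=True)
        top = counts.max()
        winners = set(vals[counts == top].tolist())
        if labels[i] not in winners:
            out[i] = sorted(winners, key=str)[0]
    return out


_FRAME_RE = re.compile(r"(\d+)\D*$")


def _numeric_index(path: Path) -> int | None:
    m = _FRAME_RE.search(path.stem)
    return int(m.group(1)) if m else None


def _load_sequence_dir(d: Path, layout: str):
    exts = {".png", ".jpg", ".jpeg"}
    files = [
        p for p in d.iterdir()
        if p.suffix.lower() in exts and p.name != "background.png"
    ]
    indexed = [(_numeric_index(p), p) for p in files]
    indexed = [(i, p) for i, p in indexed if i is not None]
    if not indexed:
        raise FileNotFoundError(f"no numbered frames in {d}")
    indexed.sort()
    idxs = [i for i, _ in indexed]
    if layout == "frames":
        expected = list(range(idxs[0], idxs[0] + len(idxs)))
        if idxs != expected:
            missing = sorted(set(expected) - set(idxs))
            raise FileNotFoundError(f"gap in frame numbering in {d}: missing {missing}")
    frames = np.stack([np.asarray(iio.imread(p)) for _, p in indexed])
    if frames.ndim == 4:  # RGB -> luma
        from .foreground import to_grayscale

        frames = np.stack([
            np.clip(np.rint(to_grayscale(f)), 0, 255).astype(np.uint8) for f in frames
        ])
    labels = None
    lab_file = d / "labels.csv"
    if lab_file.exists():
        df = pd.read_csv(lab_file).sort_values("frame_index")
        labels = df["label"].astype(str).tolist()
        if len(labels) != len(frames):
            raise ValueError(
                f"{lab_file}: {len(labels)} labels for {len(frames)} frames"
            )
    background = None
    bg_file = d / "background.png"
    if bg_file.exists():
        background = np.asarray(iio.imread(bg_file))
    return frames, labels, background


def load_frame_dataset(path: str | Path, layout: str = "frames"):
    """Load one or more frame-directory sequences.

    ``frames`` expects the simulator's own layout (contiguous numbered PNGs,
    optional ``labels.csv`` and ``background.png``); ``mcf-like`` and
    ``urfd-like`` accept arbitrary numbered PNG/JPEG frames (sorted by their
    trailing number, gaps tolerated) as those datasets ship them.  A
    directory whose children are directories is read as a list of sequences.
    Returns a list of (frames, labels-or-None, background-or-None).
    """
    if layout not in ("frames", "mcf-like", "urfd-like"):
        raise ValueError(f"unknown layout {layout!r}")
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    has_frames = any(
        p.suffix.lower() in (".png", ".jpg", ".jpeg") for p in root.iterdir()
    )
    if has_frames:
        return [_load_sequence_dir(root, layout)]
    if not subdirs:
        raise FileNotFoundError(f"{root} contains neither frames nor sequence dirs")
    return [_load_sequence_dir(d, layout) for d in subdirs]
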