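"""Synthetic surveillance sequences of a single moving person-blob.

The generator renders a person as a filled ellipse on a flat grey background
and animates one of four scenarios:

``walk``
    constant-speed horizontal translation, upright the whole time;
``fall``
    walk, then a rapid rotation of the body axis from vertical (90 deg) to
    horizontal (0 deg) over a short window (default 10 frames, ~0.33 s at
    30 fps), then lying still;
``sit``
    the same rotation performed slowly (default 45 frames, 1.5 s) — the only
    scripted difference between sitting down and falling is the speed of the
    action;
``crouch``
    gradual height shrink with no rotation, never labelled as a fall.

Every frame carries a ground-truth activity label and the true blob
parameters (center, body-axis angle, extents), so segmentation, ellipse
fitting and classification can all be checked against the values the scene
was rendered from.  Output is bit-deterministic for a fixed spec (seed
included).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ScenarioSpec",
    "FrameSequence",
    "GroundTruth",
    "SCENARIOS",
    "rasterize_ellipse",
    "simulate_sequence",
    "generate_dataset",
    "write_sequence",
]

SCENARIOS = ("walk", "fall", "sit", "crouch")

#: default action lengths (frames at 30 fps); the fall is rapid, sitting is
#: gradual — the speed of the rotation is what separates the two classes.
DEFAULT_ACTION_DURATION = {"walk": 0, "fall": 10, "sit": 45, "crouch": 45}

LABEL_FALL = "fall"
LABEL_SIT = "sitting"
LABEL_NONE = "no_fall"


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated sequence.

    ``person_size`` is the (height, width) of the upright body in pixels;
    ``walk_speed`` is horizontal translation in px/frame; ``action_duration``
    is the number of frames the fall/sit rotation (or crouch shrink) spans,
    defaulting per scenario; ``label_onset_deg`` is the body-axis angle below
    which a frame is labelled fall/sitting (the datasets the pipeline targets
    publish no frame-level labelling rule, so this documented threshold
    stands in for one).
    """

    scenario: str = "walk"
    frame_size: tuple[int, int] = (120, 160)
    fps: float = 30.0
    person_size: tuple[int, int] = (40, 14)
    walk_speed: float = 1.5
    action_duration: int | None = None
    pre_frames: int = 45
    post_frames: int = 25
    noise_sigma: float = 2.0
    background_intensity: int = 110
    person_intensity: int = 200
    label_onset_deg: float = 80.0
    seed: int = 0

    def resolved_action_duration(self) -> int:
        if self.action_duration is not None:
            return int(self.action_duration)
        return DEFAULT_ACTION_DURATION[self.scenario]

    def n_frames(self) -> int:
        return self.pre_frames + self.resolved_action_duration() + self.post_frames

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        ph, pw = self.person_size
        fh, fw = self.frame_size
        if not (ph < fh and pw < fw):
            raise ValueError(
                f"person_size {self.person_size} must be strictly smaller than "
                f"frame_size {self.frame_size} in both dimensions"
            )
        if ph >= fh or 2 * math.ceil(ph / 2) + 4 >= fw:
            # lying body extends horizontally by the full body height
            raise ValueError("frame too narrow for the lying person")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pre_frames < 0 or self.post_frames < 0:
            raise ValueError("frame counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class FrameSequence:
    """Ordered uniform-size 8-bit grayscale frames plus the clean background."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float
    background: np.ndarray  # (H, W) uint8

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class GroundTruth:
    """Per-frame truth: activity label and the rendered blob parameters."""

    labels: list[str]
    centers: np.ndarray  # (T, 2) float, (x, y)
    angles: np.ndarray  # (T,) degrees of the body major axis from horizontal
    extents: np.ndarray  # (T, 2) float, (semi_major, semi_minor) px
    masks: list[np.ndarray] = field(default_factory=list)  # (H, W) bool, per frame

    @property
    def action_onset(self) -> int | None:
        """Index of the first fall/sitting-labelled frame, if any."""
        for i, lab in enumerate(self.labels):
            if lab != LABEL_NONE:
                return i
        return None


def rasterize_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of a filled ellipse.

    ``center`` is (x, y) with the origin at the top-left corner; ``angle_deg``
    is the major-axis angle measured from the horizontal image axis (an
    upright person has angle 90).  A pixel belongs to the ellipse when its
    center lies inside the continuous ellipse.
    """
    h, w = shape
    cx, cy = center
    phi = math.radians(angle_deg)
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - cx
    # image rows grow downward; flip so the angle convention is y-up
    dy = -(ys - cy)
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def _vertical_half_extent(a: float, b: float, angle_deg: float) -> float:
    """Half the vertical extent of an ellipse with semi-axes a, b at angle_deg."""
    phi = math.radians(angle_deg)
    return math.hypot(a * math.sin(phi), b * math.cos(phi))


def simulate_sequence(spec: ScenarioSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render one scenario; identical spec (incl. seed) gives identical bytes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    ph, pw = spec.person_size
    a0 = ph / 2.0  # semi-major (body half-height) while upright
    b0 = pw / 2.0
    action = spec.resolved_action_duration()
    n = spec.n_frames()
    floor_y = h - 6.0

    # randomised walk: direction, start abscissa and a mild speed jitter
    direction = 1 if rng.random() < 0.5 else -1
    speed = spec.walk_speed * rng.uniform(0.85, 1.15)
    travel = speed * spec.pre_frames
    lateral_margin = a0 + 2.0  # room for the lying body
    lo, hi = lateral_margin, w - 1 - lateral_margin - travel
    if hi <= lo:
        raise ValueError("frame too narrow for the requested walk distance")
    x_start = rng.uniform(lo, hi)
    if direction < 0:
        x_start = (w - 1) - x_start

    angles = np.full(n, 90.0)
    heights = np.full(n, a0)
    if action > 0:
        t = np.arange(1, action + 1, dtype=float) / action
        sl = slice(spec.pre_frames, spec.pre_frames + action)
        if spec.scenario in ("fall", "sit"):
            angles[sl] = 90.0 * (1.0 - t)
            angles[spec.pre_frames + action :] = 0.0
        elif spec.scenario == "crouch":
            heights[sl] = a0 * (1.0 - 0.45 * t)
            heights[spec.pre_frames + action :] = a0 * 0.55

    xs = np.empty(n)
    for i in range(n):
        walked = min(i, spec.pre_frames)  # translation stops at action onset
        xs[i] = x_start + direction * speed * walked

    background = np.full((h, w), spec.background_intensity, dtype=np.uint8)

    frames = np.empty((n, h, w), dtype=np.uint8)
    labels: list[str] = []
    centers = np.empty((n, 2))
    extents = np.empty((n, 2))
    masks: list[np.ndarray] = []
    action_label = LABEL_SIT if spec.scenario == "sit" else LABEL_FALL
    for i in range(n):
        a = heights[i]
        cy = floor_y - _vertical_half_extent(a, b0, angles[i])
        mask = rasterize_ellipse((h, w), (xs[i], cy), a, b0, angles[i])
        frame = background.copy()
        frame[mask] = spec.person_intensity
        if spec.noise_sigma > 0:
            noisy = frame.astype(np.float64) + rng.normal(0.0, spec.noise_sigma, (h, w))
            frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        frames[i] = frame
        centers[i] = (xs[i], cy)
        extents[i] = (a, b0)
        masks.append(mask)
        if spec.scenario in ("fall", "sit") and angles[i] < spec.label_onset_deg:
            labels.append(action_label)
        else:
            labels.append(LABEL_NONE)

    seq = FrameSequence(frames=frames, fps=spec.fps, background=background)
    gt = GroundTruth(
        labels=labels, centers=centers, angles=angles, extents=extents, masks=masks
    )
    return seq, gt


def generate_dataset(
    n_sequences: int,
    class_mix: dict[str, float],
    spec_template: ScenarioSpec = ScenarioSpec(),
    seed: int = 0,
) -> list[tuple[FrameSequence, GroundTruth]]:
    """Simulate ``n_sequences`` sequences with scenario proportions ``class_mix``.

    Counts follow largest-remainder rounding of ``mix * n``; per-sequence seeds
    are drawn deterministically from ``seed``, so the whole dataset is
    reproducible from (n, mix, template, seed).
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    for scen, p in class_mix.items():
        if scen not in SCENARIOS:
            raise ValueError(f"unknown scenario {scen!r} in class_mix")
        if p < 0:
            raise ValueError("class_mix proportions must be non-negative")
    total = sum(class_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class_mix proportions must sum to 1 (got {total})")

    scens = sorted(class_mix)
    exact = {s: class_mix[s] * n_sequences for s in scens}
    counts = {s: int(math.floor(exact[s])) for s in scens}
    short = n_sequences - sum(counts.values())
    for s in sorted(scens, key=lambda s: (-(exact[s] - counts[s]), s))[:short]:
        counts[s] += 1

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_sequences)
    out: list[tuple[FrameSequence, GroundTruth]] = []
    i = 0
    for s in scens:
        for _ in range(counts[s]):
            spec = replace(
                spec_template,
                scenario=s,
                action_duration=None
                if spec_template.scenario != s
                else spec_template.action_duration,
                seed=int(child_seeds[i]),
            )
            out.append(simulate_sequence(spec))
            i += 1
    return out


def write_sequence(
    seq: FrameSequence, gt: GroundTruth, out_dir: str | Path
) -> Path:
    """Write zero-padded PNG frames, ``background.png`` and ``labels.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(len(seq)):
        iio.imwrite(out / f"frame_{i:05d}.png", seq.frames[i])
    iio.imwrite(out / "background.png", seq.background)
    with open(out / "labels.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame_index", "label"])
        for i, lab in enumerate(gt.labels):
            wr.writerow([i, lab])
    return out
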