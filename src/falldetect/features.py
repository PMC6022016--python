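"""Per-frame geometric/motion descriptors and their sliding-window variances.

Six raw measurements are taken from each segmented person blob:

========  ==========================================================
``ar``    bounding-box aspect ratio, width/height (low standing, high lying)
``pa``    person angle: fitted-ellipse major axis vs. the horizontal, deg
``er``    ellipse ratio: vertical-ish axis / horizontal-ish axis (>1 upright)
``sd``    foreground pixel count in the upper half of the bounding box
``gc``    geometric center: mean of the blob's boundary (edge) pixels
``mv``    centroid displacement magnitude between consecutive frames
========  ==========================================================

The classifier input is the temporal variance of each measurement over a
trailing window of k frames (default 30 ~ 1 s at 30 fps), with the variance
denominator exactly k (population form), and the geometric center split into
x and y components — seven variance features per frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .foreground import PersonBlob

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseFit",
    "FrameDescriptor",
    "WindowConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "fit_ellipse",
    "person_angle",
    "ellipse_ratio",
    "aspect_ratio",
    "upper_half_area",
    "geometric_center",
    "motion_magnitude",
    "temporal_variance",
    "compute_descriptors",
    "build_feature_vectors",
]

FEATURE_NAMES = ("var_ar", "var_pa", "var_mv", "var_sd", "var_gcx", "var_gcy", "var_er")
DESCRIPTOR_NAMES = ("ar", "pa", "er", "sd", "gcx", "gcy", "mv")


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a blob.

    ``theta`` is the major-axis angle from the horizontal x-axis folded into
    [0, 90] degrees (left/right orientations are merged); axis lengths are
    full lengths under the 4*sqrt(eigenvalue) convention, which recovers the
    true axes of a solid ellipse.
    """

    center: tuple[float, float]
    major_len: float
    minor_len: float
    theta: float


@dataclass
class FrameDescriptor:
    """The six raw per-frame measurements; invalid when no blob was found."""

    frame_index: int
    ar: float = 0.0
    pa: float = 0.0
    er: float = 0.0
    sd: float = 0.0
    gcx: float = 0.0
    gcy: float = 0.0
    mv: float = 0.0
    valid: bool = False
    mv_defined: bool = False  # False on the first valid frame (no predecessor)


@dataclass(frozen=True)
class WindowConfig:
    """Trailing-window setup: length ``k`` (>= 2), stride, invalid handling."""

    k: int = 30
    step: int = 1
    invalid_policy: str = "skip"  # or "interpolate"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("window length k must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.invalid_policy not in ("skip", "interpolate"):
            raise ValueError("invalid_policy must be 'skip' or 'interpolate'")


@dataclass
class FeatureVector:
    """Seven trailing-window variances ending at ``frame_index``."""

    frame_index: int
    var_ar: float
    var_pa: float
    var_mv: float
    var_sd: float
    var_gcx: float
    var_gcy: float
    var_er: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.var_ar, self.var_pa, self.var_mv, self.var_sd,
             self.var_gcx, self.var_gcy, self.var_er]
        )


def fit_ellipse(blob: PersonBlob) -> EllipseFit:
    """Ellipse from second-order central moments of the blob mask.

    theta = 1/2 * atan2(2*mu11, mu20 - mu02) in a y-up frame, folded to
    [0, 90] degrees; axis lengths are 4*sqrt of the covariance eigenvalues.
    A near-isotropic blob (disk) takes theta = 90 by convention; a degenerate
    (collinear) blob has its minor axis clamped to 1 px.
    """
    ys, xs = np.nonzero(blob.mask)
    if xs.size < 5:
        raise ValueError("blob too small for a moment ellipse (area < 5 px)")
    cx, cy = xs.mean(), ys.mean()
    dx = xs - cx
    dy = -(ys - cy)  # y-up so angles are measured from the horizontal
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)

    aniso = math.hypot(2.0 * mu11, mu20 - mu02)
    if aniso < 1e-9 * max(mu20 + mu02, 1.0):
        theta = 90.0
    else:
        theta = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02))
        theta = abs(theta)  # fold: left/right fall directions merge
    common = 0.5 * aniso
    mean = 0.5 * (mu20 + mu02)
    lam1 = mean + common
    lam2 = max(mean - common, 0.0)
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    if minor < 1.0:
        logger.warning("degenerate blob: minor axis clamped to 1 px")
        minor = 1.0
        major = max(major, minor)
    return EllipseFit(center=(float(cx), float(cy)), major_len=float(major),
                      minor_len=float(minor), theta=float(theta))


def person_angle(fit: EllipseFit) -> float:
    """Body-axis angle in degrees: 90 upright, approaching 0 when lying."""
    return fit.theta


def ellipse_ratio(fit: EllipseFit, oriented: bool = True) -> float:
    """Axis-length ratio of the fitted ellipse.

    Oriented form (default): the axis pointing within 45 degrees of vertical
    divided by the other, so a standing person scores > 1 and a fallen one
    < 1.  ``oriented=False`` gives the strict major/minor ratio (always >= 1).
    """
    if not oriented:
        return fit.major_len / fit.minor_len
    if fit.theta >= 45.0:
        return fit.major_len / fit.minor_len
    return fit.minor_len / fit.major_len


def aspect_ratio(blob: PersonBlob) -> float:
    """Bounding-box width / height."""
    _, _, w, h = blob.bbox
    return w / h


def upper_half_area(blob: PersonBlob) -> int:
    """Foreground pixels in the upper half of the bounding box.

    The box is split at row y + ceil(h/2); an odd-height box gives the upper
    half the extra row.
    """
    x, y, w, h = blob.bbox
    half = math.ceil(h / 2)
    return int(blob.mask[y : y + half, x : x + w].sum())


def geometric_center(blob: PersonBlob) -> tuple[float, float]:
    """Mean (x, y) of the blob's boundary (edge) pixels — not all members."""
    pts = blob.boundary_points
    if pts.shape[0] == 0:
        raise ValueError("blob has no boundary points")
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def motion_magnitude(
    prev_centroid: tuple[float, float], centroid: tuple[float, float]
) -> float:
    """Euclidean displacement of the blob centroid, px/frame."""
    return math.hypot(centroid[0] - prev_centroid[0], centroid[1] - prev_centroid[1])


def temporal_variance(series, k: int) -> float:
    """Variance of the k most recent values with denominator exactly k.

    Population-style (1/k, not 1/(k-1)) as used throughout the feature set.
    A constant window returns exactly 0.0.
    """
    arr = np.asarray(series, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if arr.size < k:
        raise ValueError(f"series length {arr.size} < window k={k}")
    win = arr[-k:]
    if np.ptp(win) == 0.0:
        return 0.0
    mu = win.mean()
    return float(np.mean((win - mu) ** 2))


def compute_descriptors(
    blobs: list[PersonBlob | None], oriented_er: bool = True
) -> list[FrameDescriptor]:
    """Raw measurements per frame from the per-frame segmentation output.

    Frames without a blob produce an invalid descriptor.  ``mv`` is the
    displacement from the previous *valid* frame's centroid; the first valid
    frame has no predecessor, so its mv is 0 and flagged undefined.
    """
    out: list[FrameDescriptor] = []
    prev_centroid: tuple[float, float] | None = None
    for i, blob in enumerate(blobs):
        if blob is None:
            out.append(FrameDescriptor(frame_index=i))
            continue
        fit = fit_ellipse(blob)
        gx, gy = geometric_center(blob)
        if prev_centroid is None:
            mv, mv_def = 0.0, False
        else:
            mv, mv_def = motion_magnitude(prev_centroid, blob.centroid), True
        out.append(
            FrameDescriptor(
                frame_index=i,
                ar=aspect_ratio(blob),
                pa=person_angle(fit),
                er=ellipse_ratio(fit, oriented=oriented_er),
                sd=float(upper_half_area(blob)),
                gcx=gx,
                gcy=gy,
                mv=mv,
                valid=True,
                mv_defined=mv_def,
            )
        )
        prev_centroid = blob.centroid
    return out


def _window_variance(values: np.ndarray, defined: np.ndarray) -> float:
    """Variance over the defined entries of a window (denominator = count)."""
    vals = values[defined]
    if vals.size < 2:
        return 0.0
    if np.ptp(vals) == 0.0:
        return 0.0
    return float(np.mean((vals - vals.mean()) ** 2))


def build_feature_vectors(
    descriptors: list[FrameDescriptor], config: WindowConfig = WindowConfig()
) -> list[FeatureVector]:
    """One FeatureVector per window end index >= k-1 (stride ``step``).

    Windows containing invalid frames follow ``invalid_policy``: ``skip``
    emits nothing; ``interpolate`` linearly fills interior gaps of up to 3
    frames per field and skips otherwise.  The mv variance uses only entries
    where mv is defined (everything past the first valid frame).
    """
    k = config.k
    n = len(descriptors)
    if n < k:
        raise ValueError(f"need at least k={k} descriptors, got {n}")

    fields = np.array(
        [[d.ar, d.pa, d.er, d.sd, d.gcx, d.gcy, d.mv] for d in descriptors]
    )
    valid = np.array([d.valid for d in descriptors])
    mv_def = np.array([d.mv_defined and d.valid for d in descriptors])

    if config.invalid_policy == "interpolate" and (~valid).any():
        fields = fields.copy()
        idx = np.arange(n)
        runs = _invalid_runs(valid)
        fillable = np.zeros(n, dtype=bool)
        for start, stop in runs:  # [start, stop)
            if start > 0 and stop < n and (stop - start) <= 3:
                fillable[start:stop] = True
        if fillable.any():
            for j in range(fields.shape[1]):
                fields[fillable, j] = np.interp(
                    idx[fillable], idx[valid], fields[valid, j]
                )
            valid = valid | fillable
            # interpolated frames contribute a defined mv too
            mv_def = mv_def | fillable

    out: list[FeatureVector] = []
    for end in range(k - 1, n, config.step):
        w = slice(end - k + 1, end + 1)
        if not valid[w].all():
            continue
        ar, pa, er, sd, gcx, gcy, mv = (fields[w, j] for j in range(7))
        out.append(
            FeatureVector(
                frame_index=end,
                var_ar=_var_k(ar),
                var_pa=_var_k(pa),
                var_mv=_window_variance(mv, mv_def[w]),
                var_sd=_var_k(sd),
                var_gcx=_var_k(gcx),
                var_gcy=_var_k(gcy),
                var_er=_var_k(er),
            )
        )
    return out


def _var_k(win: np.ndarray) -> float:
    if np.ptp(win) == 0.0:
        return 0.0
    return float(np.mean((win - win.mean()) ** 2))


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
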