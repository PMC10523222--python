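"""Turn a 10-joint skeleton sequence into the classifier's delta-feature tensor.

Pipeline: pick an upright reference frame from the early part of the clip,
translate/scale so that the reference mid-hip sits at (0, 0) and the torso
(mid-hip to neck distance) has length 1, Gaussian-smooth each coordinate
series over time (SD 1 frame by default), then take per-frame differences.
A k-frame clip becomes a (k-1) x 20 tensor; a motionless clip becomes all
zeros. The representation is invariant to global translation and uniform
scaling of the raw pixels — but deliberately *not* to rotation, so postural
lean remains visible to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegeneratePoseError, EmptyInputError, SchemaError, TooShortError
from .joints import MODEL_JOINTS, N_CHANNELS
from .keypoint_io import (
    SkeletonSequence,
    interpolate_missing,
    select_keypoints,
)

#: index of neck / mid-hip within the fixed channel order
_NECK = MODEL_JOINTS.index("neck")
_MID_HIP = MODEL_JOINTS.index("mid_hip")


@dataclass(frozen=True)
class NormalizationTransform:
    """Translation followed by uniform scaling: p -> (p + translation) * scale."""

    translation: tuple[float, float]
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise SchemaError(f"scale must be positive, got {self.scale}")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return (xy + np.asarray(self.translation)) * self.scale


@dataclass
class FeatureTensor:
    """(k-1) x 20 per-frame position deltas in the fixed channel order."""

    values: np.ndarray
    channel_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            f"{j}_{c}" for j in MODEL_JOINTS for c in ("x", "y")
        )
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise SchemaError(
                f"feature tensor must have {N_CHANNELS} channels, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_frames(self) -> int:
        """Number of frames k in the originating clip (rows + 1)."""
        return self.values.shape[0] + 1


@dataclass
class PreprocessConfig:
    sigma: float = 1.0          # Gaussian SD, in frames
    ref_window: int = 30        # frames searched for the reference pose (~1 s)
    max_missing_frac: float = 0.2


def _torso_lengths(seq: SkeletonSequence) -> np.ndarray:
    """Mid-hip -> neck Euclidean distance per frame; NaN where either is missing."""
    xy, conf = seq.coords()
    d = np.linalg.norm(xy[:, _NECK] - xy[:, _MID_HIP], axis=1)
    bad = (conf[:, _NECK] == 0) | (conf[:, _MID_HIP] == 0)
    d[bad] = np.nan
    return d


def choose_reference_frame(seq: SkeletonSequence, window: int = 30) -> int:
    """Pick the upright reference frame from the early part of the clip.

    Returns the index, within the first ``window`` frames, of the frame with
    the longest projected torso (mid-hip to neck). Standing upright in front
    of a level camera maximizes that projection, so this is a robust proxy
    for "upright and standing straight". Ties break to the earliest index.
    """
    if len(seq) == 0:
        raise EmptyInputError("empty sequence")
    if window < 1:
        raise SchemaError(f"window must be >= 1, got {window}")
    d = _torso_lengths(seq)[: min(window, len(seq))]
    if np.isnan(d).all():
        raise DegeneratePoseError(
            "no candidate frame has both mid-hip and neck observed"
        )
    return int(np.nanargmax(d))  # argmax takes the first maximum


def compute_normalization(
    seq: SkeletonSequence, ref: int
) -> NormalizationTransform:
    """Transform mapping the reference mid-hip to (0,0) and torso length to 1."""
    frame = seq.frames[ref]
    hip, neck = frame.get("mid_hip"), frame.get("neck")
    if hip.missing or neck.missing:
        raise DegeneratePoseError(f"frame {ref}: mid-hip or neck missing")
    torso = float(np.hypot(neck.x - hip.x, neck.y - hip.y))
    if torso <= 0.0:
        raise DegeneratePoseError(f"frame {ref}: zero torso length")
    return NormalizationTransform(translation=(-hip.x, -hip.y), scale=1.0 / torso)


def apply_normalization(
    seq: SkeletonSequence, t: NormalizationTransform
) -> SkeletonSequence:
    """Apply the transform to every joint of every frame; confidences unchanged."""
    xy, conf = seq.coords(seq.joint_names())
    return SkeletonSequence.from_coords(
        t.apply(xy), conf, seq.joint_names(), fps=seq.fps
    )


def smooth(seq: SkeletonSequence, sigma: float = 1.0) -> SkeletonSequence:
    """Gaussian-smooth each joint's x- and y-series independently over time.

    Kernel truncated at radius ceil(4*sigma) and renormalized; boundaries
    handled by reflection. Suppresses frame-to-frame pose-estimation jitter
    without shifting the motion (the kernel is symmetric).
    """
    if sigma <= 0:
        raise SchemaError(f"sigma must be positive, got {sigma}")
    names = seq.joint_names()
    xy, conf = seq.coords(names)
    radius = int(np.ceil(4.0 * sigma))
    smoothed = gaussian_filter1d(xy, sigma=sigma, axis=0, mode="reflect", radius=radius)
    return SkeletonSequence.from_coords(smoothed, conf, names, fps=seq.fps)


def delta_features(seq: SkeletonSequence) -> FeatureTensor:
    """Per-frame position differences, stacked as a (k-1) x 20 tensor.

    Row t holds position(frame t+1) - position(frame t) for all 20
    coordinates. A motionless clip yields an all-zero tensor.
    """
    if len(seq) < 2:
        raise TooShortError(
            f"need at least 2 frames for delta features, got {len(seq)}"
        )
    names = seq.joint_names()
    if set(names) != set(MODEL_JOINTS):
        raise SchemaError(
            f"expected the {len(MODEL_JOINTS)}-joint model subset, got {sorted(names)}"
        )
    xy, conf = seq.coords()  # model joint order
    if (conf == 0).any():
        raise SchemaError("sequence still contains missing joints")
    flat = xy.reshape(len(seq), N_CHANNELS)  # joint-major, x then y
    return FeatureTensor(np.diff(flat, axis=0))


def preprocess(
    seq: SkeletonSequence, cfg: PreprocessConfig | None = None
) -> FeatureTensor:
    """Full preprocessing chain: subset, fill gaps, normalize, smooth, difference."""
    cfg = cfg or PreprocessConfig()
    seq = select_keypoints(seq, max_missing_frac=cfg.max_missing_frac)
    seq = interpolate_missing(seq)
    ref = choose_reference_frame(seq, cfg.ref_window)
    t = compute_normalization(seq, ref)
    seq = apply_normalization(seq, t)
    seq = smooth(seq, cfg.sigma)
    return delta_features(seq)
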