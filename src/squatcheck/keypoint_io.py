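"""Read/write 2D pose keypoint streams in OpenPose-compatible JSON dialects.

Two dialects are supported:

``per_frame_files``
    A directory of one JSON file per frame, as written by OpenPose itself:
    ``{"people": [{"pose_keypoints_2d": [x0, y0, c0, x1, y1, c1, ...]}]}``
    with 25 (x, y, confidence) triples in BODY_25 order.  Files are taken in
    lexicographic order; person index 0 is always used.

``single_stream``
    A single JSON document holding the whole sequence:
    ``{"fps": 30.0, "frames": [{"joints": {"neck": [x, y, c], ...}}, ...]}``.
    A bare JSON array of frame records (without the fps wrapper) is also
    accepted on read; the writer always emits the wrapped form.

A joint whose (x, y, confidence) triple is (0, 0, 0), or whose confidence is
0, is *missing*: its coordinates are ignored by all downstream math.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import (
    DataQualityError,
    EmptyInputError,
    PoseParseError,
    SchemaError,
)
from .joints import BODY_25, MODEL_JOINTS, canonical_name

Dialect = Literal["per_frame_files", "single_stream"]


@dataclass(frozen=True)
class Joint:
    """A single named 2D landmark with detection confidence.

    Image coordinates: origin top-left, y increases downward. A confidence
    of exactly 0 marks the joint as missing for this frame.
    """

    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise SchemaError(
                f"joint {self.name!r}: confidence {self.confidence} outside [0, 1]"
            )

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0


@dataclass
class SkeletonFrame:
    """One frame's joints, keyed by joint name."""

    joints: dict[str, Joint]
    index: int = 0

    def get(self, name: str) -> Joint:
        """Return the named joint, or a missing placeholder if absent."""
        j = self.joints.get(name)
        if j is None:
            return Joint(name, 0.0, 0.0, 0.0)
        return j


@dataclass
class SkeletonSequence:
    """An ordered, gapless run of skeleton frames at a fixed frame rate."""

    frames: list[SkeletonFrame] = field(default_factory=list)
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        for i, f in enumerate(self.frames):
            f.index = i

    def __len__(self) -> int:
        return len(self.frames)

    def joint_names(self) -> list[str]:
        names: list[str] = []
        for f in self.frames:
            for n in f.joints:
                if n not in names:
                    names.append(n)
        return names

    def coords(self, names: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack coordinates into arrays.

        Returns ``(xy, conf)`` with shapes ``(k, J, 2)`` and ``(k, J)`` where
        J joints follow ``names`` order (default: the 10-joint model subset).
        Missing joints appear with conf 0; their xy values are meaningless.
        """
        names = list(names) if names is not None else list(MODEL_JOINTS)
        k = len(self.frames)
        xy = np.zeros((k, len(names), 2))
        conf = np.zeros((k, len(names)))
        for t, f in enumerate(self.frames):
            for j, n in enumerate(names):
                joint = f.get(n)
                xy[t, j] = (joint.x, joint.y)
                conf[t, j] = joint.confidence
        return xy, conf

    @staticmethod
    def from_coords(
        xy: np.ndarray,
        conf: np.ndarray | None = None,
        names: Iterable[str] | None = None,
        fps: float = 30.0,
    ) -> "SkeletonSequence":
        """Inverse of :meth:`coords`."""
        names = list(names) if names is not None else list(MODEL_JOINTS)
        xy = np.asarray(xy, dtype=float)
        if conf is None:
            conf = np.ones(xy.shape[:2])
        frames = []
        for t in range(xy.shape[0]):
            joints = {
                n: Joint(n, float(xy[t, j, 0]), float(xy[t, j, 1]), float(conf[t, j]))
                for j, n in enumerate(names)
            }
            frames.append(SkeletonFrame(joints, t))
        return SkeletonSequence(frames, fps=fps)


def _joint_from_triple(name: str, x: float, y: float, c: float) -> Joint:
    # OpenPose marks undetected joints as the all-zeros triple.
    if c == 0.0 or (x == 0.0 and y == 0.0 and c == 0.0):
        return Joint(name, 0.0, 0.0, 0.0)
    return Joint(name, float(x), float(y), float(c))


def _frame_from_openpose(record: dict, index: int, source: str) -> SkeletonFrame:
    people = record.get("people", [])
    joints: dict[str, Joint] = {}
    if people:
        flat = people[0].get("pose_keypoints_2d", [])
        if len(flat) % 3 != 0:
            raise PoseParseError(
                f"{source}: frame {index}: pose_keypoints_2d length "
                f"{len(flat)} is not a multiple of 3"
            )
        n = len(flat) // 3
        if n > len(BODY_25):
            raise PoseParseError(
                f"{source}: frame {index}: {n} keypoints exceeds BODY_25"
            )
        for j in range(n):
            name = BODY_25[j]
            joints[name] = _joint_from_triple(name, *flat[3 * j : 3 * j + 3])
    return SkeletonFrame(joints, index)


def _frame_from_record(record: dict, index: int, source: str) -> SkeletonFrame:
    if "people" in record:
        return _frame_from_openpose(record, index, source)
    raw = record.get("joints")
    if raw is None:
        raise PoseParseError(f"{source}: frame {index}: no 'joints' key")
    joints: dict[str, Joint] = {}
    for name, triple in raw.items():
        name = canonical_name(name)
        if len(triple) != 3:
            raise PoseParseError(
                f"{source}: frame {index}: joint {name!r} is not an [x, y, c] triple"
            )
        joints[name] = _joint_from_triple(name, *triple)
    return SkeletonFrame(joints, index)


def read_pose_json(
    path: str | Path, dialect: Dialect = "single_stream", fps: float = 30.0
) -> SkeletonSequence:
    """Load a keypoint stream as a :class:`SkeletonSequence`.

    Frames come out in temporal order with gapless indices 0..k-1. Missing
    joints carry confidence 0.

    Raises :class:`PoseParseError` on malformed JSON (naming file and frame)
    and :class:`EmptyInputError` if no frames are found.
    """
    path = Path(path)
    frames: list[SkeletonFrame] = []
    if dialect == "per_frame_files":
        files = sorted(p for p in path.iterdir() if p.suffix == ".json")
        for i, f in enumerate(files):
            try:
                record = json.loads(f.read_text())
            except json.JSONDecodeError as e:
                raise PoseParseError(f"{f}: frame {i}: invalid JSON: {e}") from e
            frames.append(_frame_from_record(record, i, str(f)))
    elif dialect == "single_stream":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise PoseParseError(f"{path}: invalid JSON: {e}") from e
        if isinstance(doc, dict):
            fps = float(doc.get("fps", fps))
            records = doc.get("frames", [])
        else:
            records = doc
        for i, record in enumerate(records):
            frames.append(_frame_from_record(record, i, str(path)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    return SkeletonSequence(frames, fps=fps)


def write_pose_json(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence in the ``single_stream`` dialect.

    Coordinates round-trip to full precision; missing joints are preserved
    as confidence-0 triples.
    """
    if len(seq) == 0:
        raise EmptyInputError("cannot write an empty sequence")
    doc = {
        "fps": seq.fps,
        "frames": [
            {
                "joints": {
                    n: [j.x, j.y, j.confidence] for n, j in frame.joints.items()
                }
            }
            for frame in seq.frames
        ],
    }
    Path(path).write_text(json.dumps(doc))


def select_keypoints(
    seq: SkeletonSequence,
    required: Iterable[str] = MODEL_JOINTS,
    max_missing_frac: float = 0.2,
) -> SkeletonSequence:
    """Restrict every frame to the model's joint subset.

    All other joints are dropped. If any required joint is missing
    (confidence 0) in more than ``max_missing_frac`` of frames, the sequence
    cannot be trusted — interpolation would fabricate motion — and a
    :class:`DataQualityError` is raised.
    """
    required = list(required)
    if len(seq) == 0:
        raise EmptyInputError("empty sequence")
    frames = []
    for f in seq.frames:
        frames.append(SkeletonFrame({n: f.get(n) for n in required}, f.index))
    k = len(frames)
    for n in required:
        n_missing = sum(1 for f in frames if f.joints[n].missing)
        if n_missing > max_missing_frac * k:
            raise DataQualityError(
                f"joint {n!r} missing in {n_missing}/{k} frames "
                f"(tolerance {max_missing_frac:.0%})"
            )
    return SkeletonSequence(frames, fps=seq.fps)


def interpolate_missing(seq: SkeletonSequence) -> SkeletonSequence:
    """Fill missing-joint gaps by linear interpolation in time.

    Interior gaps are interpolated between the nearest observed frames;
    leading/trailing gaps copy the nearest observation. Frames where the
    joint was observed are never altered. The output has no missing joints.
    """
    if len(seq) == 0:
        raise EmptyInputError("empty sequence")
    names = seq.joint_names()
    k = len(seq)
    new_frames = [SkeletonFrame(dict(f.joints), f.index) for f in seq.frames]
    t_all = np.arange(k)
    for n in names:
        obs = np.array([not seq.frames[t].get(n).missing for t in range(k)])
        if obs.all():
            continue
        if not obs.any():
            raise DataQualityError(f"joint {n!r} never observed")
        t_obs = t_all[obs]
        xs = np.array([seq.frames[t].joints[n].x for t in t_obs])
        ys = np.array([seq.frames[t].joints[n].y for t in t_obs])
        cs = np.array([seq.frames[t].joints[n].confidence for t in t_obs])
        for t in t_all[~obs]:
            new_frames[t].joints[n] = Joint(
                n,
                float(np.interp(t, t_obs, xs)),
                float(np.interp(t, t_obs, ys)),
                float(np.interp(t, t_obs, cs)),
            )
    return SkeletonSequence(new_frames, fps=seq.fps)
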