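"""Kinematic generator of labeled frontal-view squat keypoint sequences.

A planar two-leg + torso linkage performs squat repetitions seen from a
front camera. The knee-flexion angle follows a cosine-eased profile per
repetition (0 deg standing, ``depth_deg`` at mid-rep). Because the camera is
frontal, sagittal-plane motion appears as vertical foreshortening: with
flexion theta and a symmetric squat, the knee sits ``shank*cos(theta/2)``
above the ankle and the hip ``thigh*cos(theta/2)`` above the knee; forward
lean of the torso foreshortens the projected torso length by ``cos(lean)``.
Image convention: y increases downward, so "above" means smaller y.

Defect modes perturb the chain and determine the ground-truth label:

===============  =======================================  ==================
defect           geometric effect                          incorrect when
===============  =======================================  ==================
shallow_depth    achieved depth = depth_deg - magnitude    achieved < 70 deg
knee_valgus      knees move medially by magnitude *        offset > 15% of
                 hip_width * (theta/peak) at peak           hip width
forward_lean     torso foreshortened by cos(magnitude deg)  lean > 20 deg
asymmetric       left/right flexion split by +/- magnitude  split > 15 deg
===============  =======================================  ==================

These thresholds are conventions of this package, fixed so labels are
reproducible; they are not measurements of human form criteria.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import ValidationError
from .keypoint_io import SkeletonSequence, write_pose_json

Defect = Literal["none", "shallow_depth", "knee_valgus", "forward_lean", "asymmetric"]

# Label thresholds (see module docstring).
SHALLOW_DEPTH_MIN_DEG = 70.0
VALGUS_MAX_FRAC = 0.15
LEAN_MAX_DEG = 20.0
ASYMMETRY_MAX_DEG = 15.0


@dataclass(frozen=True)
class SquatSimParams:
    """Geometry, tempo and defect controls for one simulated squat clip.

    Lengths are in arbitrary pixel units. ``depth_deg`` is the peak knee
    flexion (0 = standing straight). ``noise_px`` is the SD of per-frame
    Gaussian jitter added to every coordinate, emulating pose-estimator
    noise. ``dropout_prob`` optionally marks random joints missing.
    """

    torso: float = 160.0
    thigh: float = 130.0
    shank: float = 120.0
    shoulder_width: float = 110.0
    hip_width: float = 80.0
    depth_deg: float = 95.0
    tempo_s: float = 2.0
    n_reps: int = 1
    fps: float = 30.0
    noise_px: float = 1.0
    defect: Defect = "none"
    defect_magnitude: float = 0.0
    dropout_prob: float = 0.0
    origin: tuple[float, float] = (320.0, 420.0)  # ankle-midpoint image position
    pixel_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("torso", "thigh", "shank", "shoulder_width", "hip_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.depth_deg <= 150.0):
            raise ValidationError(f"depth_deg must be in [0, 150], got {self.depth_deg}")
        if self.tempo_s <= 0:
            raise ValidationError("tempo_s must be positive")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.noise_px < 0:
            raise ValidationError("noise_px must be >= 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.defect_magnitude < 0:
            raise ValidationError("defect_magnitude must be >= 0")

    @property
    def n_frames(self) -> int:
        return round(self.n_reps * self.tempo_s * self.fps)

    @property
    def achieved_depth_deg(self) -> float:
        depth = self.depth_deg
        if self.defect == "shallow_depth":
            depth = max(0.0, depth - self.defect_magnitude)
        return depth

    @property
    def label(self) -> str:
        """Ground-truth label, a deterministic function of the parameters."""
        if self.defect == "none":
            return "correct"
        over = {
            "shallow_depth": self.achieved_depth_deg < SHALLOW_DEPTH_MIN_DEG,
            "knee_valgus": self.defect_magnitude > VALGUS_MAX_FRAC,
            "forward_lean": self.defect_magnitude > LEAN_MAX_DEG,
            "asymmetric": self.defect_magnitude > ASYMMETRY_MAX_DEG,
        }[self.defect]
        return "incorrect" if over else "correct"


@dataclass
class LabeledSequence:
    seq: SkeletonSequence
    label: str
    params: SquatSimParams
    subject: int = 0


def _flexion_profile(params: SquatSimParams) -> np.ndarray:
    """Per-frame knee-flexion angle (radians), cosine-eased, 0 at rep ends."""
    t = np.arange(params.n_frames) / params.fps
    phase = 2.0 * math.pi * t / params.tempo_s
    depth = math.radians(params.achieved_depth_deg)
    return depth * 0.5 * (1.0 - np.cos(phase))


def simulate_squat(params: SquatSimParams) -> LabeledSequence:
    """Generate one labeled squat clip. Deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    theta = _flexion_profile(params)  # symmetric flexion, radians
    peak = math.radians(params.achieved_depth_deg) or 1.0

    # Per-leg flexion; asymmetric defect splits it.
    split = math.radians(params.defect_magnitude) if params.defect == "asymmetric" else 0.0
    frac = np.clip(theta / peak, 0.0, 1.0)
    theta_l = np.clip(theta + 0.5 * split * frac, 0.0, None)
    theta_r = np.clip(theta - 0.5 * split * frac, 0.0, None)

    lean = math.radians(params.defect_magnitude) if params.defect == "forward_lean" else 0.0
    valgus = params.defect_magnitude if params.defect == "knee_valgus" else 0.0

    ox, oy = params.origin
    hw, sw = params.hip_width / 2.0, params.shoulder_width / 2.0
    xy = np.zeros((n, 10, 2))
    for t in range(n):
        cl, cr = math.cos(theta_l[t] / 2.0), math.cos(theta_r[t] / 2.0)
        # Ankles fixed on the ground line, hip-width apart.
        ankle_l = (ox - hw, oy)
        ankle_r = (ox + hw, oy)
        # Knees: vertically above the ankles, pulled medially by valgus.
        med = valgus * params.hip_width * frac[t]
        knee_l = (ox - hw + med, oy - params.shank * cl)
        knee_r = (ox + hw - med, oy - params.shank * cr)
        # Hips above the knees; mid-hip between them.
        hip_l = (ox - hw, knee_l[1] - params.thigh * cl)
        hip_r = (ox + hw, knee_r[1] - params.thigh * cr)
        mid_hip = ((hip_l[0] + hip_r[0]) / 2.0, (hip_l[1] + hip_r[1]) / 2.0)
        # Torso: forward lean is out-of-plane, seen frontally as foreshortening.
        torso_proj = params.torso * math.cos(lean * frac[t])
        neck = (mid_hip[0], mid_hip[1] - torso_proj)
        sh_l = (neck[0] - sw, neck[1])
        sh_r = (neck[0] + sw, neck[1])
        # Channel order: neck, mid_hip, L/R shoulder, L/R hip, L/R knee, L/R ankle.
        xy[t] = [neck, mid_hip, sh_l, sh_r, hip_l, hip_r, knee_l, knee_r, ankle_l, ankle_r]

    xy = (xy - (ox, oy)) * params.pixel_scale + (ox, oy)
    if params.noise_px > 0:
        xy = xy + rng.normal(0.0, params.noise_px * params.pixel_scale, xy.shape)
    conf = np.full((n, 10), 0.9)
    if params.dropout_prob > 0:
        conf[rng.random((n, 10)) < params.dropout_prob] = 0.0
    seq = SkeletonSequence.from_coords(xy, conf, fps=params.fps)
    return LabeledSequence(seq, params.label, params)


def measured_depth_deg(seq: SkeletonSequence) -> float:
    """Recover peak knee flexion from generated coordinates.

    Uses the left leg's knee-to-hip vertical extent: standing it equals the
    thigh length; at flexion theta it is thigh*cos(theta/2), so
    theta = 2*acos(extent_peak / extent_standing). Independent of the
    simulator's internals — usable as an oracle on its output.
    """
    xy, _ = seq.coords()
    hip_y, knee_y = xy[:, 4, 1], xy[:, 6, 1]  # l_hip, l_knee
    extent = knee_y - hip_y
    standing = float(np.max(extent))
    ratio = np.clip(extent / standing, -1.0, 1.0)
    return float(np.degrees(2.0 * np.arccos(np.min(ratio))))


def simulate_dataset(
    n_per_class: int,
    correct_params: SquatSimParams | None = None,
    incorrect_params: SquatSimParams | None = None,
    seed: int = 0,
    n_subjects: int = 20,
    depth_jitter_deg: float = 5.0,
) -> list[LabeledSequence]:
    """Balanced labeled dataset with inter-subject nuisance variation.

    Sequences are assigned round-robin to ``n_subjects`` synthetic subjects;
    each subject has its own segment lengths (+-10%), tempo (+-20%), global
    image position and scale, shared across that subject's clips so that a
    subject-wise split is meaningful. Per-clip peak depth additionally
    jitters by ``+-depth_jitter_deg`` (uniform). Deterministic given seed.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    correct_params = correct_params or SquatSimParams(defect="none", depth_deg=95.0)
    incorrect_params = incorrect_params or SquatSimParams(
        defect="shallow_depth", depth_deg=95.0, defect_magnitude=50.0
    )
    rng = np.random.default_rng(seed)

    subjects = []
    for _ in range(n_subjects):
        subjects.append(
            dict(
                torso=160.0 * rng.uniform(0.9, 1.1),
                thigh=130.0 * rng.uniform(0.9, 1.1),
                shank=120.0 * rng.uniform(0.9, 1.1),
                shoulder_width=110.0 * rng.uniform(0.9, 1.1),
                hip_width=80.0 * rng.uniform(0.9, 1.1),
                tempo_s=2.0 * rng.uniform(0.8, 1.2),
                origin=(320.0 + rng.uniform(-80, 80), 420.0 + rng.uniform(-40, 40)),
                pixel_scale=rng.uniform(0.8, 1.25),
            )
        )

    out: list[LabeledSequence] = []
    for c, base in enumerate((correct_params, incorrect_params)):
        for i in range(n_per_class):
            subject = (2 * i + c) % n_subjects
            depth = base.depth_deg + rng.uniform(-depth_jitter_deg, depth_jitter_deg)
            p = replace(
                base,
                depth_deg=float(np.clip(depth, 0.0, 150.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
                **subjects[subject],
            )
            labeled = simulate_squat(p)
            labeled.subject = subject
            out.append(labeled)
    return out


def write_dataset(dataset: list[LabeledSequence], out_dir: str | Path) -> Path:
    """Write clips as single-stream JSON plus a labels CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "labels.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sequence", "label", "defect", "magnitude", "subject", "seed"])
        for i, item in enumerate(dataset):
            name = f"squat_{i:04d}.json"
            write_pose_json(item.seq, out_dir / name)
            w.writerow(
                [
                    name,
                    item.label,
                    item.params.defect,
                    item.params.defect_magnitude,
                    item.subject,
                    item.params.seed,
                ]
            )
    return csv_path
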