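"""App-side decision layer: thresholded pass/fail verdicts and session scoring.

A repetition passes ("good") when its softmax correct-posture score reaches
the configured threshold; a session of N repetitions (10 by default, as in
screening protocols that admit participants scoring fewer than 3 goods out
of 10) is summarized as the count of goods. A repetition that cannot be
preprocessed or is too short to classify counts as bad, with a warning, so
a session score always exists.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import EmptyInputError, SquatCheckError, ValidationError
from .keypoint_io import SkeletonSequence, read_pose_json
from .model import TrainedModel, classify
from .preprocessing import PreprocessConfig, preprocess

logger = logging.getLogger("squatcheck")


@dataclass(frozen=True)
class FeedbackConfig:
    """Score threshold and session length.

    Boundary convention: a score exactly at the threshold is "good".
    """

    threshold: float = 0.5
    session_reps: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.session_reps < 1:
            raise ValidationError("session_reps must be >= 1")


@dataclass
class SessionScore:
    """Per-repetition scores/verdicts and the session's good count."""

    n_good: int
    n_total: int
    per_rep: list[dict] = field(default_factory=list)


def verdict(score: float, cfg: FeedbackConfig | None = None) -> str:
    """"good" iff score >= threshold."""
    cfg = cfg or FeedbackConfig()
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must be in [0, 1], got {score}")
    return "good" if score >= cfg.threshold else "bad"


def score_session(
    seqs: Sequence[SkeletonSequence],
    model: TrainedModel,
    cfg: FeedbackConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> SessionScore:
    """Classify every repetition and count the goods.

    Unprocessable repetitions (too short, too many dropouts, ...) are scored
    0.0 and counted bad, with a logged warning.
    """
    cfg = cfg or FeedbackConfig()
    if not seqs:
        raise EmptyInputError("no repetitions to score")
    per_rep: list[dict] = []
    for i, seq in enumerate(seqs):
        try:
            feats = preprocess(seq, pre_cfg)
            score = classify(model, feats)
            v = verdict(score, cfg)
            per_rep.append({"rep": i, "score": score, "verdict": v, "error": None})
        except SquatCheckError as e:
            logger.warning("repetition %d unclassifiable (%s); counted bad", i, e)
            per_rep.append({"rep": i, "score": 0.0, "verdict": "bad", "error": str(e)})
    n_good = sum(1 for r in per_rep if r["verdict"] == "good")
    return SessionScore(n_good=n_good, n_total=len(per_rep), per_rep=per_rep)


def _config_hash(*objs) -> str:
    return hashlib.sha256(
        json.dumps(objs, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(
    inputs: str | Path | Sequence[str | Path],
    model: TrainedModel,
    cfg: FeedbackConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    dialect: str = "single_stream",
) -> dict:
    """End-to-end: load -> preprocess -> classify -> verdict -> session score.

    ``inputs`` is a directory of per-repetition JSON files, or a list of
    files. Returns a JSON-serializable report with per-rep scores, verdicts,
    session totals and a config echo; deterministic for fixed inputs/config.
    """
    cfg = cfg or FeedbackConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    if isinstance(inputs, (str, Path)):
        p = Path(inputs)
        files = sorted(p.glob("*.json")) if p.is_dir() else [p]
        files = [f for f in files if f.name != "labels.csv"]
    else:
        files = [Path(f) for f in inputs]
    if not files:
        raise EmptyInputError(f"no pose JSON files in {inputs}")
    seqs = []
    for f in files:
        logger.info("loading %s", f)
        seqs.append(read_pose_json(f, dialect=dialect))
    session = score_session(seqs, model, cfg, pre_cfg)
    report = {
        "files": [str(f) for f in files],
        "per_rep": session.per_rep,
        "n_good": session.n_good,
        "n_total": session.n_total,
        "config": {
            "threshold": cfg.threshold,
            "session_reps": cfg.session_reps,
            "sigma": pre_cfg.sigma,
            "ref_window": pre_cfg.ref_window,
            "variant": model.config.variant,
        },
        "config_hash": _config_hash(
            cfg.threshold, cfg.session_reps, pre_cfg.sigma, pre_cfg.ref_window
        ),
    }
    return report


def format_session(report: dict) -> str:
    """Human-readable session summary."""
    lines = [f"{'rep':>4} {'score':>8}  verdict"]
    for r in report["per_rep"]:
        note = f"  ({r['error']})" if r["error"] else ""
        lines.append(f"{r['rep']:>4} {r['score']:>8.4f}  {r['verdict']}{note}")
    lines.append(
        f"session: {report['n_good']}/{report['n_total']} good "
        f"at threshold {report['config']['threshold']}"
    )
    return "\n".join(lines)
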