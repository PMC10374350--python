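"""Per-polyp decision protocol: up to three captures, traffic-light feedback.

Each capture runs the chain detect -> localization gate -> quality gate ->
BoVW characterization -> confidence tier, and is answered with:

* green  — high-confidence diagnosis (max posterior >= 0.50); the session is
           finalized immediately with that diagnosis;
* orange — low-confidence diagnosis (max posterior >= 0.33); another capture
           may be taken;
* red    — the image could not be used (localization not accepted, or quality
           gate failed); another capture may be taken.

After three captures without a green outcome, the session must stop: the
final diagnosis is the low-confidence (orange) capture with the highest
prediction score (earliest capture on ties); if no capture produced any class
scores, the session is a *failure* of the system. The success rate over a set
of sessions is the fraction of non-failures, with an exact binomial CI.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import bovw, localization, quality
from .bovw import BovwModel, ClassScores

MAX_CAPTURES = 3


class ProtocolError(RuntimeError):
    """A capture or finalization violated the protocol state machine."""


@dataclass(frozen=True)
class CaptureOutcome:
    signal: str    # green | orange | red
    reason: str    # localization_failed | quality_failed | low_confidence | high_confidence
    scores: ClassScores | None = None

    def __post_init__(self) -> None:
        ok = {("green", "high_confidence"), ("orange", "low_confidence"),
              ("red", "localization_failed"), ("red", "quality_failed")}
        if (self.signal, self.reason) not in ok:
            raise ValueError(f"inconsistent outcome {(self.signal, self.reason)}")
        if (self.scores is None) == (self.signal != "red"):
            raise ValueError("scores must be present iff the classifier ran")


@dataclass(frozen=True)
class FinalDiagnosis:
    diagnosis: str
    tier: str      # high | low


@dataclass
class PolypSession:
    """Protocol state for one polyp; ``final`` is set exactly once."""

    polyp_id: str
    captures: list[CaptureOutcome] = field(default_factory=list)
    final: FinalDiagnosis | None = None
    _finalized: bool = False

    @property
    def is_final(self) -> bool:
        return self._finalized

    @property
    def failed(self) -> bool:
        return self._finalized and self.final is None

    @property
    def images_used(self) -> int:
        return len(self.captures)


def record_outcome(session: PolypSession, outcome: CaptureOutcome) -> CaptureOutcome:
    """Append one capture outcome and advance the state machine.

    Green finalizes immediately; the third capture forces finalization.
    """
    if session.is_final:
        raise ProtocolError("session already finalized")
    if len(session.captures) >= MAX_CAPTURES:
        raise ProtocolError(f"at most {MAX_CAPTURES} captures per polyp")
    session.captures.append(outcome)
    if outcome.signal == "green" or len(session.captures) == MAX_CAPTURES:
        finalize(session)
    return outcome


def finalize(session: PolypSession) -> FinalDiagnosis | None:
    """Apply the final-diagnosis rule; returns None on failure.

    A green capture wins at high confidence; otherwise the orange capture with
    the highest prediction score (earliest on ties) wins at low confidence;
    with no scored capture at all the session is a failure.
    """
    if session.is_final:
        return session.final
    greens = [c for c in session.captures if c.signal == "green"]
    if not greens and len(session.captures) < MAX_CAPTURES:
        raise ProtocolError("cannot finalize before a green capture or three captures")
    if greens:
        session.final = FinalDiagnosis(greens[0].scores.top_class, "high")
    else:
        oranges = [c for c in session.captures if c.signal == "orange"]
        if oranges:
            best = max(oranges, key=lambda c: c.scores.max_score)  # max keeps first on ties
            session.final = FinalDiagnosis(best.scores.top_class, "low")
        else:
            session.final = None
    session._finalized = True
    return session.final


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the per-capture chain needs besides the trained model."""

    detector: localization.DetectorConfig = field(default_factory=localization.DetectorConfig)
    localization_threshold: float = localization.DEFAULT_LOCALIZATION_THRESHOLD
    quality: quality.QualityConfig = field(default_factory=quality.QualityConfig)


def classify_capture(image: np.ndarray, model: BovwModel,
                     config: PipelineConfig = PipelineConfig()) -> CaptureOutcome:
    """Run the full chain on one image and emit the first failing stage."""
    loc = localization.detect(image, config.detector)
    if not localization.accept_localization(loc, config.localization_threshold):
        return CaptureOutcome("red", "localization_failed")
    report = quality.check_quality(image, loc.box, config.quality)
    if not report.passed:
        return CaptureOutcome("red", "quality_failed")
    scores = model.predict_image(image, loc.box)
    if scores.tier == "high":
        return CaptureOutcome("green", "high_confidence", scores)
    return CaptureOutcome("orange", "low_confidence", scores)


def process_capture(session: PolypSession, image: np.ndarray, model: BovwModel,
                    config: PipelineConfig = PipelineConfig()) -> CaptureOutcome:
    """Process one capture within a session (protocol-checked)."""
    if session.is_final:
        raise ProtocolError("session already finalized")
    return record_outcome(session, classify_capture(image, model, config))


def run_session(polyp_id: str, images, model: BovwModel,
                config: PipelineConfig = PipelineConfig()) -> PolypSession:
    """Feed captures from an iterable until the session finalizes (or the
    supply of images runs out, in which case the remaining captures count as
    never taken and the session finalizes on what it has, per the three-image
    rule only if three were taken)."""
    session = PolypSession(polyp_id)
    for img in images:
        process_capture(session, img, model, config)
        if session.is_final:
            break
    return session


@dataclass(frozen=True)
class SuccessRate:
    proportion: float
    ci: tuple[float, float]
    n_success: int
    n: int
    images_needed: Counter         # images used per *successful* session


def success_rate(sessions, ci_alpha: float = 0.05) -> SuccessRate:
    """Fraction of sessions with a (high- or low-confidence) final diagnosis,
    with an exact Clopper-Pearson CI, plus the 1/2/3-image distribution."""
    sessions = list(sessions)
    if not sessions:
        raise ValueError("success_rate requires at least one session")
    if any(not s.is_final for s in sessions):
        raise ValueError("all sessions must be finalized")
    n = len(sessions)
    succ = [s for s in sessions if not s.failed]
    lo, hi = proportion_confint(len(succ), n, alpha=ci_alpha, method="beta")
    return SuccessRate(proportion=len(succ) / n, ci=(float(lo), float(hi)),
                       n_success=len(succ), n=n,
                       images_needed=Counter(s.images_used for s in succ))
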