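"""Assisted-review grading: CTR_diff, the excellent/good/poor scheme and the
combined-two-model mode.

In assisted use a reader is shown the model's CTR lines and either accepts
them unchanged or adjusts.  A result is *excellent* when it is accepted as-is
by every reader, *good* when any adjustment is needed, and *poor* when
segmentation failed outright and the case falls back to manual measurement.
Empirically, accepted results sit within ±1.8% of the reader's own value, so
validation grading uses that band on CTR_diff — the signed percentage
difference between the model CTR and the reference CTR:

    CTR_diff = 100 · (ctr_model − ctr_reference) / ctr_reference

The band edge is inclusive (|CTR_diff| = 1.8% grades excellent).

In combined mode two models are presented and the one with the smaller
|CTR_diff| is kept (ties break to model A, deterministically).  Since
min(|dA|, |dB|) ≤ |dA|, the combined excellent yield can never fall below
either single-model yield — the dominance that makes two mediocre models
worth pairing.

:func:`simulate_session` replaces live readers with a scripted oracle: each
simulated reader accepts a presented result iff it lies within the band of
that reader's own (Gaussian-jittered) reference.  It is an explicit
simplification — real readers can accept outside the band or fiddle inside
it — and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError

__all__ = [
    "Grade",
    "GradingRecord",
    "CaseMeasurement",
    "ReviewerOracle",
    "SessionSummary",
    "ctr_diff",
    "grade_single",
    "grade_combined",
    "simulate_session",
    "records_to_frame",
]

EXCELLENT_BAND = 1.8  # percent half-width of the acceptance range


class Grade:
    EXCELLENT = "excellent"
    GOOD = "good"
    POOR = "poor"


@dataclass
class CaseMeasurement:
    """Per-case inputs to grading: reference CTR plus up to two model CTRs."""

    identifier: str
    ctr_reference: float
    ctr_model_a: float | None = None
    ctr_model_b: float | None = None
    processing_time_s: float = 0.0


@dataclass
class GradingRecord:
    identifier: str
    ctr_reference: float
    ctr_model_a: float | None
    ctr_model_b: float | None
    ctr_diff_a: float | None
    ctr_diff_b: float | None
    selected_model: str       # "a", "b" or "none"
    grade: str
    adjusted: bool
    processing_time_s: float = 0.0


def ctr_diff(ctr_ai: float, ctr_reference: float) -> float:
    """Signed percentage difference of a model CTR against the reference."""
    if ctr_reference <= 0:
        raise ContractError(f"reference CTR must be positive, got {ctr_reference}")
    return 100.0 * (ctr_ai - ctr_reference) / ctr_reference


def grade_single(
    ctr_ai: float | None,
    ctr_reference: float,
    band: float = EXCELLENT_BAND,
) -> str:
    """Excellent if |CTR_diff| <= band (inclusive), poor if the model failed."""
    if ctr_ai is None:
        return Grade.POOR
    return Grade.EXCELLENT if abs(ctr_diff(ctr_ai, ctr_reference)) <= band else Grade.GOOD


def grade_combined(
    case: CaseMeasurement,
    band: float = EXCELLENT_BAND,
) -> GradingRecord:
    """Grade with up-to-two models; keep the one with the smaller |CTR_diff|.

    Poor only when both models failed.  Ties select model A.
    """
    ref = case.ctr_reference
    if ref <= 0:
        raise ContractError(f"reference CTR must be positive, got {ref}")
    da = None if case.ctr_model_a is None else ctr_diff(case.ctr_model_a, ref)
    db = None if case.ctr_model_b is None else ctr_diff(case.ctr_model_b, ref)

    if da is None and db is None:
        selected, grade, adjusted = "none", Grade.POOR, True
    else:
        if db is None or (da is not None and abs(da) <= abs(db)):
            selected, d = "a", da
        else:
            selected, d = "b", db
        grade = Grade.EXCELLENT if abs(d) <= band else Grade.GOOD
        adjusted = grade != Grade.EXCELLENT
    return GradingRecord(
        identifier=case.identifier,
        ctr_reference=ref,
        ctr_model_a=case.ctr_model_a,
        ctr_model_b=case.ctr_model_b,
        ctr_diff_a=da,
        ctr_diff_b=db,
        selected_model=selected,
        grade=grade,
        adjusted=adjusted,
        processing_time_s=case.processing_time_s,
    )


@dataclass(frozen=True)
class ReviewerOracle:
    """A scripted reader: accepts iff the result is within ``acceptance_band``
    percent of the reader's own reference, which is the nominal reference
    perturbed by Gaussian ``jitter_sd`` percent (per reader, per case)."""

    acceptance_band: float = EXCELLENT_BAND
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acceptance_band <= 0:
            raise ParameterError("acceptance_band must be positive")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


@dataclass
class SessionSummary:
    n: int
    per_reviewer_excellent_pct: list[float]
    joint_excellent_pct: float
    good_pct: float
    poor_pct: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"reviewer": f"reviewer{i + 1}", "excellent_pct": p}
            for i, p in enumerate(self.per_reviewer_excellent_pct)
        ]
        rows.append({"reviewer": "joint", "excellent_pct": self.joint_excellent_pct})
        return pd.DataFrame(rows)


def simulate_session(
    cases: Sequence[CaseMeasurement],
    oracle: ReviewerOracle,
    reviewers: int = 2,
    band: float | None = None,
) -> tuple[list[GradingRecord], SessionSummary]:
    """Run a scripted review session over a cohort of measured cases.

    The presented result per case is the combined-mode selection (smaller
    |CTR_diff| against the nominal reference).  Each reviewer independently
    accepts it iff it lies within the oracle band of their jittered
    reference; a record is excellent only when all reviewers accept, good if
    any would adjust, and poor grades propagate unchanged.  With zero jitter
    and one reviewer the session reduces exactly to :func:`grade_combined`.
    """
    if reviewers < 1:
        raise ParameterError(f"need at least one reviewer, got {reviewers}")
    if not cases:
        raise ContractError("cohort must be non-empty")
    band = oracle.acceptance_band if band is None else band
    rng = np.random.default_rng(oracle.seed)
    jitter = rng.normal(0.0, oracle.jitter_sd, size=(reviewers, len(cases)))

    records: list[GradingRecord] = []
    accept = np.zeros((reviewers, len(cases)), dtype=bool)
    poor = np.zeros(len(cases), dtype=bool)
    for j, case in enumerate(cases):
        rec = grade_combined(case, band=band)
        if rec.grade == Grade.POOR:
            poor[j] = True
            records.append(rec)
            continue
        presented = case.ctr_model_a if rec.selected_model == "a" else case.ctr_model_b
        for r in range(reviewers):
            ref_r = case.ctr_reference * (1.0 + jitter[r, j] / 100.0)
            accept[r, j] = abs(ctr_diff(presented, ref_r)) <= band
        all_accept = bool(accept[:, j].all())
        rec.grade = Grade.EXCELLENT if all_accept else Grade.GOOD
        rec.adjusted = not all_accept
        records.append(rec)

    n = len(cases)
    measurable = ~poor
    per_reviewer = [100.0 * float((accept[r] & measurable).mean()) for r in range(reviewers)]
    joint = 100.0 * float((accept.all(axis=0) & measurable).mean())
    good = 100.0 * float(sum(r.grade == Grade.GOOD for r in records)) / n
    poor_pct = 100.0 * float(poor.mean())
    return records, SessionSummary(
        n=n,
        per_reviewer_excellent_pct=per_reviewer,
        joint_excellent_pct=joint,
        good_pct=good,
        poor_pct=poor_pct,
    )


def records_to_frame(records: Sequence[GradingRecord]) -> pd.DataFrame:
    """Flatten grading records to a DataFrame for CSV export."""
    return pd.DataFrame([vars(r) for r in records])
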