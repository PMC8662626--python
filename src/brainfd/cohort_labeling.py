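"""CDR windowing rules and cross-sectional cohort assembly.

MRI sessions and Clinical Dementia Rating (CDR) assessments happen on
different days, so each MRI session is assigned a CDR score by rule:

1. ``between_equal`` — the MRI day lies between two CDR assessments with
   the same score: that score is assigned, at any distance.
2. ``nearest_within_window`` — the MRI day lies between two assessments
   with different scores: the nearer one's score is assigned, but only if
   its distance is at most the window (default 45 days); equidistant
   different scores are undecidable and the session is dropped.
3. ``single_within_window`` — only one assessment exists on one side: its
   score is assigned if within the window, else the session is dropped.

The cross-sectional cohort then keeps exactly one labeled session per
subject (earliest by default) and maps CDR to a class: 0 → control,
>= ``dementia_min`` (default 1, i.e. at least mild dementia) → dementia.
CDR 0.5 falls in neither class under the defaults and is excluded; the
thresholds are explicit configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_sessions import SessionRecord

logger = logging.getLogger("brainfd")

#: Valid CDR staging scores.
CDR_SCORES = (0.0, 0.5, 1.0, 2.0, 3.0)

#: Default maximum distance (days) between MRI and CDR assessment.
DEFAULT_WINDOW_DAYS = 45

RULE_BETWEEN_EQUAL = "between_equal"
RULE_NEAREST = "nearest_within_window"
RULE_SINGLE = "single_within_window"

CONTROL = "control"
DEMENTIA = "dementia"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class CDRRecord:
    """One CDR assessment: subject, day since study entry, staging score."""

    subject_id: str
    day: int
    score: float

    def __post_init__(self) -> None:
        if self.score not in CDR_SCORES:
            raise ValueError(f"CDR score must be one of {CDR_SCORES}, got {self.score}")
        if self.day < 0:
            raise ValueError("day must be non-negative")


@dataclass(frozen=True)
class LabeledSession:
    """An MRI session with its assigned CDR and the rule that assigned it."""

    session: SessionRecord
    cdr: float
    rule_applied: str


@dataclass(frozen=True)
class DroppedSession:
    """A session no rule could label, with the reason."""

    session: SessionRecord
    reason: str


def assign_cdr(
    session: SessionRecord,
    cdr_history: list[CDRRecord],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> LabeledSession | DroppedSession:
    """Apply the windowing rules to one MRI session.

    ``cdr_history`` must belong to the session's subject. Enlarging the
    window never turns a labeled session into a dropped one: the between-
    equal rule ignores the window entirely, and the other rules only
    compare fixed distances against it.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    history = sorted(
        (r for r in cdr_history if r.subject_id == session.subject_id),
        key=lambda r: r.day,
    )
    if not history:
        return DroppedSession(session=session, reason="no_cdr")

    before = [r for r in history if r.day <= session.day]
    after = [r for r in history if r.day >= session.day]
    prev = before[-1] if before else None
    nxt = after[0] if after else None

    if prev is not None and nxt is not None:
        if prev.score == nxt.score:
            return LabeledSession(session, prev.score, RULE_BETWEEN_EQUAL)
        d_prev = session.day - prev.day
        d_next = nxt.day - session.day
        if d_prev == d_next:
            return DroppedSession(session, reason="equidistant_conflict")
        nearer, dist = (prev, d_prev) if d_prev < d_next else (nxt, d_next)
        if dist <= window_days:
            return LabeledSession(session, nearer.score, RULE_NEAREST)
        return DroppedSession(session, reason="window_exceeded")

    only = prev if prev is not None else nxt
    assert only is not None
    if abs(session.day - only.day) <= window_days:
        return LabeledSession(session, only.score, RULE_SINGLE)
    return DroppedSession(session, reason="window_exceeded")


@dataclass(frozen=True)
class ClassPolicy:
    """CDR → class mapping: control at ``control_cdr``, dementia at or
    above ``dementia_min``; anything between is excluded."""

    control_cdr: float = 0.0
    dementia_min: float = 1.0

    def classify(self, cdr: float) -> str:
        if cdr == self.control_cdr:
            return CONTROL
        if cdr >= self.dementia_min:
            return DEMENTIA
        return EXCLUDED


def build_cohort(
    sessions: list[LabeledSession | DroppedSession],
    policy: ClassPolicy | None = None,
) -> pd.DataFrame:
    """One-session-per-subject cross-sectional cohort.

    Keeps the earliest labeled session of each subject (removing repeated
    sessions deletes the within-subject factor), applies the class policy,
    and excludes subjects whose CDR maps to neither class (logged).
    Columns: subject_id, session_id, day, cdr, rule_applied, class.
    """
    policy = policy or ClassPolicy()
    labeled = [s for s in sessions if isinstance(s, LabeledSession)]
    rows = []
    for s in sorted(labeled, key=lambda s: (s.session.subject_id, s.session.day)):
        if rows and rows[-1]["subject_id"] == s.session.subject_id:
            continue
        rows.append(
            {
                "subject_id": s.session.subject_id,
                "session_id": s.session.session_id,
                "day": s.session.day,
                "cdr": s.cdr,
                "rule_applied": s.rule_applied,
                "class": policy.classify(s.cdr),
            }
        )
    df = pd.DataFrame(
        rows, columns=["subject_id", "session_id", "day", "cdr", "rule_applied", "class"]
    )
    n_excluded = int((df["class"] == EXCLUDED).sum()) if len(df) else 0
    if n_excluded:
        logger.info(
            "%d subject(s) excluded: CDR maps to neither class under %s",
            n_excluded,
            policy,
        )
    return df[df["class"] != EXCLUDED].reset_index(drop=True)


def label_sessions_table(
    sessions: list[SessionRecord],
    cdr_table: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
    policy: ClassPolicy | None = None,
) -> pd.DataFrame:
    """Label every MRI session from a CDR table (subject_id, day, cdr).

    Returns one row per input session with columns cdr, class,
    rule_applied, drop_reason (NaN where not applicable); dropped sessions
    are kept in the output so the attrition is auditable.
    """
    policy = policy or ClassPolicy()
    by_subject: dict[str, list[CDRRecord]] = {}
    for row in cdr_table.itertuples(index=False):
        rec = CDRRecord(str(row.subject_id), int(row.day), float(row.cdr))
        by_subject.setdefault(rec.subject_id, []).append(rec)
    rows = []
    for session in sessions:
        result = assign_cdr(
            session, by_subject.get(session.subject_id, []), window_days
        )
        row = {
            "subject_id": session.subject_id,
            "session_id": session.session_id,
            "day": session.day,
        }
        if isinstance(result, LabeledSession):
            row.update(
                cdr=result.cdr,
                **{"class": policy.classify(result.cdr)},
                rule_applied=result.rule_applied,
                drop_reason=None,
            )
        else:
            row.update(cdr=None, **{"class": None}, rule_applied=None,
                       drop_reason=result.reason)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "session_id", "day", "cdr", "class",
            "rule_applied", "drop_reason",
        ],
    )
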