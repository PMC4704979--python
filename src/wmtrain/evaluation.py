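"""Outcome statistics: adherence summaries and the usability questionnaire.

The 9-item disposability-to-use questionnaire mixes five yes/no items
(Q1–Q5: readiness after the practice session, independence at home,
interest, usefulness, motivation to use the system again) and four 4-point
Likert items (Q6–Q9: motivation, stress, boredom and amusement while
exercising, answered 1 = "Not at all", 2 = "Low", 3 = "Medium",
4 = "High").

Yes/no items are summarised as exact counts with half-up integer
percentages; Likert items as arithmetic mean with the standard error of the
mean (sample standard deviation, n−1 denominator, over √n).  Adherence is
delegated to :mod:`wmtrain.scheduler` and applied to cohort means, so a
cohort completing on average 33.4 of 40 scheduled sessions reports 84%.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .scheduler import (
    Program,
    adherence_percent,
    inclusion_threshold_sessions,
    round_half_up,
)

__all__ = [
    "YESNO_QUESTIONS",
    "LIKERT_QUESTIONS",
    "LIKERT_LABELS",
    "read_questionnaire",
    "summarize_yesno",
    "summarize_likert",
    "summarize_questionnaire",
    "adherence_summary",
    "AdherenceSummary",
    "simulate_questionnaire",
]

YESNO_QUESTIONS = ("q1", "q2", "q3", "q4", "q5")
LIKERT_QUESTIONS = ("q6", "q7", "q8", "q9")
LIKERT_LABELS = {1: "Not at all", 2: "Low", 3: "Medium", 4: "High"}

_TRUTHY = {"yes", "y", "true", "1"}
_FALSY = {"no", "n", "false", "0"}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise InputError(f"cannot interpret {value!r} as a yes/no answer")


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    """Read a TSV of responses (columns ``patient_id``, ``q1``..``q9``)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in ("patient_id",) + YESNO_QUESTIONS + LIKERT_QUESTIONS
               if c not in df.columns]
    if missing:
        raise InputError(f"questionnaire file lacks columns: {missing}")
    for q in YESNO_QUESTIONS:
        df[q] = df[q].map(_as_bool)
    for q in LIKERT_QUESTIONS:
        vals = df[q].astype(int)
        if not vals.isin([1, 2, 3, 4]).all():
            raise InputError(f"{q} answers must lie in 1..4")
        df[q] = vals
    return df


def summarize_yesno(responses: pd.DataFrame, question: str) -> tuple[int, int, int]:
    """``(count_yes, n, percent)`` for one yes/no item (half-up percent)."""
    if question not in YESNO_QUESTIONS:
        raise InputError(f"{question!r} is not a yes/no item")
    answers = [_as_bool(v) for v in responses[question]]
    n = len(answers)
    if n < 1:
        raise InputError("need at least one response")
    count = sum(answers)
    percent = round_half_up(Fraction(100 * count, n))
    return count, n, percent


def summarize_likert(responses: pd.DataFrame, question: str) -> tuple[float, float]:
    """``(mean, standard_error)`` for one Likert item.

    SE is the sample (n−1) standard deviation divided by √n.
    """
    if question not in LIKERT_QUESTIONS:
        raise InputError(f"{question!r} is not a Likert item")
    values = np.asarray(responses[question], dtype=float)
    if len(values) < 2:
        raise InputError("need at least two responses for a standard error")
    if not np.isin(values, [1, 2, 3, 4]).all():
        raise InputError(f"{question} answers must lie in 1..4")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values)))
    return mean, se


def summarize_questionnaire(responses: pd.DataFrame) -> pd.DataFrame:
    """One summary row per item: counts/percent or mean/SE."""
    rows = []
    for q in YESNO_QUESTIONS:
        count, n, pct = summarize_yesno(responses, q)
        rows.append({"question": q, "kind": "yes/no", "count_yes": count,
                     "n": n, "percent": pct, "mean": None, "se": None})
    for q in LIKERT_QUESTIONS:
        mean, se = summarize_likert(responses, q)
        rows.append({"question": q, "kind": "likert", "count_yes": None,
                     "n": len(responses), "percent": None,
                     "mean": round(mean, 2), "se": round(se, 2)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AdherenceSummary:
    mean_sessions: float
    adherence_percent: int
    threshold_sessions: int
    included: tuple[str, ...]
    excluded: tuple[str, ...]


def adherence_summary(
    histories: Mapping[str, int] | Iterable,
    program: Program,
    inclusion_fraction: float = 80.0,
) -> AdherenceSummary:
    """Cohort adherence: mean completed sessions, percent, inclusion filter.

    ``histories`` maps patient id → completed session count, or is an
    iterable of per-patient session-log lists / counts (patients are then
    named by position).
    """
    if isinstance(histories, Mapping):
        counts = {str(k): _count(v) for k, v in histories.items()}
    else:
        counts = {f"patient-{i + 1}": _count(v) for i, v in enumerate(histories)}
    if not counts:
        raise InputError("histories must not be empty")
    n = len(counts)
    mean = Fraction(sum(counts.values()), n)
    threshold = inclusion_threshold_sessions(program, inclusion_fraction)
    included = tuple(pid for pid, c in counts.items() if c >= threshold)
    excluded = tuple(pid for pid, c in counts.items() if c < threshold)
    return AdherenceSummary(
        mean_sessions=float(mean),
        adherence_percent=adherence_percent(mean, program),
        threshold_sessions=threshold,
        included=included,
        excluded=excluded,
    )


def _count(value) -> int:
    if isinstance(value, (int, np.integer)):
        return int(value)
    if hasattr(value, "sessions"):  # a responder History
        return len(value.sessions)
    return len(value)  # a list of session logs


def simulate_questionnaire(
    n: int,
    yes_probabilities: Mapping[str, float] | None = None,
    likert_probabilities: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic response table (for desk-scale cohort studies).

    Yes/no items are Bernoulli; Likert items are categorical over 1..4 with
    the given probabilities (uniform by default).
    """
    if n < 1:
        raise InputError("need at least one simulated respondent")
    rng = np.random.default_rng(seed)
    data: dict[str, list] = {"patient_id": [f"sim-{i + 1:03d}" for i in range(n)]}
    for q in YESNO_QUESTIONS:
        p = (yes_probabilities or {}).get(q, 0.5)
        data[q] = (rng.random(n) < p).tolist()
    for q in LIKERT_QUESTIONS:
        probs = np.asarray((likert_probabilities or {}).get(q, [0.25] * 4), dtype=float)
        if len(probs) != 4 or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise InputError(f"likert probabilities for {q} must be 4 values summing to 1")
        data[q] = rng.choice([1, 2, 3, 4], size=n, p=probs).tolist()
    return pd.DataFrame(data)
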