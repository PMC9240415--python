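"""Global-coherence scoring of discourse transcripts.

Each participant's response to a discourse task (picture description,
storytelling, procedural) is reduced to its content words, composed into a
single LSA vector, and compared by cosine with a *prototype* vector — the
mean of control participants' response vectors for the same task. Controls
are scored against a leave-one-out prototype (their own response excluded)
to keep score and prototype independent. The cosine is the global-coherence
score: how closely a response tracks the semantic content typically produced
for that stimulus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .semantic_space import MISSING, SemanticSpace
from .stoplist import DEFAULT_STOPLIST

__all__ = [
    "TASKS",
    "ResponseRecord",
    "PrototypeVector",
    "preprocess",
    "compose_response_vector",
    "composite_prototype",
    "global_coherence",
    "score_cohort",
    "flag_deficit",
    "deficit_cutoff",
]

logger = logging.getLogger(__name__)

TASKS = ("picture_description", "storytelling", "procedural")
GROUPS = ("control", "patient")

# split on non-alphabetic characters, keep intra-word apostrophes;
# numerals are dropped (not content words in these tasks)
_TOKEN_RE = re.compile(r"[a-z]+(?:'[a-z]+)*")


@dataclass
class ResponseRecord:
    """One participant x task transcript and its derived vector."""

    participant_id: str
    group: str
    task: str
    raw_text: str
    content_tokens: list[str] = field(default_factory=list)
    response_vector: np.ndarray | None = None
    n_oov: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; allowed: {GROUPS}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; allowed: {TASKS}")


@dataclass
class PrototypeVector:
    """Mean of control response vectors for one task."""

    task: str
    vector: np.ndarray
    n_contributors: int
    excluded_id: str | None = None


def preprocess(raw_text: str, stoplist: Iterable[str] = DEFAULT_STOPLIST) -> list[str]:
    """Lowercase, strip punctuation/numerals, drop stoplisted function words.

    Token order is preserved for audit although downstream composition is
    order-invariant. Empty text yields an empty list.
    """
    stop = set(stoplist)
    tokens = _TOKEN_RE.findall(raw_text.lower())
    return [t for t in tokens if t not in stop]


def compose_response_vector(
    tokens: Sequence[str], space: SemanticSpace, mode: str = "instance"
) -> np.ndarray | None:
    """Compose a single response vector as the mean of token vectors.

    ``mode="instance"`` (default) averages over token instances — a word
    occurring twice contributes twice; ``mode="type"`` averages over distinct
    word types. Returns None when no token is in the space's vocabulary.
    """
    if mode not in ("instance", "type"):
        raise ValueError("mode must be 'instance' or 'type'")
    if mode == "type":
        tokens = list(dict.fromkeys(t.lower() for t in tokens))
    vecs = [v for v in (space.get_vector(t) for t in tokens) if v is not MISSING]
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


def composite_prototype(
    responses: Sequence[ResponseRecord], exclude_id: str | None = None
) -> PrototypeVector:
    """Mean of control response vectors for one task, optionally excluding
    one participant (leave-one-out for control scoring)."""
    tasks = {r.task for r in responses}
    if len(tasks) != 1:
        raise ValueError(f"responses span multiple tasks: {sorted(tasks)}")
    contributors = [
        r
        for r in responses
        if r.group == "control"
        and r.participant_id != exclude_id
        and r.response_vector is not None
    ]
    if not contributors:
        raise ValueError("no prototype contributors")
    vec = np.mean([r.response_vector for r in contributors], axis=0)
    return PrototypeVector(
        task=tasks.pop(),
        vector=vec,
        n_contributors=len(contributors),
        excluded_id=exclude_id,
    )


def global_coherence(response_vector: np.ndarray, prototype: PrototypeVector | np.ndarray) -> float:
    """Cosine similarity between a response vector and a prototype vector.

    Symmetric and invariant to positive rescaling of either argument; raises
    on zero-norm (degenerate) vectors.
    """
    proto = prototype.vector if isinstance(prototype, PrototypeVector) else prototype
    a = np.asarray(response_vector, dtype=float)
    b = np.asarray(proto, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _prepare(records: Sequence[ResponseRecord], space: SemanticSpace,
             stoplist: Iterable[str], mode: str) -> None:
    """Fill in content tokens and response vectors in place where absent."""
    stop = set(stoplist)
    for r in records:
        if not r.content_tokens:
            r.content_tokens = preprocess(r.raw_text, stop)
        if r.response_vector is None:
            r.response_vector = compose_response_vector(r.content_tokens, space, mode)
            r.n_oov = sum(1 for t in r.content_tokens if space.get_vector(t) is MISSING)
            if r.n_oov:
                logger.debug(
                    "%s/%s: %d out-of-vocabulary tokens skipped",
                    r.participant_id, r.task, r.n_oov,
                )


def score_cohort(
    records: Sequence[ResponseRecord],
    space: SemanticSpace,
    stoplist: Iterable[str] = DEFAULT_STOPLIST,
    composition: str = "instance",
) -> pd.DataFrame:
    """Score a full cohort, returning a tidy per-participant x task table.

    Patients are scored against the all-controls prototype of each task;
    each control is scored against the prototype excluding itself. A task
    score is missing (NaN) where the response has no in-vocabulary content
    words. The per-participant ``composite_coherence`` is the mean over the
    participant's present task scores. Participants with no scorable response
    in any task are dropped with a logged warning.

    Returns
    -------
    DataFrame with columns participant_id, group, task, global_coherence;
    attribute ``df.attrs["composite"]`` holds the per-participant composite
    table (participant_id, group, composite_coherence).
    """
    records = list(records)
    _prepare(records, space, stoplist, composition)

    by_task: dict[str, list[ResponseRecord]] = {t: [] for t in TASKS}
    for r in records:
        by_task[r.task].append(r)

    rows = []
    for task in TASKS:
        task_records = by_task[task]
        if not task_records:
            continue
        controls = [r for r in task_records if r.group == "control"
                    and r.response_vector is not None]
        if len(controls) < 2:
            raise ValueError(
                f"task {task!r}: need >=2 control responses, got {len(controls)}"
            )
        all_proto = composite_prototype(task_records)
        for r in task_records:
            if r.response_vector is None:
                score = np.nan
            elif r.group == "control":
                proto = composite_prototype(task_records, exclude_id=r.participant_id)
                score = global_coherence(r.response_vector, proto)
            else:
                score = global_coherence(r.response_vector, all_proto)
            rows.append(
                {"participant_id": r.participant_id, "group": r.group,
                 "task": task, "global_coherence": score}
            )

    df = pd.DataFrame(rows)
    # drop participants with no scorable response in any task
    scorable = df.groupby("participant_id")["global_coherence"].transform(
        lambda s: s.notna().any()
    )
    dropped = df.loc[~scorable, "participant_id"].unique()
    if len(dropped):
        logger.warning(
            "dropping %d participant(s) with no scorable response in any task: %s",
            len(dropped), ", ".join(map(str, dropped)),
        )
        df = df[scorable].reset_index(drop=True)

    composite = (
        df.groupby(["participant_id", "group"], as_index=False)["global_coherence"]
        .mean()
        .rename(columns={"global_coherence": "composite_coherence"})
    )
    df.attrs["composite"] = composite
    return df


def deficit_cutoff(control_scores: Sequence[float]) -> float:
    """Deficit cutoff for a task: control mean minus 1.5 control SDs
    (sample SD, n-1 denominator)."""
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("SD undefined: need >=2 control scores")
    return float(scores.mean() - 1.5 * scores.std(ddof=1))


def flag_deficit(score: float, control_scores_for_task: Sequence[float]) -> bool:
    """True iff ``score`` falls strictly below the 1.5-SD deficit cutoff."""
    return bool(score < deficit_cutoff(control_scores_for_task))


def deficit_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-row deficit flags for patients, per task, against that task's
    control distribution. Control rows get flag False by convention."""
    out = scores.copy()
    out["deficit"] = False
    for task in out["task"].unique():
        m = out["task"] == task
        ctrl = out.loc[m & (out["group"] == "control"), "global_coherence"].dropna()
        cutoff = deficit_cutoff(ctrl.to_numpy())
        pat = m & (out["group"] == "patient") & out["global_coherence"].notna()
        out.loc[pat, "deficit"] = out.loc[pat, "global_coherence"] < cutoff
    return out
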