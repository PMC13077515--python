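"""All-or-nothing grading of multi-select vignette responses.

A benchmark run is a long table of responses — one row per
(model, question, replicate) with the set of option codes the model
selected — graded against an answer key.  Full credit requires exact set
equality with the key's correct subset: one omitted correct option or one
included distractor scores 0.  Questions that require image interpretation
are excluded (not scored) for models without multimodal capability; excluded
records never enter any aggregate.

Aggregation products:

* per-domain accuracy profiles, the radii of the radar polygon
  (:func:`domain_accuracy`),
* per-question raw accuracy, the mean over replicates
  (:func:`question_accuracy`),
* failure rates, the complement of accuracy within arbitrary groupings
  (:func:`failure_rates`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import GradingError, ValidationError

logger = logging.getLogger(__name__)

#: The five clinical-workflow domains: differential diagnosis, diagnostic
#: testing, final diagnosis, management, miscellaneous clinical reasoning.
DOMAINS = ("DD", "DT", "FD", "M", "Q")

#: Stable column order of a graded table.
GRADED_COLUMNS = (
    "model_id",
    "question_id",
    "vignette_id",
    "domain",
    "replicate",
    "score",
    "excluded",
    "age_group",
    "sex",
)

_FAILURE_GROUP_KEYS = {"model_id", "domain", "age_group", "sex", "vignette_id"}


@dataclass(frozen=True)
class AnswerKey:
    """One question's option universe, correct subset and metadata.

    ``options`` and ``correct`` are sets of opaque, case-sensitive option
    codes.  ``age_group`` and ``sex`` are vignette-level patient
    demographics, repeated on every question of the vignette.
    """

    question_id: str
    vignette_id: str
    domain: str
    options: frozenset = field(default_factory=frozenset)
    correct: frozenset = field(default_factory=frozenset)
    requires_image: bool = False
    age_group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", frozenset(self.options))
        object.__setattr__(self, "correct", frozenset(self.correct))
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"question {self.question_id!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )
        if not self.correct:
            raise ValidationError(f"question {self.question_id!r}: empty correct set")
        if not self.correct <= self.options:
            raise ValidationError(
                f"question {self.question_id!r}: correct set "
                f"{sorted(self.correct)} not a subset of options {sorted(self.options)}"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """One model's selection for one question in one replicate run."""

    model_id: str
    question_id: str
    replicate: int
    selected: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected", frozenset(self.selected))
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be >= 1, got {self.replicate}"
            )


def index_keys(keys: Iterable[AnswerKey]) -> dict[str, AnswerKey]:
    """Index answer keys by question_id, rejecting duplicates."""
    out: dict[str, AnswerKey] = {}
    for key in keys:
        if key.question_id in out:
            raise ValidationError(f"duplicate question_id {key.question_id!r} in key set")
        out[key.question_id] = key
    return out


def grade_selection(selected: Iterable[str], key: AnswerKey) -> int:
    """Score one selection: 1 iff it equals the correct set exactly, else 0.

    Raises :class:`ValidationError` if the selection contains option codes
    outside the question's option universe.
    """
    sel = frozenset(selected)
    unknown = sel - key.options
    if unknown:
        raise ValidationError(
            f"question {key.question_id!r}: unknown option code(s) "
            f"{sorted(unknown)}; valid codes are {sorted(key.options)}"
        )
    return int(sel == key.correct)


def grade_benchmark(
    responses: pd.DataFrame | Iterable[ResponseRecord],
    keys: Iterable[AnswerKey] | Mapping[str, AnswerKey],
    multimodal_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Grade a full response table into one GradedRecord row per response.

    Parameters
    ----------
    responses
        DataFrame with columns ``model_id, question_id, replicate, selected``
        (``selected`` holding sets of option codes), or an iterable of
        :class:`ResponseRecord`.
    keys
        Answer keys, as an iterable or a ``question_id -> AnswerKey`` mapping.
    multimodal_flags
        ``model_id -> bool``; image questions are excluded from scoring for
        models mapped to False (missing models default to False).

    Returns
    -------
    DataFrame with columns :data:`GRADED_COLUMNS`.  Excluded records carry a
    missing score so they cannot leak into aggregates.
    """
    key_map = keys if isinstance(keys, Mapping) else index_keys(keys)
    if not isinstance(responses, pd.DataFrame):
        responses = pd.DataFrame(
            [
                {
                    "model_id": r.model_id,
                    "question_id": r.question_id,
                    "replicate": r.replicate,
                    "selected": r.selected,
                }
                for r in responses
            ],
            columns=["model_id", "question_id", "replicate", "selected"],
        )
    if responses.empty:
        return pd.DataFrame(columns=list(GRADED_COLUMNS))

    orphans = sorted(set(responses["question_id"]) - set(key_map))
    if orphans:
        raise GradingError(f"responses reference question_ids with no answer key: {orphans}")
    dup = responses.duplicated(subset=["model_id", "question_id", "replicate"])
    if dup.any():
        bad = responses.loc[dup, ["model_id", "question_id", "replicate"]]
        raise GradingError(
            "duplicate (model, question, replicate) rows: "
            + "; ".join(f"({r.model_id}, {r.question_id}, {r.replicate})" for r in bad.itertuples())
        )

    rows = []
    for rec in responses.itertuples(index=False):
        key = key_map[rec.question_id]
        excluded = key.requires_image and not bool(multimodal_flags.get(rec.model_id, False))
        score = pd.NA if excluded else grade_selection(rec.selected, key)
        rows.append(
            (
                rec.model_id,
                rec.question_id,
                key.vignette_id,
                key.domain,
                int(rec.replicate),
                score,
                excluded,
                key.age_group,
                key.sex,
            )
        )
    graded = pd.DataFrame(rows, columns=list(GRADED_COLUMNS))
    graded["score"] = graded["score"].astype("Int64")
    return graded


def _included(graded: pd.DataFrame) -> pd.DataFrame:
    out = graded.loc[~graded["excluded"].astype(bool)].copy()
    out["score"] = out["score"].astype(float)
    return out


def domain_accuracy(graded: pd.DataFrame, mode: str = "vignette_then_mean") -> pd.DataFrame:
    """Per-domain accuracy for every (model, replicate).

    ``vignette_then_mean`` (default) first averages question scores within
    each vignette, then averages those vignette-level accuracies (unweighted)
    over vignettes that contribute at least one scored question of the
    domain.  ``question_pooled`` averages over all scored questions of the
    domain directly, weighting vignettes by their question counts.

    Returns a long DataFrame ``model_id, replicate, domain, accuracy``.
    Raises :class:`GradingError` for any (model, replicate, domain) cell with
    zero scored questions — the radar polygon would have an undefined vertex.
    """
    if mode not in ("vignette_then_mean", "question_pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    inc = _included(graded)
    if inc.empty:
        raise GradingError("no non-excluded graded records to aggregate")

    models = inc["model_id"].unique()
    reps = inc["replicate"].unique()
    domains = [d for d in DOMAINS if d in set(graded["domain"])]
    present = set(map(tuple, inc[["model_id", "replicate", "domain"]].drop_duplicates().to_numpy()))
    missing = [
        (str(m), int(r), str(d))
        for m in models
        for r in reps
        for d in domains
        if (m, r, d) not in present
    ]
    if missing:
        raise GradingError(
            "empty (model, replicate, domain) cells after exclusions: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )

    if mode == "question_pooled":
        acc = (
            inc.groupby(["model_id", "replicate", "domain"], sort=True)["score"]
            .mean()
            .rename("accuracy")
            .reset_index()
        )
    else:
        per_vignette = inc.groupby(
            ["model_id", "replicate", "domain", "vignette_id"], sort=True
        )["score"].mean()
        acc = (
            per_vignette.groupby(["model_id", "replicate", "domain"])
            .mean()
            .rename("accuracy")
            .reset_index()
        )
    return acc


def question_accuracy(graded: pd.DataFrame) -> pd.DataFrame:
    """Raw per-question accuracy: mean score over scored replicates.

    Returns ``model_id, question_id, accuracy`` with one row per
    (model, question) that retains at least one non-excluded replicate.
    """
    inc = _included(graded)
    return (
        inc.groupby(["model_id", "question_id"], sort=True)["score"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )


def failure_rates(graded: pd.DataFrame, group_by: Sequence[str]) -> pd.DataFrame:
    """Failure rate per group: proportion of scored (question, replicate)
    outcomes not answered fully correctly, i.e. ``1 - mean score``.

    ``group_by`` is a non-empty subset of
    ``{model_id, domain, age_group, sex, vignette_id}``.
    """
    group_by = list(group_by)
    bad = [g for g in group_by if g not in _FAILURE_GROUP_KEYS]
    if bad or not group_by:
        raise ValidationError(
            f"group_by must be a non-empty subset of {sorted(_FAILURE_GROUP_KEYS)}, got {group_by}"
        )
    inc = _included(graded)
    n_groups_all = graded.groupby(group_by, sort=True).size()
    agg = inc.groupby(group_by, sort=True)["score"].agg(["mean", "size"])
    dropped = n_groups_all.index.difference(agg.index)
    if len(dropped):
        logger.warning(
            "failure_rates: %d group(s) had only excluded records and were omitted: %s",
            len(dropped),
            list(dropped[:5]),
        )
    out = agg.reset_index()
    out["failure_rate"] = 1.0 - out.pop("mean")
    out = out.rename(columns={"size": "n"})
    return out[group_by + ["failure_rate", "n"]]
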