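"""The PrIME-LLM composite score: a normalized radar-polygon area.

Per-domain accuracies r_1..r_k are plotted as a radar chart — vertex i at
distance r_i from the origin, vertices equally spaced in angle.  The score
is the area of that polygon divided by the area of the full-scale reference
polygon (all radii 1):

    S = (sum_{i} r_i * r_{i+1}) / k          (cyclic index, r_{k+1} = r_1)

The sin(2*pi/k)/2 factor common to both areas cancels.  The score lives in
[0, 1], equals 1 only for a perfect profile, equals a**2 for a uniform
profile (a, ..., a), and rewards balance: spreading accuracy unevenly across
adjacent domains lowers the area at fixed arithmetic mean.

Because the area depends on which domains are adjacent, the score is
invariant under rotation and reversal of the domain order but not under
arbitrary permutation; :func:`order_sensitivity` quantifies the spread over
all cyclically distinct orderings.  The canonical clinical-workflow order is
(DD, DT, FD, M, Q).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePolygonError, ValidationError
from .grading import DOMAINS

#: Canonical domain order for five-domain clinical profiles.
CANONICAL_ORDER = DOMAINS


@dataclass(frozen=True)
class DomainProfile:
    """Ordered per-domain accuracies: the radii of one radar polygon."""

    radii: tuple
    domain_order: tuple = CANONICAL_ORDER

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        object.__setattr__(self, "domain_order", tuple(self.domain_order))
        k = len(self.radii)
        if k < 3:
            raise DegeneratePolygonError(f"need k >= 3 domains, got {k}")
        if len(self.domain_order) != k:
            raise ValidationError(
                f"{k} radii but {len(self.domain_order)} domain labels"
            )
        if len(set(self.domain_order)) != k:
            raise ValidationError(f"domain labels not distinct: {self.domain_order}")
        if any(not (0.0 <= r <= 1.0) for r in self.radii):
            raise ValidationError(f"radii must lie in [0, 1], got {self.radii}")

    @property
    def k(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class PrimeScore:
    """One normalized polygon-area score for one (model, replicate)."""

    value: float
    model_id: str = ""
    replicate: int | str = "aggregate"

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"PrIME score must lie in [0, 1], got {self.value}")


def polygon_area(radii: Sequence[float]) -> float:
    """Area of the radar polygon with vertex i at radius radii[i], angle
    2*pi*i/k: (1/2) * sin(2*pi/k) * sum of cyclic products r_i * r_{i+1}."""
    r = np.asarray(radii, dtype=float)
    k = r.size
    if k < 3:
        raise DegeneratePolygonError(f"a polygon needs k >= 3 vertices, got {k}")
    if np.any(r < 0):
        raise ValidationError(f"negative radius in {list(r)}")
    return 0.5 * math.sin(2.0 * math.pi / k) * float(np.dot(r, np.roll(r, -1)))


def polygon_vertices(
    radii: Sequence[float], start_angle: float = math.pi / 2, clockwise: bool = True
) -> np.ndarray:
    """Cartesian (k, 2) vertex array; by convention the first vertex is at the
    top and subsequent vertices proceed clockwise (plotting convention only —
    the area is independent of start and direction)."""
    r = np.asarray(radii, dtype=float)
    sign = -1.0 if clockwise else 1.0
    theta = start_angle + sign * 2.0 * math.pi * np.arange(r.size) / r.size
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def prime_score(profile: DomainProfile | Sequence[float]) -> float:
    """Normalized polygon area: polygon_area(r) / polygon_area(ones) =
    (sum of cyclic products) / k.  Domains enter with equal weight."""
    radii = profile.radii if isinstance(profile, DomainProfile) else tuple(profile)
    DomainProfile(radii, tuple(f"d{i}" for i in range(len(radii))))  # validate
    r = np.asarray(radii, dtype=float)
    return float(np.dot(r, np.roll(r, -1))) / r.size


def order_sensitivity(profile: DomainProfile) -> tuple[float, float]:
    """(min, max) PrIME score over all cyclically distinct orderings of the
    profile's domains — a diagnostic for the score's adjacency dependence.

    Rotations and reversals leave the area unchanged, so only
    (k-1)!/2 orderings are distinct; brute force, k <= 8."""
    if profile.k > 8:
        raise ValidationError("order_sensitivity is brute-force; supported for k <= 8")
    first, *rest = profile.radii
    seen = set()
    scores = []
    for perm in itertools.permutations(rest):
        canon = min(perm, tuple(reversed(perm)))
        if canon in seen:
            continue
        seen.add(canon)
        scores.append(prime_score((first, *perm)))
    return min(scores), max(scores)


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean with the n-1 sample SD; NaN for n < 2."""
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def prime_table(
    domain_accuracies: pd.DataFrame,
    domain_order: Sequence[str] = CANONICAL_ORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PrIME scores per (model, replicate) plus a per-model summary.

    Parameters
    ----------
    domain_accuracies
        Long table ``model_id, replicate, domain, accuracy`` as produced by
        :func:`primellm.grading.domain_accuracy`.
    domain_order
        The adjacency order used for the polygon; recorded in the output.

    Returns
    -------
    scores : one row per (model, replicate) with ``prime_score`` and the
        arithmetic ``mean_accuracy`` of the same radii for comparison.
    summary : per model — mean, SEM (sample SD / sqrt(R), NaN for a single
        replicate), min and max over replicates.
    """
    domain_order = tuple(domain_order)
    wide = domain_accuracies.pivot_table(
        index=["model_id", "replicate"], columns="domain", values="accuracy"
    )
    missing_cols = [d for d in domain_order if d not in wide.columns]
    if missing_cols:
        raise ValidationError(f"domain(s) {missing_cols} absent from accuracy table")
    wide = wide[list(domain_order)]
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        cell = incomplete[0]
        missing = [d for d in domain_order if pd.isna(wide.loc[cell, d])]
        raise ValidationError(
            f"incomplete profile for (model, replicate) {tuple(cell)}: missing domain(s) {missing}"
        )

    radii = wide.to_numpy()
    scores = np.einsum("ij,ij->i", radii, np.roll(radii, -1, axis=1)) / radii.shape[1]
    scores_df = wide.reset_index()[["model_id", "replicate"]].copy()
    scores_df["prime_score"] = scores
    scores_df["mean_accuracy"] = radii.mean(axis=1)
    scores_df.attrs["domain_order"] = domain_order

    summary = (
        scores_df.groupby("model_id")["prime_score"]
        .agg(
            mean="mean",
            sem=lambda v: _sem(np.asarray(v, dtype=float)),
            min="min",
            max="max",
            n_replicates="size",
        )
        .reset_index()
    )
    summary.attrs["domain_order"] = domain_order
    return scores_df, summary


def overall_accuracy(question_accuracies: pd.DataFrame) -> pd.DataFrame:
    """Per-model overall accuracy: unweighted mean (and SEM) over questions
    of the per-question raw accuracy."""
    if question_accuracies.empty:
        raise ValidationError("empty question-accuracy table")
    return (
        question_accuracies.groupby("model_id")["accuracy"]
        .agg(
            mean="mean",
            sem=lambda v: _sem(np.asarray(v, dtype=float)),
            n_questions="size",
        )
        .reset_index()
    )
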