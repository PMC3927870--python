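"""Wisdom-of-crowds aggregation of submissions and sensitivity analyses.

Predictions are aggregated by the arithmetic mean per protein and time
point; parameters by the geometric mean (submitted values can differ by
orders of magnitude, and the geometric mean is the natural average under
the factor-mismatch distance).  Consensus links are the three most voted
canonical links.  The curves and R-squared analyses quantify how aggregate
quality changes with the number of pooled teams and how strongly each
parameter drives prediction error across teams.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lab import NoiseModel
from .scoring import (
    LinkPrediction,
    ParameterSubmission,
    PredictionSubmission,
    parameter_distance,
    protein_distance,
)

__all__ = [
    "TeamSubmission",
    "SubmissionPool",
    "aggregate_predictions",
    "aggregate_parameters",
    "consensus_links",
    "aggregation_curves",
    "parameter_sensitivity",
]


@dataclass(frozen=True)
class TeamSubmission:
    team: str
    parameters: ParameterSubmission | None = None
    predictions: PredictionSubmission | None = None
    links: tuple[LinkPrediction, ...] = ()


@dataclass(frozen=True)
class SubmissionPool:
    """Ordered pool of team submissions (order is the ranking, best first)."""

    members: tuple[TeamSubmission, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ValueError("empty submission pool")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= len(self):
            raise ValueError(f"k must be in [1, {len(self)}], got {k}")


def aggregate_predictions(pool: SubmissionPool, k: int) -> PredictionSubmission:
    """Arithmetic mean of the first k teams' predicted time courses."""
    pool._check_k(k)
    subs = [m.predictions for m in pool.members[:k]]
    if any(s is None for s in subs):
        raise ValueError("a pooled team has no prediction submission")
    ref = subs[0]
    stacked = np.stack([np.stack([s.get(p) for p in ref.proteins]) for s in subs])
    return PredictionSubmission(ref.proteins, stacked.mean(axis=0), ref.grid)


def aggregate_parameters(pool: SubmissionPool, k: int) -> dict[str, float]:
    """Per-parameter geometric mean over the first k teams."""
    pool._check_k(k)
    subs = [m.parameters for m in pool.members[:k]]
    if any(s is None for s in subs):
        raise ValueError("a pooled team has no parameter submission")
    keys = sorted(subs[0])
    logs = np.array([[np.log(s[key]) for key in keys] for s in subs])
    return dict(zip(keys, np.exp(logs.mean(axis=0))))


def consensus_links(pool: SubmissionPool, n: int = 3) -> list[LinkPrediction]:
    """The n most-submitted links, ties broken lexicographically.

    Links are canonical (destinations sorted) so identical operon links
    merge in the vote.  Fewer than n distinct links returns all of them.
    """
    votes: Counter[LinkPrediction] = Counter()
    for m in pool.members:
        votes.update(m.links)
    if not votes:
        raise ValueError("no link submissions in the pool")
    ranked = sorted(
        votes.items(), key=lambda kv: (-kv[1], kv[0].source, kv[0].sign, kv[0].destinations)
    )
    return [link for link, _ in ranked[:n]]


def aggregation_curves(
    pool: SubmissionPool,
    gold_parameters: ParameterSubmission,
    gold_predictions: PredictionSubmission,
    nm: NoiseModel | None = None,
) -> pd.DataFrame:
    """D_param and D_prot of k-team aggregates, k = 1..n, both rank orders.

    ``forward`` pools best-first (the pool order); ``reverse`` pools
    worst-first.  Returns a long DataFrame with columns
    (k, order, D_param, D_prot).
    """
    nm = nm or NoiseModel()
    rows = []
    for order, members in (
        ("forward", pool.members),
        ("reverse", pool.members[::-1]),
    ):
        sub = SubmissionPool(members)
        for k in range(1, len(sub) + 1):
            d_param = (
                parameter_distance(aggregate_parameters(sub, k), gold_parameters)
                if all(m.parameters is not None for m in members[:k])
                else np.nan
            )
            d_prot = (
                protein_distance(aggregate_predictions(sub, k), gold_predictions, nm)
                if all(m.predictions is not None for m in members[:k])
                else np.nan
            )
            rows.append({"k": k, "order": order, "D_param": d_param, "D_prot": d_prot})
    return pd.DataFrame(rows)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a simple least-squares line y ~ a + b x (nan when degenerate)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class SensitivityReport:
    per_parameter_r2: Mapping[str, float]
    overall_r2: float
    d_prot: tuple[float, ...]
    d_param: tuple[float, ...]


def parameter_sensitivity(
    pool: SubmissionPool,
    gold_parameters: ParameterSubmission,
    gold_predictions: PredictionSubmission,
    nm: NoiseModel | None = None,
) -> SensitivityReport:
    """How strongly each submitted parameter tracks prediction error.

    Per parameter: R^2 of the teams' submitted values against their D_prot
    (untransformed simple regression).  Overall: R^2 of log10 D_param
    against log10 D_prot across teams.  Requires >= 3 teams with both
    parameter and prediction submissions; a parameter constant across
    teams yields nan.
    """
    members = [
        m for m in pool.members if m.parameters is not None and m.predictions is not None
    ]
    if len(members) < 3:
        raise ValueError("parameter sensitivity needs at least 3 complete submissions")
    nm = nm or NoiseModel()
    d_prot = np.array(
        [protein_distance(m.predictions, gold_predictions, nm) for m in members]
    )
    d_param = np.array(
        [parameter_distance(m.parameters, gold_parameters) for m in members]
    )
    per_param = {}
    for key in sorted(gold_parameters):
        values = np.array([m.parameters[key] for m in members])
        per_param[key] = _r_squared(values, d_prot)
    positive = (d_param > 0) & (d_prot > 0)
    overall = (
        _r_squared(np.log10(d_param[positive]), np.log10(d_prot[positive]))
        if positive.sum() >= 3
        else float("nan")
    )
    return SensitivityReport(per_param, overall, tuple(d_prot), tuple(d_param))
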