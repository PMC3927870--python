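"""Challenge scoring: distances, resampling null models, combined scores.

Parameter-estimation challenge (model 1)
    ``D_prot``: variance-weighted mean squared distance between predicted
    and simulated time courses of three requested proteins, scored from the
    11th of 41 grid points onward.  ``D_param``: mean squared log10 ratio
    between predicted and true parameters, so a factor-x mismatch costs the
    same at any nominal value.  P-values for both come from a *relative*
    null: composite submissions resampled per time point (respectively per
    parameter) from the participants' own predictions.
    ``Score1 = -log10(p_prot * p_param)``.

Topology challenge (model 2)
    Each predicted link scores ``s_link = L + N``: L = 6 per fully correct
    connection (12 when a link correctly hits both genes of an operon), and
    when no connection is fully correct, partial credit N counts correctly
    implicated genes (+1 each, destination upgraded to +2 when its sign is
    also right).  ``s_network`` sums the three link scores; its p-value
    comes from random valid 3-link additions.  ``Score2 = -log10(p_netw)``.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .lab import NoiseModel
from .model import NetworkSpec, TimeGrid, Trajectory, protein_species

__all__ = [
    "PREDICTION_GRID",
    "SCORED_FROM",
    "ParameterSubmission",
    "PredictionSubmission",
    "LinkPrediction",
    "NullDistribution",
    "ScoreReport",
    "protein_distance",
    "parameter_distance",
    "null_pvalue_protein",
    "null_pvalue_parameter",
    "score1",
    "link_score",
    "network_score",
    "enumerate_candidate_links",
    "null_pvalue_network",
    "score2",
]

#: the challenge prediction grid: t in [0, 20], step 0.5 -> N = 41 points
PREDICTION_GRID = TimeGrid(0.0, 20.0, 0.5)

#: predictions are scored from the 11th time point onward (1-based), i.e.
#: from t = 5.0; the first 10 intervals are dominated by the known initial
#: conditions.  NB the normaliser is 3*(N-11) = 90 while 31 points per
#: protein are summed -- the printed convention is kept literally.
SCORED_FROM = 10  # 0-based index of the 11th point


ParameterSubmission = Mapping[str, float]


@dataclass(frozen=True)
class PredictionSubmission:
    """Predicted protein time courses on the 41-point challenge grid."""

    proteins: tuple[str, ...]
    values: np.ndarray  # proteins x 41
    grid: TimeGrid = PREDICTION_GRID

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", tuple(self.proteins))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.proteins), self.grid.n_points):
            raise ValueError(
                f"prediction matrix {v.shape} inconsistent with "
                f"{len(self.proteins)} proteins x {self.grid.n_points} points"
            )
        if np.any(v < 0):
            raise ValueError("predicted concentrations must be >= 0")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_trajectory(cls, traj: Trajectory, genes: Sequence[str]) -> "PredictionSubmission":
        species = [protein_species(g) for g in genes]
        sub = traj.subset(species)
        return cls(tuple(genes), sub.values, traj.grid)

    def get(self, protein: str) -> np.ndarray:
        return self.values[self.proteins.index(protein)]


@dataclass(frozen=True)
class NullDistribution:
    values: np.ndarray
    B: int
    seed: int | None = None
    exhaustive: bool = False


@dataclass(frozen=True)
class ScoreReport:
    """Everything one submission earned, with null metadata for replay."""

    D_prot: float | None = None
    D_param: float | None = None
    p_prot: float | None = None
    p_param: float | None = None
    score1: float | None = None
    s_links: tuple[int, ...] = ()
    s_network: int | None = None
    p_netw: float | None = None
    score2: float | None = None
    null_meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _check_grids(pred: PredictionSubmission, gold: PredictionSubmission) -> None:
    if pred.grid != gold.grid:
        raise ValueError("prediction and gold standard use different time grids")
    if set(pred.proteins) != set(gold.proteins):
        raise ValueError("prediction and gold standard cover different proteins")


def protein_distance(
    pred: PredictionSubmission, gold: PredictionSubmission, nm: NoiseModel | None = None
) -> float:
    """Variance-weighted squared distance between predicted and true courses.

    Sums ``(pred - sim)^2 / (sigma_b^2 + sigma_s^2 sim^2)`` over the scored
    window and divides by 3*(N-11).
    """
    nm = nm or NoiseModel()
    _check_grids(pred, gold)
    n_prot = len(gold.proteins)
    N = gold.grid.n_points
    total = 0.0
    for protein in gold.proteins:
        sim = gold.get(protein)[SCORED_FROM:]
        p = pred.get(protein)[SCORED_FROM:]
        total += float(np.sum((p - sim) ** 2 / nm.variance(sim)))
    return total / (n_prot * (N - 11))


def parameter_distance(pred: ParameterSubmission, gold: ParameterSubmission) -> float:
    """Mean squared log10 ratio between predicted and true parameter values."""
    if set(pred) != set(gold):
        missing = sorted(set(gold) - set(pred))
        raise ValueError(f"submission does not cover the gold parameters: missing {missing}")
    ratios = []
    for k, truth in gold.items():
        v = pred[k]
        if v <= 0 or truth <= 0:
            raise ValueError(f"non-positive value for parameter {k!r}")
        ratios.append(np.log10(v / truth))
    return float(np.mean(np.square(ratios)))


# ---------------------------------------------------------------------------
# relative nulls (resampled from the participants' own submissions)
# ---------------------------------------------------------------------------

def _protein_null_distances_sampled(
    values: np.ndarray, gold: np.ndarray, var: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Distances of B composite submissions resampled per protein and point.

    ``values`` is teams x proteins x points (scored window only).
    """
    T, K, S = values.shape
    out = np.empty(B)
    chunk = max(1, min(B, 20000))
    sq = (values - gold) ** 2 / var  # teams x proteins x points
    start = 0
    while start < B:
        b = min(chunk, B - start)
        picks = rng.integers(T, size=(b, K, S))
        out[start : start + b] = sq[picks, np.arange(K)[:, None], np.arange(S)].sum(
            axis=(1, 2)
        )
        start += b
    return out


def null_pvalue_protein(
    submissions: Sequence[PredictionSubmission],
    team: int,
    gold: PredictionSubmission,
    nm: NoiseModel | None = None,
    B: int = 100_000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, NullDistribution]:
    """P-value of one team's D_prot under the composite-resampling null.

    Composites pick, independently per protein and per time point, a
    uniformly random team's predicted value.  ``exhaustive=True`` enumerates
    every composite over the scored window instead of sampling (only
    feasible for toy pools); sampled p-values use add-one smoothing
    ``(1 + #{null <= team}) / (B + 1)``.
    """
    if len(submissions) < 2:
        raise ValueError("need at least 2 submissions to build a relative null")
    nm = nm or NoiseModel()
    for s in submissions:
        _check_grids(s, gold)
    order = gold.proteins
    gold_win = np.stack([gold.get(p)[SCORED_FROM:] for p in order])
    var = nm.variance(gold_win)
    values = np.stack(
        [np.stack([s.get(p)[SCORED_FROM:] for p in order]) for s in submissions]
    )
    norm = len(order) * (gold.grid.n_points - 11)
    team_sum = float(np.sum((values[team] - gold_win) ** 2 / var))

    sq = (values - gold_win) ** 2 / var
    if exhaustive:
        null = _exhaustive_composite_sums(sq.reshape(len(submissions), -1))
        p = float(np.count_nonzero(null <= team_sum + 1e-12) / len(null))
        return p, NullDistribution(null / norm, B=len(null), exhaustive=True)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng or np.random.default_rng()
    null = _protein_null_distances_sampled(values, gold_win, var, B, rng)
    p = float((1 + np.count_nonzero(null <= team_sum + 1e-12)) / (B + 1))
    return p, NullDistribution(null / norm, B=B)


def _exhaustive_composite_sums(sq: np.ndarray) -> np.ndarray:
    """All possible composite distance sums; sq is teams x slots."""
    T, S = sq.shape
    if T**S > 2_000_000:
        raise ValueError(f"exhaustive null infeasible: {T}^{S} composites")
    totals = np.zeros(1)
    for j in range(S):
        totals = (totals[:, None] + sq[:, j][None, :]).ravel()
    return totals


def null_pvalue_parameter(
    submissions: Sequence[ParameterSubmission],
    team: int,
    gold: ParameterSubmission,
    B: int = 100_000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, NullDistribution]:
    """P-value of one team's D_param under the per-parameter resampling null."""
    if len(submissions) < 2:
        raise ValueError("need at least 2 submissions to build a relative null")
    keys = sorted(gold)
    logs = np.array(
        [[np.log10(s[k] / gold[k]) ** 2 for k in keys] for s in submissions]
    )  # teams x parameters
    Np = len(keys)
    team_sum = float(logs[team].sum())
    if exhaustive:
        null = _exhaustive_composite_sums(logs)
        p = float(np.count_nonzero(null <= team_sum + 1e-12) / len(null))
        return p, NullDistribution(null / Np, B=len(null), exhaustive=True)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng or np.random.default_rng()
    T = len(submissions)
    out = np.empty(B)
    chunk = max(1, min(B, 50000))
    start = 0
    while start < B:
        b = min(chunk, B - start)
        picks = rng.integers(T, size=(b, Np))
        out[start : start + b] = logs[picks, np.arange(Np)].sum(axis=1)
        start += b
    p = float((1 + np.count_nonzero(out <= team_sum + 1e-12)) / (B + 1))
    return p, NullDistribution(out / Np, B=B)


def score1(p_prot: float, p_param: float) -> float:
    """Combined parameter-challenge score, -log10 of the p-value product."""
    if not 0 < p_prot <= 1 or not 0 < p_param <= 1:
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.log10(p_prot * p_param))


# ---------------------------------------------------------------------------
# topology challenge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkPrediction:
    """A predicted regulatory link: source gene, sign, 1-2 destination genes.

    Destinations are stored sorted so that operon links compare equal
    regardless of the order they were written in.
    """

    source: str
    sign: str
    destinations: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError(f"link sign must be '+' or '-', got {self.sign!r}")
        dests = tuple(sorted(self.destinations))
        if not 1 <= len(dests) <= 2:
            raise ValueError("a link has 1 or 2 destination genes")
        if len(set(dests)) != len(dests):
            raise ValueError("duplicate destination gene")
        object.__setattr__(self, "destinations", dests)

    @property
    def connections(self) -> frozenset:
        return frozenset((self.source, self.sign, d) for d in self.destinations)


def _pair_score(pred: LinkPrediction, true: LinkPrediction) -> int:
    correct = len(pred.connections & true.connections)
    if correct:
        return 6 * correct  # 6 per fully correct connection; 12 for both operon genes
    n = 1 if pred.source == true.source else 0
    sign_ok = pred.sign == true.sign
    for d in pred.destinations:
        if d in true.destinations:
            n += 2 if sign_ok else 1
    return n


def link_score(pred: LinkPrediction, truth: Sequence[LinkPrediction]) -> int:
    """Score of one predicted link against the true links (best match)."""
    return max(_pair_score(pred, t) for t in truth)


def network_score(
    submission: Sequence[LinkPrediction], truth: Sequence[LinkPrediction]
) -> int:
    """Total score of a 3-link submission under the best one-to-one pairing.

    The pairing of predicted to true links is chosen to maximise the summed
    link scores over all permutations (exact for 3 links), which is
    deterministic and order-invariant.
    """
    if len(submission) != len(truth):
        raise ValueError(
            f"submission has {len(submission)} links, truth has {len(truth)}"
        )
    pair = np.array([[_pair_score(p, t) for t in truth] for p in submission])
    return int(
        max(
            sum(pair[i, perm[i]] for i in range(len(submission)))
            for perm in itertools.permutations(range(len(truth)))
        )
    )


def enumerate_candidate_links(spec: NetworkSpec) -> list[LinkPrediction]:
    """All single links addable to ``spec`` under the challenge rules.

    A source gene may establish at most 2 outgoing links and a gene may
    receive at most 2 regulations (counting the links already present in
    the visible topology); a link targets either a single gene or both
    members of an operon.  Both signs are enumerated.
    """
    out_free = {g: 2 - len(spec.outgoing(g)) for g in spec.gene_ids}
    in_free = {g: 2 - len(spec.incoming(g)) for g in spec.gene_ids}
    operons: dict[str, tuple[str, ...]] = {}
    for g in spec.genes:
        if g.operon_id is not None:
            operons[g.operon_id] = spec.operon_members(g.operon_id)
    target_sets: list[tuple[str, ...]] = [(g,) for g in spec.gene_ids if in_free[g] > 0]
    for members in operons.values():
        if len(members) == 2 and all(in_free[m] > 0 for m in members):
            target_sets.append(tuple(sorted(members)))
    existing = {
        (r.source, r.sign, tuple(sorted(r.targets))) for r in spec.regulations
    }
    links = []
    for src in spec.gene_ids:
        if out_free[src] <= 0:
            continue
        for dests in target_sets:
            for sign in ("+", "-"):
                if (src, sign, dests) in existing:
                    continue
                links.append(LinkPrediction(src, sign, dests))
    return links


def _combo_valid(combo: Sequence[LinkPrediction], spec: NetworkSpec) -> bool:
    out_used: dict[str, int] = {}
    in_used: dict[str, int] = {}
    for l in combo:
        out_used[l.source] = out_used.get(l.source, 0) + 1
        for d in l.destinations:
            in_used[d] = in_used.get(d, 0) + 1
    for g, n in out_used.items():
        if len(spec.outgoing(g)) + n > 2:
            return False
    for g, n in in_used.items():
        if len(spec.incoming(g)) + n > 2:
            return False
    return True


def null_pvalue_network(
    spec: NetworkSpec,
    submission: Sequence[LinkPrediction],
    truth: Sequence[LinkPrediction],
    B: int = 100_000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, NullDistribution]:
    """P-value of a 3-link submission against random valid 3-link additions.

    ``spec`` is the *visible* (incomplete) topology defining the link
    universe.  The null score distribution comes from distinct-link
    combinations that jointly respect the connection rules; the p-value is
    the (smoothed) right tail ``P(s_null >= s_team)``.
    """
    universe = enumerate_candidate_links(spec)
    if not universe:
        raise ValueError("empty candidate-link universe")
    team_score = network_score(submission, truth)
    k = len(truth)
    if exhaustive:
        scores = [
            network_score(c, truth)
            for c in itertools.combinations(universe, k)
            if _combo_valid(c, spec)
        ]
        if not scores:
            raise ValueError("no valid link combination in the universe")
        null = np.array(scores, dtype=float)
        p = float(np.count_nonzero(null >= team_score) / len(null))
        return p, NullDistribution(null, B=len(null), exhaustive=True)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng or np.random.default_rng()
    null = np.empty(B)
    n = len(universe)
    filled = 0
    while filled < B:
        idx = rng.choice(n, size=k, replace=False)
        combo = [universe[i] for i in idx]
        if not _combo_valid(combo, spec):
            continue
        null[filled] = network_score(combo, truth)
        filled += 1
    p = float((1 + np.count_nonzero(null >= team_score)) / (B + 1))
    return p, NullDistribution(null, B=B)


def score2(p_netw: float) -> float:
    """Topology-challenge score, -log10 of the network p-value."""
    if not 0 < p_netw <= 1:
        raise ValueError("p-value must lie in (0, 1]")
    return float(-np.log10(p_netw))
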