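"""Synthetic model generation and the two bundled challenge-style fixtures.

``model1_fixture`` is a 9-gene mRNA+protein network with 13 regulations and
45 free parameters; ``model2_fixture`` is an 11-gene protein-only network
with 16 regulations, 61 free parameters, one two-gene operon and sustained
oscillations, three of whose links (r9, r10, r12) are designated "missing"
for topology-inference exercises.  Both are synthetic stand-ins: the
published challenge never printed its gold-standard wiring or values, so
the bundled topologies/parameters are package defaults chosen to satisfy
the documented structural census and qualitative dynamics (see the data
files' provenance notes).

``random_network`` / ``random_parameters`` generate arbitrary valid models
for property testing, and ``make_challenge`` wraps a model in a session
that exposes only the visible topology plus the priced virtual lab.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .lab import (
    CreditLedger,
    MeasurementRequest,
    NoiseModel,
    Perturbation,
    PriceTable,
    RequestError,
    gelshift,
    initial_dataset,
    run_experiment,
)
from .model import (
    MRNA_PROTEIN,
    PROTEIN_ONLY,
    GeneSpec,
    InvalidModelError,
    ModelInstance,
    NetworkSpec,
    ParameterSet,
    RegulationSpec,
    kd_id,
    parameter_ids,
    rbs_id,
)
from .scoring import (
    LinkPrediction,
    PredictionSubmission,
    network_score,
    null_pvalue_network,
    parameter_distance,
    protein_distance,
    score2,
)

__all__ = [
    "GeneratorConfig",
    "random_network",
    "random_parameters",
    "random_model",
    "model1_fixture",
    "model2_fixture",
    "MODEL2_HIDDEN_LINKS",
    "prediction_condition",
    "PREDICTION_PROTEINS",
    "ChallengeSession",
    "make_challenge",
]

#: the three designated missing links of the bundled topology fixture
MODEL2_HIDDEN_LINKS = ("r9", "r10", "r12")

#: proteins whose perturbed time courses are requested for prediction
PREDICTION_PROTEINS = ("g3", "g5", "g8")

# log-uniform sampling ranges per parameter class; chosen to give dynamics
# that play out on the t in [0, 20] horizon
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Kd": (0.1, 10.0),
    "h": (1.0, 4.0),
    "strength": (0.1, 5.0),
    "degradation": (0.1, 1.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 5
    n_regulations: int = 5
    model_class: str = MRNA_PROTEIN
    operon_pairs: int = 0  # protein_only models only
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.n_regulations > 2 * self.n_genes:
            raise ValueError(
                "infeasible: at most 2 outgoing links per gene "
                f"allows {2 * self.n_genes} regulations"
            )
        if self.model_class == MRNA_PROTEIN and self.operon_pairs:
            raise ValueError("operons only exist in protein_only models")
        if 2 * self.operon_pairs > self.n_genes:
            raise ValueError("more operon pairs than genes")


def random_network(cfg: GeneratorConfig) -> NetworkSpec:
    """Random topology obeying the challenge connection rules (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i + 1}" for i in range(cfg.n_genes)]
    operon_of: dict[str, str] = {}
    for k in range(cfg.operon_pairs):
        a, b = gene_ids[2 * k], gene_ids[2 * k + 1]
        operon_of[a] = operon_of[b] = f"op{k + 1}"
    genes = tuple(GeneSpec(g, operon_of.get(g)) for g in gene_ids)

    for _attempt in range(50):
        out_free = {g: 2 for g in gene_ids}
        in_free = {g: 2 for g in gene_ids}
        used: set[tuple[str, tuple[str, ...]]] = set()
        regs: list[RegulationSpec] = []
        stuck = 0
        while len(regs) < cfg.n_regulations and stuck < 200:
            src = gene_ids[rng.integers(cfg.n_genes)]
            if out_free[src] <= 0:
                stuck += 1
                continue
            tgt = gene_ids[rng.integers(cfg.n_genes)]
            targets = (tgt,)
            oid = operon_of.get(tgt)
            if oid is not None and rng.random() < 0.5:
                members = tuple(sorted(g for g, o in operon_of.items() if o == oid))
                if all(in_free[m] > 0 for m in members):
                    targets = members
            if any(in_free[t] <= 0 for t in targets) or (src, targets) in used:
                stuck += 1
                continue
            sign = "+" if rng.random() < 0.5 else "-"
            regs.append(RegulationSpec(f"r{len(regs) + 1}", src, targets, sign))
            used.add((src, targets))
            out_free[src] -= 1
            for t in targets:
                in_free[t] -= 1
        if len(regs) == cfg.n_regulations:
            return NetworkSpec(genes, tuple(regs), cfg.model_class)
    raise InvalidModelError(
        f"could not place {cfg.n_regulations} regulations on {cfg.n_genes} genes"
    )


def random_parameters(spec: NetworkSpec, cfg: GeneratorConfig) -> ParameterSet:
    """Log-uniform parameter draws within the configured class ranges."""
    rng = np.random.default_rng(cfg.seed + 1)

    def draw(cls: str) -> float:
        lo, hi = cfg.ranges[cls]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    values: dict[str, float] = {}
    for pid in parameter_ids(spec):
        if pid.endswith("_Kd"):
            values[pid] = draw("Kd")
        elif pid.endswith("_h"):
            values[pid] = draw("h")
        elif pid.endswith(("_promoter", "_rbs", "_synthesis", "_basal")):
            values[pid] = draw("strength")
        else:  # degradation rates, incl. the shared protein rate
            values[pid] = draw("degradation")
    return ParameterSet(values)


def random_model(cfg: GeneratorConfig) -> ModelInstance:
    spec = random_network(cfg)
    return ModelInstance(spec, random_parameters(spec, cfg))


def _load_bundled(name: str) -> ModelInstance:
    from .io import model_from_dict

    doc = json.loads(resources.files("grnlab.data").joinpath(name).read_text())
    return model_from_dict(doc)


def model1_fixture() -> ModelInstance:
    """The bundled 9-gene, 13-regulation mRNA+protein network (45 parameters)."""
    return _load_bundled("model1.json")


def model2_fixture() -> ModelInstance:
    """The bundled 11-gene, 16-regulation protein-only network (61 parameters)."""
    return _load_bundled("model2.json")


def prediction_condition() -> tuple[Perturbation, ...]:
    """The perturbed condition under which protein courses are predicted:
    10-fold decrease of r9's Kd, 2-fold increase of g3's RBS strength and
    10-fold increase of g5's RBS strength."""
    return (
        Perturbation("parameter_scale", kd_id("r9"), 0.1),
        Perturbation("parameter_scale", rbs_id("g3"), 2.0),
        Perturbation("parameter_scale", rbs_id("g5"), 10.0),
    )


# ---------------------------------------------------------------------------
# challenge sessions
# ---------------------------------------------------------------------------

class ChallengeSession:
    """A playable challenge: visible topology, hidden truth, priced lab.

    The session exposes the (possibly incomplete) ``network``, a credit
    ledger and the purchase API; the true parameter values are held
    privately and can only be reached through the gel-shift assay or, on
    the organiser's side, through the ``evaluate_*`` scoring methods.
    """

    def __init__(
        self,
        model: ModelInstance,
        budget: int,
        prices: PriceTable | None = None,
        seed: int = 0,
        hidden_links: Sequence[str] | None = None,
        noise: NoiseModel | None = None,
    ):
        if budget <= 0:
            raise ValueError("budget must be positive")
        if hidden_links is None:
            hidden_links = ()
        for rid in hidden_links:
            model.spec.regulation(rid)  # raises KeyError on unknown id
        self._truth = model
        self.hidden_link_ids = tuple(hidden_links)
        visible_regs = tuple(
            r for r in model.spec.regulations if r.id not in self.hidden_link_ids
        )
        self.network = NetworkSpec(
            model.spec.genes, visible_regs, model.spec.model_class
        )
        self.prices = prices or PriceTable()
        self.noise = noise or NoiseModel()
        self.ledger = CreditLedger(budget)
        self.seed = seed
        self._rng = np.random.default_rng(seed)

    # -- participant side -------------------------------------------------

    def initial_data(self):
        if self.network.model_class != MRNA_PROTEIN:
            raise RequestError("the free initial microarray exists only for mRNA models")
        return initial_dataset(
            self._truth, np.random.default_rng(self.seed + 10_000), noise=self.noise
        )

    def buy(self, perturbations: Sequence[Perturbation], request: MeasurementRequest):
        return run_experiment(
            self._truth,
            perturbations,
            request,
            self.ledger,
            self._rng,
            noise=self.noise,
            prices=self.prices,
        )

    def buy_gelshift(self, regulation_id: str) -> tuple[float, float]:
        if regulation_id in self.hidden_link_ids:
            raise RequestError("cannot assay a link that is not in the visible topology")
        return gelshift(self._truth, regulation_id, self.ledger, self.prices)

    # -- organiser side ---------------------------------------------------

    def true_links(self) -> tuple[LinkPrediction, ...]:
        return tuple(
            LinkPrediction(r.source, r.sign, r.targets)
            for r in (self._truth.spec.regulation(rid) for rid in self.hidden_link_ids)
        )

    def evaluate_parameters(self, submission) -> float:
        gold = {k: self._truth.params[k] for k in parameter_ids(self._truth.spec)}
        return parameter_distance(submission, gold)

    def gold_predictions(
        self, proteins: Sequence[str] = PREDICTION_PROTEINS
    ) -> PredictionSubmission:
        from .model import simulate
        from .scoring import PREDICTION_GRID

        model = self._truth
        for p in prediction_condition():
            from .lab import apply_perturbation

            model = apply_perturbation(model, p)
        traj = simulate(model, PREDICTION_GRID)
        return PredictionSubmission.from_trajectory(traj, proteins)

    def evaluate_predictions(self, submission: PredictionSubmission) -> float:
        return protein_distance(submission, self.gold_predictions(), self.noise)

    def evaluate_links(
        self,
        submission: Sequence[LinkPrediction],
        B: int = 100_000,
        rng: np.random.Generator | None = None,
        exhaustive: bool = False,
    ) -> tuple[int, float, float]:
        truth = self.true_links()
        s = network_score(submission, truth)
        p, _ = null_pvalue_network(
            self.network, submission, truth, B=B, rng=rng, exhaustive=exhaustive
        )
        return s, p, score2(p)


def make_challenge(
    model: ModelInstance,
    budget: int,
    prices: PriceTable | None = None,
    seed: int = 0,
    hidden_links: Sequence[str] | None = None,
) -> ChallengeSession:
    """Wrap a model in a challenge session.

    For protein_only models with no explicit ``hidden_links`` the bundled
    fixture's designated missing links are hidden when present.
    """
    if hidden_links is None and model.spec.model_class == PROTEIN_ONLY:
        known = {r.id for r in model.spec.regulations}
        if set(MODEL2_HIDDEN_LINKS) <= known:
            hidden_links = MODEL2_HIDDEN_LINKS
    return ChallengeSession(
        model, budget, prices=prices, seed=seed, hidden_links=hidden_links
    )
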