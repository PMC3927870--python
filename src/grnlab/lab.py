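"""Priced in-silico experiments: perturbations, measurements, noise, credits.

The virtual lab mimics a wet lab working on a fixed grant: every experiment
debits a credit ledger at a catalogue price, the measured values carry a
mixed additive/multiplicative Gaussian noise, and the available measurement
technologies trade off coverage, resolution and cost:

- fluorescence protein fusion: 2 proteins of choice, every time unit;
- microarray: all mRNAs, every 4 (low) or 2 (high) time units
  (mrna_protein models only);
- mass spectrometry: all proteins, same resolutions (protein_only models);
- gel shift: the exact (Kd, h) of one regulation, noise free.

Perturbations: gene deletion (mRNA and protein eliminated), siRNA
knockdown (mRNA degradation x10), RBS activity decrease (translation /10),
plus an explicit parameter_scale used for prediction conditions.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    MRNA_PROTEIN,
    PROTEIN_ONLY,
    InvalidParameterError,
    ModelInstance,
    TimeGrid,
    degradation_id,
    hill_id,
    kd_id,
    mrna_species,
    protein_species,
    rbs_id,
    simulate,
    synthesis_id,
)

__all__ = [
    "Perturbation",
    "MeasurementRequest",
    "NoiseModel",
    "PriceTable",
    "CreditLedger",
    "Dataset",
    "InsufficientCreditsError",
    "RequestError",
    "UnsupportedPerturbationError",
    "apply_perturbation",
    "add_noise",
    "run_experiment",
    "gelshift",
    "initial_dataset",
    "DEFAULT_PRICES",
]


class InsufficientCreditsError(RuntimeError):
    """Purchase would overdraw the ledger; the ledger is left unchanged."""


class RequestError(ValueError):
    """Measurement request incompatible with the model or malformed."""


class UnsupportedPerturbationError(ValueError):
    """Perturbation undefined for the model class or unknown target."""


@dataclass(frozen=True)
class Perturbation:
    """kind: deletion | sirna_knockdown | rbs_decrease | parameter_scale."""

    kind: str
    target: str
    factor: float | None = None

    KINDS = ("deletion", "sirna_knockdown", "rbs_decrease", "parameter_scale")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise UnsupportedPerturbationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "parameter_scale":
            if self.factor is None or self.factor <= 0:
                raise UnsupportedPerturbationError(
                    "parameter_scale requires a positive fold-change factor"
                )


@dataclass(frozen=True)
class MeasurementRequest:
    """What to measure: technology, targets and (where applicable) resolution."""

    technology: str  # fluorescence | microarray | massspec
    targets: tuple[str, ...] = ()
    resolution: str | None = None  # low | high for microarray/massspec

    TECHNOLOGIES = ("fluorescence", "microarray", "massspec")

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.technology not in self.TECHNOLOGIES:
            raise RequestError(f"unknown technology {self.technology!r}")
        if self.technology == "fluorescence":
            if len(self.targets) != 2:
                raise RequestError("fluorescence measures exactly 2 proteins")
        else:
            if self.resolution not in ("low", "high"):
                raise RequestError(
                    f"{self.technology} requires resolution 'low' or 'high'"
                )

    @property
    def step(self) -> float:
        if self.technology == "fluorescence":
            return 1.0
        return 4.0 if self.resolution == "low" else 2.0

    @property
    def price_key(self) -> str:
        if self.technology == "fluorescence":
            return "fluorescence"
        return f"{self.technology}_{self.resolution}"


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise v_noisy = v + sigma_b*g1 + sigma_s*g2*v, clipped at 0.

    sigma_b is the baseline (signal-independent) SD and sigma_s the
    signal-proportional SD; g1, g2 are independent standard normals per
    measurement.  At large v the relative error approaches sigma_s (~20%
    with the defaults); at v ~ 0 the absolute error approaches sigma_b.
    """

    sigma_b: float = 0.1
    sigma_s: float = 0.2
    clip_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_s < 0:
            raise ValueError("noise SDs must be >= 0")

    def variance(self, x):
        """Variance of a measurement with noise-free value ``x`` (no clipping)."""
        x = np.asarray(x, dtype=float)
        return self.sigma_b**2 + self.sigma_s**2 * x**2


DEFAULT_PRICES: dict[str, int] = {
    "deletion": 800,
    "sirna_knockdown": 350,
    "rbs_decrease": 450,
    "fluorescence": 400,
    "microarray_low": 500,
    "microarray_high": 1000,
    "massspec_low": 500,
    "massspec_high": 1000,
    "gelshift": 1600,
}


class PriceTable(Mapping):
    """Credit cost per experiment kind (positive integers)."""

    def __init__(self, prices: Mapping[str, int] | None = None):
        data = dict(DEFAULT_PRICES)
        if prices:
            data.update(prices)
        for k, v in data.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"price for {k!r} must be a positive integer")
        self._data = {k: int(v) for k, v in data.items()}

    def __getitem__(self, key):
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self):
        return len(self._data)

    def perturbation_cost(self, p: Perturbation) -> int:
        if p.kind == "parameter_scale":
            return 0  # organiser-imposed condition, not a purchasable assay
        return self._data[p.kind]

    def experiment_cost(
        self, perturbations: Sequence[Perturbation], request: MeasurementRequest
    ) -> int:
        return sum(self.perturbation_cost(p) for p in perturbations) + self._data[
            request.price_key
        ]


@dataclass
class CreditLedger:
    """Append-only record of purchases against an initial budget."""

    budget: int
    transactions: list = field(default_factory=list)

    @property
    def balance(self) -> int:
        return self.budget - sum(cost for _, cost in self.transactions)

    def debit(self, description: str, cost: int) -> None:
        if cost > self.balance:
            raise InsufficientCreditsError(
                f"{description}: cost {cost} exceeds balance {self.balance}"
            )
        self.transactions.append((description, cost))


@dataclass(frozen=True)
class Dataset:
    """Purchased (noisy) measurements plus the provenance needed to replay."""

    perturbations: tuple[Perturbation, ...]
    technology: str
    grid: TimeGrid
    species: tuple[str, ...]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        object.__setattr__(self, "species", tuple(self.species))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species), self.grid.n_points):
            raise ValueError("dataset value matrix inconsistent with grid/species")
        object.__setattr__(self, "values", v)

    def get(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(model: ModelInstance, p: Perturbation) -> ModelInstance:
    """Return a new perturbed model; the input model is never modified.

    protein_only semantics: knockdown scales the target's protein
    degradation x10 and rbs_decrease divides all incoming synthesis rates
    by 10 (the menu is the same for both model classes, translation just is
    not modelled explicitly).
    """
    spec = model.spec
    if p.kind == "parameter_scale":
        return model.with_params(model.params.scaled(p.target, p.factor))
    try:
        spec.gene(p.target)
    except KeyError:
        raise UnsupportedPerturbationError(f"unknown gene {p.target!r}") from None
    if p.kind == "deletion":
        ics = dict(model.initial_conditions)
        for s in (mrna_species(p.target), protein_species(p.target)):
            ics.pop(s, None)
        return replace(
            model,
            deleted=model.deleted | {p.target},
            initial_conditions=ics,
        )
    if p.kind == "sirna_knockdown":
        if spec.model_class == MRNA_PROTEIN:
            rates = dict(model.mrna_degradation)
            rates[p.target] = rates.get(p.target, 1.0) * 10.0
            return replace(model, mrna_degradation=rates)
        return model.with_params(model.params.scaled(degradation_id(p.target), 10.0))
    # rbs_decrease
    if spec.model_class == MRNA_PROTEIN:
        return model.with_params(model.params.scaled(rbs_id(p.target), 0.1))
    incoming = spec.incoming(p.target)
    if not incoming:
        raise UnsupportedPerturbationError(
            f"rbs_decrease on {p.target!r}: gene has no incoming synthesis terms"
        )
    params = model.params
    for r in incoming:
        params = params.scaled(synthesis_id(r.id), 0.1)
    return model.with_params(params)


# ---------------------------------------------------------------------------
# noise and measurement
# ---------------------------------------------------------------------------

def add_noise(values, nm: NoiseModel, rng: np.random.Generator):
    """Apply the challenge noise model elementwise, clipping negatives at 0."""
    v = np.asarray(values, dtype=float)
    g1 = rng.standard_normal(v.shape)
    g2 = rng.standard_normal(v.shape)
    noisy = v + nm.sigma_b * g1 + nm.sigma_s * g2 * v
    if nm.clip_at_zero:
        noisy = np.clip(noisy, 0.0, None)
    return noisy


def _measured_species(model: ModelInstance, request: MeasurementRequest) -> tuple[str, ...]:
    spec = model.spec
    if request.technology == "fluorescence":
        for g in request.targets:
            try:
                spec.gene(g)
            except KeyError:
                raise RequestError(f"fluorescence target {g!r} is not a gene") from None
        return tuple(protein_species(g) for g in request.targets)
    if request.technology == "microarray":
        if spec.model_class != MRNA_PROTEIN:
            raise RequestError("microarray is only available for mrna_protein models")
        return tuple(mrna_species(g) for g in spec.gene_ids)
    if spec.model_class != PROTEIN_ONLY:
        raise RequestError("mass spectrometry is only available for protein_only models")
    return tuple(protein_species(g) for g in spec.gene_ids)


def run_experiment(
    model: ModelInstance,
    perturbations: Sequence[Perturbation],
    request: MeasurementRequest,
    ledger: CreditLedger,
    rng: np.random.Generator,
    noise: NoiseModel | None = None,
    prices: PriceTable | None = None,
    t_end: float = 20.0,
    _free: bool = False,
) -> Dataset:
    """Buy one experiment: perturb, simulate, measure, add noise, debit.

    The ledger is checked before any randomness is consumed, so a failed
    purchase leaves both the ledger and the RNG stream untouched.
    """
    noise = noise or NoiseModel()
    prices = prices or PriceTable()
    species = _measured_species(model, request)  # validates request/model pairing
    cost = 0 if _free else prices.experiment_cost(perturbations, request)
    if cost > ledger.balance:
        raise InsufficientCreditsError(
            f"experiment costs {cost}, balance is {ledger.balance}"
        )
    perturbed = model
    for p in perturbations:
        perturbed = apply_perturbation(perturbed, p)
    grid = TimeGrid(0.0, t_end, request.step)
    traj = simulate(perturbed, grid).subset(species)
    values = add_noise(traj.values, noise, rng)
    description = request.price_key + (
        " + " + ", ".join(f"{p.kind}:{p.target}" for p in perturbations)
        if perturbations
        else " (wildtype)"
    )
    ledger.debit(description, cost)
    return Dataset(
        perturbations=tuple(perturbations),
        technology=request.technology,
        grid=grid,
        species=species,
        values=values,
        provenance={
            "cost": cost,
            "request": {
                "technology": request.technology,
                "targets": list(request.targets),
                "resolution": request.resolution,
            },
            "noise": {"sigma_b": noise.sigma_b, "sigma_s": noise.sigma_s},
        },
    )


def gelshift(
    model: ModelInstance,
    regulation_id: str,
    ledger: CreditLedger,
    prices: PriceTable | None = None,
) -> tuple[float, float]:
    """Buy the exact (Kd, h) of one regulation; no noise is added."""
    prices = prices or PriceTable()
    try:
        model.spec.regulation(regulation_id)
    except KeyError:
        raise InvalidParameterError(f"unknown regulation {regulation_id!r}") from None
    cost = prices["gelshift"]
    if cost > ledger.balance:
        raise InsufficientCreditsError(
            f"gel shift costs {cost}, balance is {ledger.balance}"
        )
    ledger.debit(f"gelshift:{regulation_id}", cost)
    return (model.params[kd_id(regulation_id)], model.params[hill_id(regulation_id)])


def initial_dataset(
    model: ModelInstance,
    rng: np.random.Generator,
    noise: NoiseModel | None = None,
    t_end: float = 20.0,
) -> Dataset:
    """The free starting dataset: low-resolution wildtype microarray."""
    if model.spec.model_class != MRNA_PROTEIN:
        raise RequestError("the free initial dataset is a microarray (mrna_protein only)")
    ledger = CreditLedger(budget=0)
    request = MeasurementRequest("microarray", resolution="low")
    return run_experiment(
        model, (), request, ledger, rng, noise=noise, t_end=t_end, _free=True
    )
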