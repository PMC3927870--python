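"""Declarative gene-regulatory-network models and deterministic ODE simulation.

Two model classes are supported, mirroring the two in-silico challenge
networks:

``mrna_protein``
    Each gene *i* is represented by its mRNA :math:`m_i` and protein
    :math:`p_i`.  Transcription is a Hill-type function of the regulator
    proteins, combined multiplicatively (regulators bind independently);
    translation is proportional to mRNA through the ribosomal-binding-site
    (RBS) strength.  Time is non-dimensional, measured in units of the mRNA
    half-life: every mRNA degradation rate is fixed at 1 and all proteins
    share a single degradation rate.

    .. math::

        \\dot m_i = \\mathrm{pro}_i \\prod_r f_r(p_{s(r)}) - \\delta_{m,i} m_i,
        \\qquad
        \\dot p_i = \\mathrm{rbs}_i\\, m_i - \\delta_p\\, p_i

``protein_only``
    Transcription is not modelled; each gene contributes one protein whose
    production is an additive sum of per-regulation synthesis terms (plus a
    basal rate for genes with no incoming regulation), with per-gene
    degradation rates:

    .. math::

        \\dot p_i = b_i + \\sum_r s_r f_r(p_{s(r)}) - \\delta_i p_i

In both classes the regulatory dose-response ``f_r`` is a Hill function of
the regulator concentration with dissociation constant ``Kd`` and Hill
coefficient ``h`` (see :func:`regulation_term`).  A regulation may target up
to two genes sharing an operon, in which case the same term enters both
targets' production.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import ODEintWarning, odeint, solve_ivp
from scipy.optimize import root

try:  # optional JIT kernels; the numpy path below is the reference
    from ._kernels import rhs_mrna_protein as _jit_rhs_mp
    from ._kernels import rhs_protein_only as _jit_rhs_po
except ImportError:  # pragma: no cover - numba not installed
    _jit_rhs_mp = _jit_rhs_po = None

__all__ = [
    "GeneSpec",
    "RegulationSpec",
    "NetworkSpec",
    "ParameterSet",
    "ModelInstance",
    "TimeGrid",
    "Trajectory",
    "InvalidModelError",
    "InvalidParameterError",
    "IntegrationError",
    "DidNotConvergeError",
    "ACTIVATION",
    "REPRESSION",
    "PROTEIN_DEGRADATION",
    "regulation_term",
    "production_rate",
    "simulate",
    "steady_state",
    "count_parameters",
    "parameter_ids",
    "promoter_id",
    "rbs_id",
    "kd_id",
    "hill_id",
    "synthesis_id",
    "degradation_id",
    "basal_id",
    "mrna_species",
    "protein_species",
]

ACTIVATION = "+"
REPRESSION = "-"

MRNA_PROTEIN = "mrna_protein"
PROTEIN_ONLY = "protein_only"

#: parameter id of the shared protein degradation rate of mrna_protein models
PROTEIN_DEGRADATION = "protein_degradation_rate"


class InvalidModelError(ValueError):
    """A network or model instance violates a structural invariant."""


class InvalidParameterError(ValueError):
    """A kinetic parameter is missing, non-positive, or unknown."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; the message carries solver diagnostics."""


class DidNotConvergeError(RuntimeError):
    """Steady-state search did not converge (oscillation or divergence)."""


# ---------------------------------------------------------------------------
# parameter naming conventions
# ---------------------------------------------------------------------------

def promoter_id(gene_id: str) -> str:
    return f"{gene_id}_promoter"


def rbs_id(gene_id: str) -> str:
    return f"{gene_id}_rbs"


def kd_id(reg_id: str) -> str:
    return f"{reg_id}_Kd"


def hill_id(reg_id: str) -> str:
    return f"{reg_id}_h"


def synthesis_id(reg_id: str) -> str:
    return f"{reg_id}_synthesis"


def degradation_id(gene_id: str) -> str:
    return f"{gene_id}_degradation"


def basal_id(gene_id: str) -> str:
    return f"{gene_id}_basal"


def mrna_species(gene_id: str) -> str:
    return f"{gene_id}_mrna"


def protein_species(gene_id: str) -> str:
    return f"{gene_id}_protein"


# ---------------------------------------------------------------------------
# network structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """A gene; ``operon_id`` groups 1-2 co-transcribed genes."""

    id: str
    operon_id: str | None = None


@dataclass(frozen=True)
class RegulationSpec:
    """A directed regulatory link from a source protein to 1-2 target genes.

    ``sign`` is ``"+"`` (activation) or ``"-"`` (repression).  Two targets
    are allowed only when they form an operon (shared promoter).
    """

    id: str
    source: str
    targets: tuple[str, ...]
    sign: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.sign not in (ACTIVATION, REPRESSION):
            raise InvalidModelError(
                f"regulation {self.id}: sign must be '+' or '-', got {self.sign!r}"
            )
        if not 1 <= len(self.targets) <= 2:
            raise InvalidModelError(
                f"regulation {self.id}: must target 1 or 2 genes"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of a regulatory network: genes, regulations, model class."""

    genes: tuple[GeneSpec, ...]
    regulations: tuple[RegulationSpec, ...]
    model_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "regulations", tuple(self.regulations))
        self.validate()

    # -- queries ----------------------------------------------------------

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.genes)

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def regulation(self, reg_id: str) -> RegulationSpec:
        for r in self.regulations:
            if r.id == reg_id:
                return r
        raise KeyError(reg_id)

    def incoming(self, gene_id: str) -> tuple[RegulationSpec, ...]:
        return tuple(r for r in self.regulations if gene_id in r.targets)

    def outgoing(self, gene_id: str) -> tuple[RegulationSpec, ...]:
        return tuple(r for r in self.regulations if r.source == gene_id)

    def regulated_genes(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.genes if self.incoming(g.id))

    def unregulated_genes(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.genes if not self.incoming(g.id))

    def operon_members(self, operon_id: str) -> tuple[str, ...]:
        return tuple(g.id for g in self.genes if g.operon_id == operon_id)

    @property
    def species(self) -> tuple[str, ...]:
        if self.model_class == MRNA_PROTEIN:
            # block layout (all mRNAs, then all proteins) matching the ODE
            # state vector
            return tuple(mrna_species(g.id) for g in self.genes) + tuple(
                protein_species(g.id) for g in self.genes
            )
        return tuple(protein_species(g.id) for g in self.genes)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.model_class not in (MRNA_PROTEIN, PROTEIN_ONLY):
            raise InvalidModelError(
                f"unknown model_class {self.model_class!r}"
            )
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InvalidModelError("gene ids must be unique")
        rids = [r.id for r in self.regulations]
        if len(set(rids)) != len(rids):
            raise InvalidModelError("regulation ids must be unique")
        gene_set = set(ids)
        operons: dict[str, list[str]] = {}
        for g in self.genes:
            if g.operon_id is not None:
                operons.setdefault(g.operon_id, []).append(g.id)
        for oid, members in operons.items():
            if not 1 <= len(members) <= 2:
                raise InvalidModelError(f"operon {oid} must group 1-2 genes")
        if self.model_class == MRNA_PROTEIN and operons:
            raise InvalidModelError("mrna_protein networks have no operons")
        for r in self.regulations:
            if r.source not in gene_set:
                raise InvalidModelError(
                    f"regulation {r.id}: unknown source {r.source!r}"
                )
            for t in r.targets:
                if t not in gene_set:
                    raise InvalidModelError(
                        f"regulation {r.id}: unknown target {t!r}"
                    )
            if len(r.targets) == 2:
                o1 = self.gene(r.targets[0]).operon_id
                o2 = self.gene(r.targets[1]).operon_id
                if o1 is None or o1 != o2:
                    raise InvalidModelError(
                        f"regulation {r.id}: two targets must share an operon"
                    )
        for g in self.genes:
            if len(self.incoming(g.id)) > 2:
                raise InvalidModelError(
                    f"gene {g.id} receives more than 2 regulations"
                )
            if len(self.outgoing(g.id)) > 2:
                raise InvalidModelError(
                    f"gene {g.id} establishes more than 2 regulating links"
                )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def parameter_ids(spec: NetworkSpec) -> tuple[str, ...]:
    """Ordered ids of the free parameters of a network.

    mrna_protein: promoter and RBS strength per gene, (Kd, h) per
    regulation, one shared protein degradation rate.  protein_only:
    (synthesis, Kd, h) per regulation, a degradation rate per gene and a
    basal production rate for each unregulated gene.
    """
    ids: list[str] = []
    if spec.model_class == MRNA_PROTEIN:
        for g in spec.genes:
            ids.append(promoter_id(g.id))
            ids.append(rbs_id(g.id))
        for r in spec.regulations:
            ids.append(kd_id(r.id))
            ids.append(hill_id(r.id))
        ids.append(PROTEIN_DEGRADATION)
    else:
        for r in spec.regulations:
            ids.append(synthesis_id(r.id))
            ids.append(kd_id(r.id))
            ids.append(hill_id(r.id))
        for g in spec.genes:
            ids.append(degradation_id(g.id))
        for g in spec.unregulated_genes():
            ids.append(basal_id(g))
    return tuple(ids)


def count_parameters(spec: NetworkSpec) -> int:
    """Number of free kinetic parameters of a network."""
    return len(parameter_ids(spec))


class ParameterSet(Mapping):
    """Immutable mapping of parameter id to strictly positive value."""

    __slots__ = ("_data",)

    def __init__(self, values: Mapping[str, float]):
        data = {k: float(v) for k, v in values.items()}
        for k, v in data.items():
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"parameter {k!r} must be finite and > 0, got {v}"
                )
        self._data = data

    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"ParameterSet({self._data!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, ParameterSet):
            return self._data == other._data
        return NotImplemented

    def replace(self, **changes: float) -> "ParameterSet":
        new = dict(self._data)
        new.update(changes)
        return ParameterSet(new)

    def scaled(self, param_id: str, factor: float) -> "ParameterSet":
        if param_id not in self._data:
            raise InvalidParameterError(f"unknown parameter {param_id!r}")
        return self.replace(**{param_id: self._data[param_id] * factor})

    def validate(self, spec: NetworkSpec) -> None:
        expected = set(parameter_ids(spec))
        got = set(self._data)
        if expected != got:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise InvalidParameterError(
                f"parameter set mismatch: missing {missing}, unexpected {extra}"
            )


# ---------------------------------------------------------------------------
# model instance, grids, trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid on non-dimensional time."""

    t0: float = 0.0
    t_end: float = 20.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.step <= 0 or self.t_end <= self.t0:
            raise ValueError("TimeGrid requires step > 0 and t_end > t0")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t0) / self.step)) + 1
        return self.t0 + self.step * np.arange(n)

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ModelInstance:
    """A network together with parameters, initial conditions and any
    structural perturbations (gene deletions, mRNA-degradation overrides)."""

    spec: NetworkSpec
    params: ParameterSet
    initial_conditions: Mapping[str, float] = field(default_factory=dict)
    deleted: frozenset = frozenset()
    mrna_degradation: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params.validate(self.spec)
        known = set(self.spec.species)
        ics = dict(self.initial_conditions)
        for s, v in ics.items():
            if s not in known:
                raise InvalidModelError(f"initial condition for unknown species {s!r}")
            if v < 0:
                raise InvalidModelError(f"negative initial condition for {s!r}")
        object.__setattr__(self, "initial_conditions", ics)
        object.__setattr__(self, "deleted", frozenset(self.deleted))
        for g in self.deleted:
            self.spec.gene(g)
        object.__setattr__(self, "mrna_degradation", dict(self.mrna_degradation))

    @property
    def species(self) -> tuple[str, ...]:
        return self.spec.species

    def initial_state(self) -> np.ndarray:
        ics = self.initial_conditions
        y0 = np.array([ics.get(s, 0.0) for s in self.species], dtype=float)
        for g in self.deleted:
            for s in _gene_species(self.spec, g):
                y0[self.species.index(s)] = 0.0
        return y0

    def mrna_degradation_rate(self, gene_id: str) -> float:
        # fixed at 1 in non-dimensional time unless perturbed (siRNA)
        return self.mrna_degradation.get(gene_id, 1.0)

    def with_params(self, params: ParameterSet) -> "ModelInstance":
        return replace(self, params=params)


def _gene_species(spec: NetworkSpec, gene_id: str) -> tuple[str, ...]:
    if spec.model_class == MRNA_PROTEIN:
        return (mrna_species(gene_id), protein_species(gene_id))
    return (protein_species(gene_id),)


@dataclass(frozen=True)
class Trajectory:
    """Noise-free concentrations on a time grid (species x time matrix)."""

    grid: TimeGrid
    species: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species), self.grid.n_points):
            raise ValueError(
                f"trajectory shape {v.shape} inconsistent with "
                f"{len(self.species)} species x {self.grid.n_points} points"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species", tuple(self.species))

    def get(self, species: str) -> np.ndarray:
        try:
            i = self.species.index(species)
        except ValueError:
            raise KeyError(species) from None
        return self.values[i]

    def subset(self, species: Iterable[str]) -> "Trajectory":
        species = tuple(species)
        rows = np.array([self.species.index(s) for s in species])
        return Trajectory(self.grid, species, self.values[rows])


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def regulation_term(P, Kd: float, h: float, sign: str):
    """Hill-type regulatory dose-response, a dimensionless fraction in [0, 1].

    Repression: ``1 / (1 + (P/Kd)^h)``; activation: the complementary
    saturating form ``(P/Kd)^h / (1 + (P/Kd)^h)``.  Both equal 1/2 at
    ``P = Kd`` for any Hill coefficient.

    Accepts scalar or array regulator concentrations ``P >= 0``.
    """
    if Kd <= 0:
        raise InvalidParameterError(f"Kd must be > 0, got {Kd}")
    if h <= 0:
        raise InvalidParameterError(f"Hill coefficient must be > 0, got {h}")
    if sign not in (ACTIVATION, REPRESSION):
        raise InvalidParameterError(f"sign must be '+' or '-', got {sign!r}")
    P = np.maximum(np.asarray(P, dtype=float), 0.0)
    x = _hill_power(P, Kd, h)
    term = x / (1.0 + x) if sign == ACTIVATION else 1.0 / (1.0 + x)
    if term.ndim == 0:
        return float(term)
    return term


def _hill_power(P, Kd, h):
    """(P/Kd)^h computed overflow-safe in log space; 0^h -> 0."""
    with np.errstate(divide="ignore"):
        logx = h * (np.log(P) - np.log(Kd))
    return np.exp(np.clip(logx, -700.0, 700.0))


def production_rate(gene_id: str, state: Mapping[str, float], model: ModelInstance) -> float:
    """Instantaneous production rate of a gene at the given species state.

    For ``mrna_protein`` models this is the mRNA transcription rate
    (promoter strength times the product of regulatory terms; the promoter
    strength itself acts as the basal rate of an unregulated gene).  For
    ``protein_only`` models it is the protein production rate (basal plus
    additive per-regulation synthesis terms).
    """
    spec = model.spec
    spec.gene(gene_id)  # raises KeyError on unknown gene
    if gene_id in model.deleted:
        return 0.0
    params = model.params
    incoming = spec.incoming(gene_id)
    if spec.model_class == MRNA_PROTEIN:
        rate = params[promoter_id(gene_id)]
        for r in incoming:
            P = state[protein_species(r.source)]
            rate *= regulation_term(P, params[kd_id(r.id)], params[hill_id(r.id)], r.sign)
        return rate
    rate = params[basal_id(gene_id)] if not incoming else 0.0
    for r in incoming:
        P = state[protein_species(r.source)]
        rate += params[synthesis_id(r.id)] * regulation_term(
            P, params[kd_id(r.id)], params[hill_id(r.id)], r.sign
        )
    return rate


# ---------------------------------------------------------------------------
# vectorized right-hand side
# ---------------------------------------------------------------------------

class _CompiledModel:
    """Index arrays and parameter vectors for a fast ODE right-hand side."""

    def __init__(self, model: ModelInstance):
        spec = model.spec
        p = model.params
        genes = spec.gene_ids
        g_index = {g: i for i, g in enumerate(genes)}
        G = len(genes)
        self.G = G
        self.model_class = spec.model_class
        active = np.ones(G)
        for g in model.deleted:
            active[g_index[g]] = 0.0
        self.active = active

        regs = spec.regulations
        self.src = np.array([g_index[r.source] for r in regs], dtype=int)
        self.Kd = np.array([p[kd_id(r.id)] for r in regs])
        self.h = np.array([p[hill_id(r.id)] for r in regs])
        self.is_act = np.array([r.sign == ACTIVATION for r in regs])

        # flattened (regulation, target) pairs for additive/multiplicative
        # accumulation of the regulatory terms into target genes
        pair_reg: list[int] = []
        pair_tgt: list[int] = []
        for j, r in enumerate(regs):
            for t in r.targets:
                pair_reg.append(j)
                pair_tgt.append(g_index[t])
        self.pair_reg = np.array(pair_reg, dtype=int)
        self.pair_tgt = np.array(pair_tgt, dtype=int)

        if spec.model_class == MRNA_PROTEIN:
            self.pro = np.array([p[promoter_id(g)] for g in genes])
            self.rbs = np.array([p[rbs_id(g)] for g in genes])
            self.mdeg = np.array([model.mrna_degradation_rate(g) for g in genes])
            self.pdeg = p[PROTEIN_DEGRADATION]
        else:
            self.syn = np.array([p[synthesis_id(r.id)] for r in regs])
            self.deg = np.array([p[degradation_id(g)] for g in genes])
            basal = np.zeros(G)
            for g in spec.unregulated_genes():
                basal[g_index[g]] = p[basal_id(g)]
            self.basal = basal
        self.rhs = self._make_rhs()

    def terms(self, prot: np.ndarray) -> np.ndarray:
        P = np.maximum(prot[self.src], 0.0)
        x = _hill_power(P, self.Kd, self.h)
        return np.where(self.is_act, x / (1.0 + x), 1.0 / (1.0 + x))

    def _make_rhs(self):
        """t-first callable f(t, y); JIT kernel when available."""
        if self.model_class == MRNA_PROTEIN:
            if _jit_rhs_mp is not None:
                args = (self.active, self.src, self.Kd, self.h, self.is_act,
                        self.pair_reg, self.pair_tgt, self.pro, self.rbs,
                        self.mdeg, self.pdeg)
                return lambda t, y: _jit_rhs_mp(y, *args)
        elif _jit_rhs_po is not None:
            args = (self.active, self.src, self.Kd, self.h, self.is_act,
                    self.pair_reg, self.pair_tgt, self.syn, self.deg, self.basal)
            return lambda t, y: _jit_rhs_po(y, *args)
        return self.rhs_numpy

    def rhs_numpy(self, t: float, y: np.ndarray) -> np.ndarray:
        G = self.G
        if self.model_class == MRNA_PROTEIN:
            m, prot = y[:G], y[G:]
            f = self.terms(prot)
            regprod = np.ones(G)
            np.multiply.at(regprod, self.pair_tgt, f[self.pair_reg])
            dm = self.active * self.pro * regprod - self.mdeg * m
            dp = self.active * self.rbs * m - self.pdeg * prot
            return np.concatenate([dm, dp])
        prot = y
        f = self.terms(prot)
        production = self.basal.copy()
        np.add.at(production, self.pair_tgt, self.syn[self.pair_reg] * f[self.pair_reg])
        return self.active * production - self.deg * prot


def simulate(
    model: ModelInstance,
    grid: TimeGrid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_steps: int = 100_000,
) -> Trajectory:
    """Integrate the model ODEs and sample the solution on ``grid``.

    Uses a stiffness-capable solver (lsoda; any other ``method`` is routed
    through ``scipy.integrate.solve_ivp``) with tight default tolerances;
    trajectories with non-negative initial conditions stay non-negative up
    to integration error (tiny negative excursions are clipped to 0).
    """
    compiled = _CompiledModel(model)
    y0 = model.initial_state()
    times = grid.times
    if method == "LSODA":
        with warnings.catch_warnings():
            # failures are detected from full_output and raised below
            warnings.simplefilter("ignore", ODEintWarning)
            y, info = odeint(
                compiled.rhs,
                y0,
                times,
                rtol=rtol,
                atol=atol,
                tfirst=True,
                full_output=True,
                mxstep=max_steps,
            )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE integration failed ({model.spec.model_class}, "
                f"{len(y0)} species): {info['message']}"
            )
        values = y.T
    else:
        sol = solve_ivp(
            compiled.rhs,
            (times[0], times[-1]),
            y0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed ({model.spec.model_class}, "
                f"{len(y0)} species): {sol.message}"
            )
        values = sol.y
    if not np.all(np.isfinite(values)):
        raise IntegrationError("non-finite values in integrated trajectory")
    values = np.clip(values, 0.0, None)
    return Trajectory(grid, model.species, values)


def steady_state(
    model: ModelInstance,
    tol: float = 1e-8,
    t_max: float = 500.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, float]:
    """Converged steady state of the model, or raise on non-convergence.

    Integrates until ``max |dx/dt| < tol * (1 + |x|)`` (checked in chunks
    up to ``t_max``), then root-polishes the algebraic balance
    production = degradation.  Oscillatory or divergent models raise
    :class:`DidNotConvergeError`.
    """
    compiled = _CompiledModel(model)
    y = model.initial_state()
    t = 0.0
    chunk = 50.0
    converged = False
    while t < t_max:
        sol = solve_ivp(
            compiled.rhs, (t, t + chunk), y, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:
            raise IntegrationError(f"steady-state integration failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk
        dy = compiled.rhs(t, y)
        if np.max(np.abs(dy) - tol * (1.0 + np.abs(y))) < 0:
            converged = True
            break
    if not converged:
        raise DidNotConvergeError(
            f"no steady state within t={t_max}: model may oscillate or diverge "
            f"(max |dx/dt| = {np.max(np.abs(compiled.rhs(t, y))):.3g})"
        )
    polished = root(lambda v: compiled.rhs(0.0, v), y, method="hybr")
    if polished.success and np.all(polished.x > -tol):
        y = np.clip(polished.x, 0.0, None)
    residual = np.max(np.abs(compiled.rhs(0.0, y)))
    if residual > 1e-6:
        raise DidNotConvergeError(
            f"steady-state residual {residual:.3g} above tolerance"
        )
    return dict(zip(model.species, y))
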