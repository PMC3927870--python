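"""File formats and session logging.

Models travel as versioned JSON documents; time-course data as long-format
CSV (time, species, value) with a JSON provenance sidecar; submissions as
two-column CSV (parameters), long CSV (predictions) or JSON (links).
A session log is an append-only JSON-lines record of commands and
purchases, sufficient to replay a session and to build usage summaries.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lab import Dataset, Perturbation
from .model import (
    GeneSpec,
    ModelInstance,
    NetworkSpec,
    ParameterSet,
    RegulationSpec,
    TimeGrid,
    Trajectory,
)
from .scoring import LinkPrediction, PredictionSubmission

__all__ = [
    "SchemaError",
    "MODEL_SCHEMA",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "write_trajectory",
    "read_trajectory",
    "write_dataset",
    "read_dataset",
    "read_parameter_submission",
    "write_parameter_submission",
    "read_prediction_submission",
    "write_prediction_submission",
    "read_links",
    "write_links",
    "SessionLog",
    "usage_summary",
]

MODEL_SCHEMA = "grnlab-model/1"


class SchemaError(ValueError):
    """A document does not conform to the expected schema."""


def _require(doc: Mapping, key: str, context: str):
    if key not in doc:
        raise SchemaError(f"{context}: missing required field {key!r}")
    return doc[key]


def model_to_dict(model: ModelInstance) -> dict:
    """Canonical JSON-ready form of a model instance."""
    spec = model.spec
    return {
        "schema": MODEL_SCHEMA,
        "model_class": spec.model_class,
        "genes": [
            {"id": g.id, "operon_id": g.operon_id} for g in spec.genes
        ],
        "regulations": [
            {
                "id": r.id,
                "source": r.source,
                "targets": list(r.targets),
                "sign": r.sign,
            }
            for r in spec.regulations
        ],
        "parameters": {k: model.params[k] for k in sorted(model.params)},
        "initial_conditions": {
            k: v for k, v in sorted(model.initial_conditions.items())
        },
    }


def model_from_dict(doc: Mapping) -> ModelInstance:
    if doc.get("schema") != MODEL_SCHEMA:
        raise SchemaError(
            f"unsupported schema {doc.get('schema')!r}, expected {MODEL_SCHEMA!r}"
        )
    genes = []
    for g in _require(doc, "genes", "model"):
        genes.append(
            GeneSpec(id=_require(g, "id", "gene"), operon_id=g.get("operon_id"))
        )
    regulations = []
    for r in _require(doc, "regulations", "model"):
        rid = _require(r, "id", "regulation")
        regulations.append(
            RegulationSpec(
                id=rid,
                source=_require(r, "source", f"regulation {rid}"),
                targets=tuple(_require(r, "targets", f"regulation {rid}")),
                sign=_require(r, "sign", f"regulation {rid}"),
            )
        )
    spec = NetworkSpec(
        genes=tuple(genes),
        regulations=tuple(regulations),
        model_class=_require(doc, "model_class", "model"),
    )
    try:
        params = ParameterSet(_require(doc, "parameters", "model"))
        model = ModelInstance(
            spec=spec,
            params=params,
            initial_conditions=doc.get("initial_conditions", {}),
        )
    except ValueError as err:
        raise SchemaError(str(err)) from err
    return model


def write_model(model: ModelInstance, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n"
    )


def read_model(path: str | Path) -> ModelInstance:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid JSON: {err}") from err
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# time-course data
# ---------------------------------------------------------------------------

def _long_frame(grid: TimeGrid, species: Sequence[str], values: np.ndarray) -> pd.DataFrame:
    times = grid.times
    return pd.DataFrame(
        {
            "time": np.repeat(times, len(species)),
            "species": list(species) * len(times),
            "value": values.T.ravel(),
        }
    )


def _grid_from_times(times: np.ndarray) -> TimeGrid:
    times = np.unique(times)
    steps = np.diff(times)
    if len(steps) == 0 or np.ptp(steps) > 1e-9:
        raise SchemaError("time points do not form a uniform grid")
    return TimeGrid(float(times[0]), float(times[-1]), float(steps[0]))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    _long_frame(traj.grid, traj.species, traj.values).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("time", "species", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    grid = _grid_from_times(df["time"].to_numpy())
    species = tuple(dict.fromkeys(df["species"]))
    wide = df.pivot_table(index="species", columns="time", values="value")
    values = wide.reindex(species).to_numpy()
    return Trajectory(grid, species, values)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """CSV of the noisy values plus a ``.meta.json`` provenance sidecar."""
    path = Path(path)
    _long_frame(ds.grid, ds.species, ds.values).to_csv(path, index=False)
    sidecar = {
        "technology": ds.technology,
        "perturbations": [
            {"kind": p.kind, "target": p.target, "factor": p.factor}
            for p in ds.perturbations
        ],
        "provenance": ds.provenance,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    traj = read_trajectory(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    perturbations = tuple(
        Perturbation(p["kind"], p["target"], p.get("factor"))
        for p in meta.get("perturbations", [])
    )
    return Dataset(
        perturbations=perturbations,
        technology=meta.get("technology", "unknown"),
        grid=traj.grid,
        species=traj.species,
        values=traj.values,
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# submissions
# ---------------------------------------------------------------------------

def write_parameter_submission(params: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"parameter_id": sorted(params), "value": [params[k] for k in sorted(params)]}
    ).to_csv(path, index=False)


def read_parameter_submission(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    for col in ("parameter_id", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return dict(zip(df["parameter_id"], df["value"].astype(float)))


def write_prediction_submission(sub: PredictionSubmission, path: str | Path) -> None:
    times = sub.grid.times
    pd.DataFrame(
        {
            "protein": np.repeat(sub.proteins, len(times)),
            "time": np.tile(times, len(sub.proteins)),
            "value": sub.values.ravel(),
        }
    ).to_csv(path, index=False)


def read_prediction_submission(path: str | Path) -> PredictionSubmission:
    df = pd.read_csv(path)
    for col in ("protein", "time", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    grid = _grid_from_times(df["time"].to_numpy())
    proteins = tuple(dict.fromkeys(df["protein"]))
    wide = df.pivot_table(index="protein", columns="time", values="value")
    return PredictionSubmission(proteins, wide.reindex(proteins).to_numpy(), grid)


def write_links(links: Sequence[LinkPrediction], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"source": l.source, "sign": l.sign, "destinations": list(l.destinations)}
                for l in links
            ],
            indent=2,
        )
        + "\n"
    )


def read_links(path: str | Path) -> list[LinkPrediction]:
    doc = json.loads(Path(path).read_text())
    return [
        LinkPrediction(
            _require(l, "source", "link"),
            _require(l, "sign", "link"),
            tuple(_require(l, "destinations", "link")),
        )
        for l in doc
    ]


# ---------------------------------------------------------------------------
# session log and usage summaries
# ---------------------------------------------------------------------------

@dataclass
class SessionLog:
    """Append-only record of commands, seeds and purchases."""

    entries: list = field(default_factory=list)

    def record(self, event: str, **fields) -> None:
        self.entries.append({"event": event, **fields})

    def record_purchase(self, experiment: str, cost: int, **fields) -> None:
        self.record("purchase", experiment=experiment, cost=cost, **fields)

    def purchases(self) -> list[dict]:
        return [e for e in self.entries if e["event"] == "purchase"]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SessionLog":
        entries = [
            json.loads(line)
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        return cls(entries)


def usage_summary(log: SessionLog) -> tuple[Counter, Counter]:
    """Histogram of experiment kinds and purchase-sequence transition counts.

    Returns ``(histogram, transitions)``: histogram totals equal the number
    of purchases; transitions count directed edges between consecutive
    purchases (the raw material of a purchase-path diagram).
    """
    purchases = log.purchases()
    if not purchases:
        raise ValueError("session log contains no purchases")
    kinds = [p["experiment"] for p in purchases]
    histogram = Counter(kinds)
    transitions = Counter(zip(kinds, kinds[1:]))
    return histogram, transitions
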