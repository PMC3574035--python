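"""Model documents: a serialisable, human-editable description of the model.

A ModelDocument carries everything needed to rebuild a Model -- species with
initial values/units/roles, parameters with provenance, the reaction table,
and the mode flags -- and round-trips through YAML or JSON without loss.
It is also the in-memory form the SBML importer produces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .model import (
    BOUNDARY_NAMES,
    PARAMETER_NAMES,
    PARAMETER_UNITS,
    SPECIES_NAMES,
    SPECIES_ROLES,
    SPECIES_UNITS,
    BoundarySet,
    Model,
    ModelOptions,
    ParameterSet,
    StateVector,
    reactions_for,
)

__all__ = [
    "ModelDocument",
    "document_from_model",
    "model_from_document",
    "load_model",
    "save_model",
    "parameter_hash",
]

#: identifiers of the published model this implementation follows
MODEL_METADATA = {
    "name": "whole_body_cholesterol_metabolism",
    "biomodels_id": "MODEL1206010000",
}


@dataclass
class ModelDocument:
    """Declarative model description (species, parameters, reactions, modes)."""

    species: list[dict] = field(default_factory=list)
    parameters: list[dict] = field(default_factory=list)
    reactions: list[dict] = field(default_factory=list)
    modes: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=lambda: dict(MODEL_METADATA))
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check internal consistency: every id a rate law uses is declared."""
        declared = {s["id"] for s in self.species} | {
            p["id"] for p in self.parameters}
        dupes = [i for i in declared
                 if sum(1 for s in self.species if s["id"] == i)
                 + sum(1 for p in self.parameters if p["id"] == i) > 1]
        if dupes:
            raise ValueError(f"duplicate identifiers: {sorted(dupes)}")
        import sympy

        for r in self.reactions:
            expr = sympy.sympify(r["rate"], evaluate=False)
            used = {str(s) for s in expr.free_symbols}
            missing = used - declared
            if missing:
                raise ValueError(
                    f"reaction {r['id']!r} references undeclared "
                    f"identifiers: {sorted(missing)}")
            missing_st = set(r.get("stoichiometry", {})) - declared
            if missing_st:
                raise ValueError(
                    f"reaction {r['id']!r} changes undeclared species: "
                    f"{sorted(missing_st)}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("warnings", None)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelDocument":
        doc = cls(
            species=list(d.get("species", [])),
            parameters=list(d.get("parameters", [])),
            reactions=list(d.get("reactions", [])),
            modes=dict(d.get("modes", {})),
            metadata=dict(d.get("metadata", {})),
        )
        doc.validate()
        return doc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelDocument":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelDocument":
        return cls.from_dict(json.loads(text))


def document_from_model(model: Model) -> ModelDocument:
    """Snapshot a Model into a declarative document."""
    species = []
    for name in SPECIES_NAMES:
        species.append({
            "id": name,
            "initial_value": float(getattr(model.state, name)),
            "unit": SPECIES_UNITS[name],
            "role": SPECIES_ROLES[name],
        })
    for name in BOUNDARY_NAMES:
        species.append({
            "id": name,
            "initial_value": float(getattr(model.boundaries, name)),
            "unit": "mg" if name == "DC" else "dimensionless",
            "role": "boundary",
        })
    parameters = []
    for name in PARAMETER_NAMES:
        entry = {
            "id": name,
            "value": float(getattr(model.params, name)),
            "unit": PARAMETER_UNITS[name],
            "provenance": model.params.provenance.get(name, "printed"),
        }
        if name in model.params.printed_values:
            entry["printed_value"] = model.params.printed_values[name]
        parameters.append(entry)
    reactions = [
        {"id": r.id, "name": r.name, "rate": r.rate,
         "stoichiometry": dict(r.stoich)}
        for r in reactions_for(model.options)
    ]
    doc = ModelDocument(
        species=species,
        parameters=parameters,
        reactions=reactions,
        modes={
            "strict_paper_cetp": model.options.strict_paper_cetp,
            "bilinear_bile_return": model.options.bilinear_bile_return,
        },
    )
    doc.validate()
    return doc


def model_from_document(doc: ModelDocument) -> Model:
    """Rebuild a Model from a document (values, provenance and modes)."""
    doc.validate()
    state_vals: dict[str, float] = {}
    boundary_vals: dict[str, float] = {}
    for s in doc.species:
        if s["role"] == "boundary":
            boundary_vals[s["id"]] = float(s["initial_value"])
        else:
            state_vals[s["id"]] = float(s["initial_value"])
    missing = set(SPECIES_NAMES) - set(state_vals)
    if missing:
        raise ValueError(f"document missing species: {sorted(missing)}")
    param_vals = {p["id"]: float(p["value"]) for p in doc.parameters}
    missing_p = set(PARAMETER_NAMES) - set(param_vals)
    if missing_p:
        raise ValueError(f"document missing parameters: {sorted(missing_p)}")
    params = ParameterSet(**{n: param_vals[n] for n in PARAMETER_NAMES})
    params.provenance = {p["id"]: p.get("provenance", "printed")
                         for p in doc.parameters}
    params.printed_values = {p["id"]: p["printed_value"]
                             for p in doc.parameters if "printed_value" in p}
    options = ModelOptions(
        strict_paper_cetp=bool(doc.modes.get("strict_paper_cetp", False)),
        bilinear_bile_return=bool(doc.modes.get("bilinear_bile_return", False)),
    )
    return Model(
        params=params,
        boundaries=BoundarySet(**{n: boundary_vals[n] for n in BOUNDARY_NAMES}),
        state=StateVector(**{n: state_vals[n] for n in SPECIES_NAMES}),
        options=options,
    )


def save_model(model: Model, path: str | Path) -> None:
    """Write a model to YAML (.yaml/.yml) or JSON (.json) by extension."""
    path = Path(path)
    doc = document_from_model(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(doc.to_yaml())
    elif path.suffix == ".json":
        path.write_text(doc.to_json())
    else:
        raise ValueError(f"unknown config extension {path.suffix!r}")


def load_model(path: str | Path) -> Model:
    """Read a model config written by save_model (or hand-edited)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = ModelDocument.from_yaml(text)
    elif path.suffix == ".json":
        doc = ModelDocument.from_json(text)
    else:
        raise ValueError(f"unknown config extension {path.suffix!r}")
    return model_from_document(doc)


def parameter_hash(params: ParameterSet) -> str:
    """Short digest of a full parameterisation, for results traceability."""
    payload = json.dumps(
        {n: getattr(params, n) for n in PARAMETER_NAMES}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
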