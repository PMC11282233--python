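"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites (rows of
the stoichiometric matrix S), reactions (columns, each with flux bounds in
mmol/gDW/h) and one objective reaction whose flux is maximized, typically a
biomass pseudo-reaction whose optimal flux is the growth rate (h^-1).

Sign conventions follow the BiGG ecosystem: in a reaction's stoichiometry a
negative coefficient means the metabolite is consumed, positive produced.
An exchange reaction moves a single extracellular metabolite across the
system boundary; negative exchange flux is uptake, positive is secretion.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Media",
    "ModelValidationError",
    "ModelParseError",
    "DEFAULT_BOUND",
    "EXTRACELLULAR_IDS",
    "parse_formula",
    "format_formula",
    "read_model",
    "write_model",
    "read_media",
    "write_media",
    "apply_media",
    "stoichiometric_matrix",
]

#: Default magnitude for an effectively unconstrained flux bound.
DEFAULT_BOUND = 1000.0

#: Compartment ids treated as extracellular for exchange detection.
EXTRACELLULAR_IDS = frozenset({"e", "e0"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """A model (or reaction/metabolite) violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file could not be parsed in the requested format."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation chemical formula into element counts.

    Multi-letter element symbols are supported ("NaCl" -> {Na: 1, Cl: 1}).
    A trailing charge annotation is not expected here; charge lives on the
    metabolite's dedicated field.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ModelParseError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = match.groups()
        n = int(digits) if digits else 1
        if n < 1:
            raise ModelParseError(f"element count < 1 in formula {formula!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(formula):
        raise ModelParseError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a Hill-style formula string (sorted symbols)."""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items())
    )


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to count; an empty mapping means the
    composition is unknown (balance checks then return "indeterminate").
    ``charge`` is the net charge, or None when unknown.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] = field(default_factory=dict)
    charge: int | None = None

    def validate(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        for el, n in self.formula.items():
            if n < 1:
                raise ModelValidationError(
                    f"metabolite {self.id}: element count {el}={n} < 1"
                )

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment,
                          dict(self.formula), self.charge)


@dataclass
class Reaction:
    """A (pseudo-)reaction: stoichiometry plus flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced). Bounds are in mmol/gDW/h.
    ``is_exchange`` is set automatically for reactions touching exactly one
    metabolite in an extracellular compartment.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_rule: str = ""
    subsystem: str = ""
    is_exchange: bool = False

    def validate(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, self.name, self.gene_rule,
                        self.subsystem, self.is_exchange)


class MetabolicModel:
    """A stoichiometric network with bounds and an objective reaction."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        compartments: Mapping[str, str] | None = None,
        objective_id: str | None = None,
    ):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.compartments: dict[str, str] = dict(compartments or {})
        self.objective_id = objective_id
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        met.validate()
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        rxn.validate()
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id} references undeclared metabolites: "
                + ", ".join(sorted(missing))
            )
        rxn.is_exchange = self._looks_like_exchange(rxn)
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def _looks_like_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolites[met_id].compartment in EXTRACELLULAR_IDS

    def refresh_exchange_flags(self) -> None:
        for rxn in self.reactions.values():
            rxn.is_exchange = self._looks_like_exchange(rxn)

    # -- views ------------------------------------------------------------

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None:
            raise ModelValidationError(f"model {self.id}: no objective set")
        return self.reactions[self.objective_id]

    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def reactions_of(self, met_id: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if met_id in r.stoichiometry]

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` listing every violation."""
        problems: list[str] = []
        if not self.reactions:
            problems.append("model has no reactions")
        if self.objective_id is not None and self.objective_id not in self.reactions:
            problems.append(f"objective reaction {self.objective_id!r} not found")
        for rxn in self.reactions.values():
            try:
                rxn.validate()
            except ModelValidationError as exc:
                problems.append(str(exc))
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    problems.append(
                        f"reaction {rxn.id} references missing metabolite {met_id}"
                    )
        if problems:
            raise ModelValidationError(
                f"model {self.id} invalid: " + "; ".join(problems)
            )

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id, compartments=dict(self.compartments),
                           objective_id=self.objective_id)
        m.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        m.reactions = {k: v.copy() for k, v in self.reactions.items()}
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.objective_id == other.objective_id
            and self.compartments == other.compartments
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


@dataclass
class Media:
    """A nutrient environment: per-exchange maximum uptake rates (>= 0)."""

    name: str
    uptake_limits: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        bad = {k: v for k, v in self.uptake_limits.items() if v < 0}
        if bad:
            raise ModelValidationError(f"media {self.name}: negative uptake limits {bad}")


# ---------------------------------------------------------------------------
# Media I/O: two-column TSV (exchange_id, max_uptake), '#' comments.

def read_media(path: str | Path, name: str | None = None) -> Media:
    path = Path(path)
    limits: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ModelParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            limits[parts[0]] = float(parts[1])
        except ValueError as exc:
            raise ModelParseError(f"{path}:{lineno}: bad rate {parts[1]!r}") from exc
    media = Media(name or path.stem, limits)
    media.validate()
    return media


def write_media(media: Media, path: str | Path) -> None:
    media.validate()
    lines = [f"# media: {media.name}", "# exchange_id\tmax_uptake"]
    lines += [f"{k}\t{v:g}" for k, v in sorted(media.uptake_limits.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def apply_media(
    model: MetabolicModel, media: Media, closed_default: bool = True
) -> MetabolicModel:
    """Return a copy of *model* constrained to *media*.

    Each listed exchange gets ``lower_bound = -max_uptake``. With
    ``closed_default`` every unlisted exchange's lower bound is set to 0, so
    only the listed nutrients can be taken up. Secretion (upper) bounds are
    never touched; the input model is not modified.
    """
    media.validate()
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges}
    unresolved = sorted(set(media.uptake_limits) - exchange_ids)
    if unresolved:
        raise ModelValidationError(
            "unresolved exchange: " + ", ".join(unresolved)
        )
    for rxn in out.exchanges:
        if rxn.id in media.uptake_limits:
            rxn.lower_bound = -media.uptake_limits[rxn.id]
        elif closed_default:
            rxn.lower_bound = 0.0
    return out


def stoichiometric_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """The sparse stoichiometric matrix S (rows = metabolites, cols = reactions).

    Rows and columns are ordered by sorted id so flux vectors from different
    runs over the same model are directly comparable.
    """
    met_index = {m: i for i, m in enumerate(model.metabolite_ids())}
    rows, cols, data = [], [], []
    for j, rxn_id in enumerate(model.reaction_ids()):
        for met_id, coeff in model.reactions[rxn_id].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coeff)
    return sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


# ---------------------------------------------------------------------------
# JSON dialect: a one-to-one mirror of the SBML content, hand-writable.
#
# {
#   "id": "...", "objective": "BIOMASS",
#   "compartments": {"c": "cytosol", "e": "extracellular"},
#   "metabolites": [{"id", "name", "compartment", "formula": {"C": 6, ...}|null,
#                    "charge": int|null}],
#   "reactions":   [{"id", "name", "stoichiometry": {met_id: coeff},
#                    "lower_bound", "upper_bound", "gene_rule", "subsystem"}]
# }

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective": model.objective_id,
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": dict(sorted(m.formula.items())) if m.formula else None,
                "charge": m.charge,
            }
            for m in (model.metabolites[k] for k in model.metabolite_ids())
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in (model.reactions[k] for k in model.reaction_ids())
        ],
    }


def _model_from_dict(doc: dict, source: str = "<json>") -> MetabolicModel:
    try:
        model = MetabolicModel(
            doc["id"], compartments=doc.get("compartments", {}),
            objective_id=doc.get("objective"),
        )
        for m in doc["metabolites"]:
            model.add_metabolite(Metabolite(
                m["id"], m.get("name", ""), m.get("compartment", "c"),
                dict(m.get("formula") or {}),
                m.get("charge"),
            ))
        for r in doc["reactions"]:
            model.add_reaction(Reaction(
                r["id"], {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r.get("lower_bound", -DEFAULT_BOUND)),
                float(r.get("upper_bound", DEFAULT_BOUND)),
                r.get("name", ""), r.get("gene_rule", ""), r.get("subsystem", ""),
            ))
    except KeyError as exc:
        raise ModelParseError(f"{source}: missing required key {exc}") from exc
    if model.objective_id is None:
        raise ModelParseError(f"{source}: model declares no objective reaction")
    if model.objective_id not in model.reactions:
        raise ModelParseError(
            f"{source}: objective reaction {model.objective_id!r} not defined"
        )
    return model


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML Level-3 FBC or the package JSON dialect.

    The format is inferred from the suffix (.xml/.sbml vs .json) when not
    given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "sbml-fbc" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
        model = _model_from_dict(doc, str(path))
    elif format == "sbml-fbc":
        from . import sbml_io
        model = sbml_io.read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    model.refresh_exchange_flags()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model to SBML Level-3 FBC or JSON; refuses invalid models."""
    path = Path(path)
    model.validate()
    if model.objective_id is None:
        raise ModelValidationError(f"model {model.id}: cannot write without an objective")
    if format is None:
        format = "sbml-fbc" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")
    elif format == "sbml-fbc":
        from . import sbml_io
        sbml_io.write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
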