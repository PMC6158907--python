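"""Reading, validating and writing genome-scale models in COBRA JSON.

The COBRA JSON format (schema version 1) is the interchange format used by
COBRApy and the BiGG model repository: a single JSON object with top-level
``reactions``, ``metabolites`` and ``genes`` arrays.  This module parses such
documents into immutable in-memory models, validates structural invariants
(unique identifiers, consistent bounds, stoichiometry referencing declared
metabolites), and writes models back out losslessly — unknown keys are carried
through an opaque ``annotations`` slot so that round-tripping a document
preserves information this package does not interpret.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "MetabolicModel",
    "Diagnostic",
    "ModelFormatError",
    "ModelValidationError",
    "parse_cobra_json",
    "write_cobra_json",
    "validate_model",
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
]

#: COBRA convention for bounds omitted from a document, in mmol/gDW/hr.
DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0

# Keys this package interprets; anything else is preserved verbatim in the
# entity's `annotations` mapping so write_cobra_json is lossless.
_METABOLITE_KEYS = frozenset({"id", "name", "compartment", "formula", "charge"})
_REACTION_KEYS = frozenset(
    {
        "id",
        "name",
        "metabolites",
        "lower_bound",
        "upper_bound",
        "objective_coefficient",
        "gene_reaction_rule",
        "subsystem",
    }
)
_GENE_KEYS = frozenset({"id", "name"})
_MODEL_KEYS = frozenset({"id", "reactions", "metabolites", "genes", "version"})


class ModelFormatError(ValueError):
    """The document is not a COBRA JSON schema-1 model."""


class ModelValidationError(ValueError):
    """The document parses but violates a model invariant."""

    def __init__(self, diagnostics: list["Diagnostic"]):
        self.diagnostics = diagnostics
        super().__init__(
            "model failed validation:\n" + "\n".join(str(d) for d in diagnostics)
        )


@dataclass(frozen=True)
class Metabolite:
    """A metabolite with a BiGG-style identifier such as ``glc__D_e``."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None
    annotations: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class Reaction:
    """A reaction: stoichiometry plus flux bounds in mmol/gDW/hr.

    Negative stoichiometric coefficients denote consumption.  The
    ``gene_reaction_rule`` is stored verbatim and never evaluated.
    """

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    objective_coefficient: float = 0.0
    gene_reaction_rule: str = ""
    subsystem: str | None = None
    annotations: Mapping[str, Any] = field(default_factory=dict)

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions moving a single metabolite."""
        return len(self.stoichiometry) == 1

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class Gene:
    id: str
    name: str = ""
    annotations: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class MetabolicModel:
    """An immutable genome-scale model: the base state of every analysis.

    Reaction and metabolite order is preserved exactly as in the source
    document; columns of the stoichiometric matrix follow reaction order.
    """

    id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    genes: tuple[Gene, ...] = ()
    annotations: Mapping[str, Any] = field(default_factory=dict)

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._reactions_by_id[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.id!r}") from None

    def metabolite(self, metabolite_id: str) -> Metabolite:
        try:
            return self._metabolites_by_id[metabolite_id]
        except KeyError:
            raise KeyError(
                f"no metabolite {metabolite_id!r} in model {self.id!r}"
            ) from None

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self._reactions_by_id

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    def objective_reactions(self) -> tuple[Reaction, ...]:
        """Reactions carrying a nonzero objective coefficient."""
        return tuple(r for r in self.reactions if r.objective_coefficient != 0)

    @property
    def _reactions_by_id(self) -> dict[str, Reaction]:
        cache = self.__dict__.get("_rxn_cache")
        if cache is None:
            cache = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxn_cache", cache)
        return cache

    @property
    def _metabolites_by_id(self) -> dict[str, Metabolite]:
        cache = self.__dict__.get("_met_cache")
        if cache is None:
            cache = {m.id: m for m in self.metabolites}
            object.__setattr__(self, "_met_cache", cache)
        return cache


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the rule violated and the offending id."""

    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"[{self.rule}] {self.subject}: {self.message}"


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def validate_model(model: MetabolicModel) -> list[Diagnostic]:
    """Check model invariants, returning diagnostics instead of raising.

    An empty list means the model is well-formed.  A model with no objective
    reaction is *not* flagged: objective-less models are legal and simply
    cannot be solved until an objective is set.
    """
    diagnostics: list[Diagnostic] = []
    for dup in _duplicates(m.id for m in model.metabolites):
        diagnostics.append(
            Diagnostic("unique-metabolite-id", dup, "metabolite id appears more than once")
        )
    for dup in _duplicates(r.id for r in model.reactions):
        diagnostics.append(
            Diagnostic("unique-reaction-id", dup, "reaction id appears more than once")
        )
    declared = {m.id for m in model.metabolites}
    for met in model.metabolites:
        if not met.id:
            diagnostics.append(
                Diagnostic("nonempty-id", "<metabolite>", "metabolite with empty id")
            )
    for rxn in model.reactions:
        if not rxn.id:
            diagnostics.append(
                Diagnostic("nonempty-id", "<reaction>", "reaction with empty id")
            )
        if rxn.lower_bound > rxn.upper_bound:
            diagnostics.append(
                Diagnostic(
                    "bound-order",
                    rxn.id,
                    f"lower bound {rxn.lower_bound} exceeds upper bound {rxn.upper_bound}",
                )
            )
        if not rxn.stoichiometry:
            diagnostics.append(
                Diagnostic("nonempty-stoichiometry", rxn.id, "reaction has no metabolites")
            )
        for met_id in rxn.stoichiometry:
            if met_id not in declared:
                diagnostics.append(
                    Diagnostic(
                        "declared-metabolite",
                        met_id,
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}",
                    )
                )
    return diagnostics


def _extra(entry: Mapping[str, Any], known: frozenset[str]) -> dict[str, Any]:
    return {k: v for k, v in entry.items() if k not in known}


def parse_cobra_json(document: str | bytes | Mapping[str, Any]) -> MetabolicModel:
    """Parse a COBRA JSON (schema version 1) document into a model.

    Parameters
    ----------
    document:
        JSON text, or an already-decoded mapping.

    Returns
    -------
    MetabolicModel
        With bounds defaulting to ±1000 mmol/gDW/hr and objective
        coefficients defaulting to 0 where the document omits them.

    Raises
    ------
    ModelFormatError
        If a required top-level key is missing, the document is not an
        object, or it declares a schema version other than 1.
    ModelValidationError
        If identifiers are duplicated or stoichiometry references an
        undeclared metabolite (validation is strict by default).
    """
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"document is not valid JSON: {exc}") from exc
    if not isinstance(document, Mapping):
        raise ModelFormatError("COBRA JSON document must be a JSON object")
    for key in ("reactions", "metabolites", "genes"):
        if key not in document:
            raise ModelFormatError(f"missing required top-level key {key!r}")
    version = document.get("version")
    if version not in (None, 1, "1"):
        raise ModelFormatError(
            f"unsupported COBRA JSON schema version {version!r}; only version 1 is supported"
        )

    metabolites = tuple(
        Metabolite(
            id=str(entry["id"]),
            name=str(entry.get("name") or ""),
            compartment=str(entry.get("compartment") or ""),
            formula=entry.get("formula"),
            charge=entry.get("charge"),
            annotations=_extra(entry, _METABOLITE_KEYS),
        )
        for entry in document["metabolites"]
    )
    reactions = tuple(
        Reaction(
            id=str(entry["id"]),
            name=str(entry.get("name") or ""),
            stoichiometry={
                str(k): float(v) for k, v in entry.get("metabolites", {}).items()
            },
            lower_bound=float(entry.get("lower_bound", DEFAULT_LOWER_BOUND)),
            upper_bound=float(entry.get("upper_bound", DEFAULT_UPPER_BOUND)),
            objective_coefficient=float(entry.get("objective_coefficient", 0.0)),
            gene_reaction_rule=str(entry.get("gene_reaction_rule") or ""),
            subsystem=entry.get("subsystem"),
            annotations=_extra(entry, _REACTION_KEYS),
        )
        for entry in document["reactions"]
    )
    genes = tuple(
        Gene(
            id=str(entry["id"]),
            name=str(entry.get("name") or ""),
            annotations=_extra(entry, _GENE_KEYS),
        )
        for entry in document["genes"]
    )
    model = MetabolicModel(
        id=str(document.get("id") or ""),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        annotations=_extra(document, _MODEL_KEYS),
    )
    diagnostics = validate_model(model)
    if diagnostics:
        raise ModelValidationError(diagnostics)
    return model


def write_cobra_json(model: MetabolicModel, *, pretty: bool = False) -> str:
    """Serialize a model to COBRA JSON schema version 1 text.

    ``parse_cobra_json(write_cobra_json(m))`` returns a model equal to ``m``:
    identifiers and integers exactly, bounds and coefficients bit-equal
    (JSON float serialization in Python round-trips IEEE doubles).
    """
    doc: dict[str, Any] = {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                **m.annotations,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_reaction_rule,
                **(
                    {"objective_coefficient": r.objective_coefficient}
                    if r.objective_coefficient != 0
                    else {}
                ),
                **({"subsystem": r.subsystem} if r.subsystem is not None else {}),
                **r.annotations,
            }
            for r in model.reactions
        ],
        "genes": [
            {"id": g.id, "name": g.name, **g.annotations} for g in model.genes
        ],
        "id": model.id,
        "version": "1",
        **model.annotations,
    }
    if pretty:
        return json.dumps(doc, indent=1)
    return json.dumps(doc)
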