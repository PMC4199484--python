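"""Domain types for stoichiometric models, media, and Boolean gene rules.

The JSON model dialect used here is a flat document::

    {
      "id": "<model id>",
      "biomass_reaction_id": "bio1",
      "metabolites": [{"id": "glc_c", "name": "...", "compartment": "c"}, ...],
      "reactions": [
        {
          "id": "rxn1",
          "stoichiometry": {"glc_c": -1.0, "a_c": 1.0},
          "lower_bound": 0.0,
          "upper_bound": 1000.0,
          "gpr": "(g1 and g2) or g3",        # empty string for no rule
          "delta_g": null,                    # kcal/mol, null = unknown
          "is_transporter": false,
          "source_confidence": "high",        # or "low"
          "priority_class": "other"           # central|biosynthesis|peripheral|other
        }, ...
      ]
    }

SBML output targets Level 3 with the fbc package (flux bounds + gene
associations) through COBRApy; the per-reaction attributes that SBML does not
carry (delta_g, is_transporter, source_confidence, priority_class) are written
to a sidecar TSV next to the SBML file (``<path>.attrs.tsv``) and merged back
on read.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
import math
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

COMPARTMENTS = ("c", "e")
SOURCE_CONFIDENCES = ("high", "low")
PRIORITY_CLASSES = ("central", "biosynthesis", "peripheral", "other")

SIDECAR_COLUMNS = [
    "reaction_id",
    "delta_g",
    "is_transporter",
    "source_confidence",
    "priority_class",
]


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprExpression:
    """Boolean tree over gene identifiers with ``and``/``or`` nodes.

    The empty expression (no gene association) evaluates TRUE for every
    knockout set: reactions without genes are never disabled by knockouts.

    Canonical serialization: lowercase ``and``/``or``, children of a node
    sorted lexicographically by their own canonical string, nested nodes of
    the *other* operator fully parenthesized, nested nodes of the same
    operator flattened.
    """

    __slots__ = ("op", "children", "gene")

    def __init__(self, op: Optional[str] = None,
                 children: Optional[list["GprExpression"]] = None,
                 gene: Optional[str] = None):
        self.op = op          # "and", "or", or None for a leaf / empty
        self.children = children or []
        self.gene = gene      # set only on leaves

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls) -> "GprExpression":
        return cls()

    @classmethod
    def leaf(cls, gene: str) -> "GprExpression":
        if not gene:
            raise ValidationError("GPR leaf gene id must be non-empty")
        return cls(gene=gene)

    @classmethod
    def and_(cls, children: Iterable["GprExpression"]) -> "GprExpression":
        return cls._combine("and", children)

    @classmethod
    def or_(cls, children: Iterable["GprExpression"]) -> "GprExpression":
        return cls._combine("or", children)

    @classmethod
    def _combine(cls, op: str, children: Iterable["GprExpression"]) -> "GprExpression":
        flat: list[GprExpression] = []
        for child in children:
            if child.is_empty():
                continue
            if child.op == op:
                flat.extend(child.children)
            else:
                flat.append(child)
        if not flat:
            return cls.empty()
        if len(flat) == 1:
            return flat[0]
        return cls(op=op, children=flat)

    @classmethod
    def parse(cls, text: Optional[str]) -> "GprExpression":
        """Parse a parenthesized and/or expression; '' or None yield empty."""
        if text is None:
            return cls.empty()
        tokens = _TOKEN_RE.findall(text)
        if not tokens:
            return cls.empty()
        pos = 0

        def peek() -> Optional[str]:
            return tokens[pos] if pos < len(tokens) else None

        def take() -> str:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or() -> GprExpression:
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                terms.append(parse_and())
            return cls.or_(terms)

        def parse_and() -> GprExpression:
            factors = [parse_factor()]
            while peek() is not None and peek().lower() == "and":
                take()
                factors.append(parse_factor())
            return cls.and_(factors)

        def parse_factor() -> GprExpression:
            tok = peek()
            if tok is None:
                raise FormatError(f"unexpected end of GPR string: {text!r}")
            if tok == "(":
                take()
                node = parse_or()
                if peek() != ")":
                    raise FormatError(f"unbalanced parenthesis in GPR: {text!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise FormatError(f"unexpected token {tok!r} in GPR: {text!r}")
            return cls.leaf(take())

        node = parse_or()
        if pos != len(tokens):
            raise FormatError(f"trailing tokens in GPR string: {text!r}")
        return node

    # -- queries ------------------------------------------------------------

    def is_empty(self) -> bool:
        return self.op is None and self.gene is None

    def genes(self) -> set[str]:
        if self.is_empty():
            return set()
        if self.gene is not None:
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        """TRUE iff the rule is satisfied with ``knocked_out`` genes absent."""
        ko = set(knocked_out)
        if self.is_empty():
            return True
        if self.gene is not None:
            return self.gene not in ko
        if self.op == "and":
            return all(c.evaluate(ko) for c in self.children)
        return any(c.evaluate(ko) for c in self.children)

    # -- serialization ------------------------------------------------------

    def to_string(self) -> str:
        if self.is_empty():
            return ""
        return self._render(top=True)

    def _render(self, top: bool = False) -> str:
        if self.gene is not None:
            return self.gene
        parts = sorted(child._render() for child in self.children)
        joined = f" {self.op} ".join(parts)
        return joined if top else f"({joined})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return f"GprExpression({self.to_string()!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GprExpression):
            return NotImplemented
        return self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


def evaluate_gpr(gpr: GprExpression, knocked_out: Iterable[str]) -> bool:
    """Module-level convenience wrapper around :meth:`GprExpression.evaluate`."""
    return gpr.evaluate(knocked_out)


# ---------------------------------------------------------------------------
# Network types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprExpression = field(default_factory=GprExpression.empty)
    delta_g: Optional[float] = None
    is_transporter: bool = False
    source_confidence: str = "high"
    priority_class: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}")
        if self.source_confidence not in SOURCE_CONFIDENCES:
            raise ValidationError(
                f"reaction {self.id}: bad source_confidence "
                f"{self.source_confidence!r}")
        if self.priority_class not in PRIORITY_CLASSES:
            raise ValidationError(
                f"reaction {self.id}: bad priority_class "
                f"{self.priority_class!r}")

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=GprExpression.parse(self.gpr.to_string()),
            delta_g=self.delta_g,
            is_transporter=self.is_transporter,
            source_confidence=self.source_confidence,
            priority_class=self.priority_class,
        )

    def is_reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class Media:
    """A growth medium: per-compound maximum uptake fluxes.

    ``complete_flag`` means "open every exchange reaction the model has" and
    is mutually exclusive with an explicit compound list.
    """

    name: str
    uptake_limits: dict[str, float] = field(default_factory=dict)
    complete_flag: bool = False

    def __post_init__(self) -> None:
        if self.complete_flag and self.uptake_limits:
            raise ValidationError(
                f"media {self.name}: complete media cannot list compounds")
        for compound, limit in self.uptake_limits.items():
            if limit < 0:
                raise ValidationError(
                    f"media {self.name}: negative uptake limit for {compound}")

    @classmethod
    def from_tsv(cls, path: str, name: Optional[str] = None) -> "Media":
        """Read a media TSV with header ``compound_id<TAB>max_uptake``."""
        limits: dict[str, float] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            rows = list(reader)
        if rows and rows[0][:2] == ["compound_id", "max_uptake"]:
            rows = rows[1:]
        for row in rows:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: media row needs 2 columns: {row}")
            limits[row[0]] = float(row[1])
        if name is None:
            name = os.path.splitext(os.path.basename(path))[0]
        return cls(name=name, uptake_limits=limits)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["compound_id", "max_uptake"])
            for compound in sorted(self.uptake_limits):
                writer.writerow([compound, repr(self.uptake_limits[compound])])


class MetabolicModel:
    """Stoichiometric network with bounds, GPRs, and a biomass reaction."""

    def __init__(self, id: str, metabolites: Iterable[Metabolite],
                 reactions: Iterable[Reaction], biomass_reaction_id: str):
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            seen: set[str] = set()
            dupes = sorted({m.id for m in self.metabolites
                            if m.id in seen or seen.add(m.id)})
            raise ValidationError(f"model {self.id}: duplicate metabolite ids {dupes}")
        if len(self._rxn_index) != len(self.reactions):
            seen = set()
            dupes = sorted({r.id for r in self.reactions
                            if r.id in seen or seen.add(r.id)})
            raise ValidationError(f"model {self.id}: duplicate reaction ids {dupes}")
        if not self.biomass_reaction_id:
            raise ValidationError(f"model {self.id}: biomass_reaction_id missing")
        if self.biomass_reaction_id not in self._rxn_index:
            raise ValidationError(
                f"model {self.id}: biomass reaction "
                f"{self.biomass_reaction_id!r} not in model")
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValidationError(
                        f"model {self.id}: reaction {rxn.id} references "
                        f"unknown metabolite {met_id!r}")
            spans_both = self._spans_both_compartments(rxn)
            if rxn.is_transporter != spans_both:
                raise ValidationError(
                    f"model {self.id}: reaction {rxn.id} transporter flag "
                    f"({rxn.is_transporter}) inconsistent with compartments")

    def _spans_both_compartments(self, rxn: Reaction) -> bool:
        comps = {self._met_index[m].compartment for m in rxn.stoichiometry}
        return comps == {"c", "e"}

    # -- accessors ----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def is_exchange(self, rxn_id: str) -> bool:
        """Exchange = single-metabolite stoichiometry in compartment 'e'."""
        rxn = self._rxn_index[rxn_id]
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self._met_index[met_id].compartment == "e"

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r.id)]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        for rxn in self.reactions:
            if self.is_exchange(rxn.id) and met_id in rxn.stoichiometry:
                return rxn
        return None

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.gpr.genes()
        return out

    def gene_associated_reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.gpr.genes()]

    # -- mutation -----------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def add_reaction(self, rxn: Reaction,
                     metabolites: Iterable[Metabolite] = ()) -> None:
        if rxn.id in self._rxn_index:
            raise ValidationError(f"model {self.id}: duplicate reaction {rxn.id}")
        for met in metabolites:
            if met.id not in self._met_index:
                self.metabolites.append(met)
                self._met_index[met.id] = met
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ValidationError(
                    f"model {self.id}: cannot add {rxn.id}; metabolite "
                    f"{met_id!r} unknown (pass it in `metabolites`)")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        if rxn_id not in self._rxn_index:
            raise ValidationError(f"model {self.id}: no reaction {rxn_id!r}")
        rxn = self._rxn_index.pop(rxn_id)
        self.reactions.remove(rxn)
        return rxn

    # -- equality -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return _model_to_dict(self) == _model_to_dict(other)

    def __iter__(self) -> Iterator[Reaction]:  # pragma: no cover
        return iter(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k]
                                  for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "delta_g": r.delta_g,
                "is_transporter": r.is_transporter,
                "source_confidence": r.source_confidence,
                "priority_class": r.priority_class,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
    }


def _model_from_dict(doc: dict, source: str = "<json>") -> MetabolicModel:
    for key in ("metabolites", "reactions", "biomass_reaction_id"):
        if key not in doc:
            raise ValidationError(f"{source}: model document missing {key!r}")
    metabolites = [
        Metabolite(id=m["id"], name=m.get("name", ""),
                   compartment=m.get("compartment", "c"))
        for m in doc["metabolites"]
    ]
    reactions = []
    for r in doc["reactions"]:
        reactions.append(Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=GprExpression.parse(r.get("gpr", "")),
            delta_g=None if r.get("delta_g") is None else float(r["delta_g"]),
            is_transporter=bool(r.get("is_transporter", False)),
            source_confidence=r.get("source_confidence", "high"),
            priority_class=r.get("priority_class", "other"),
        ))
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=doc["biomass_reaction_id"],
    )


# ---------------------------------------------------------------------------
# Sidecar attribute TSV
# ---------------------------------------------------------------------------

def write_sidecar(model: MetabolicModel, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SIDECAR_COLUMNS)
        for rxn in sorted(model.reactions, key=lambda r: r.id):
            writer.writerow([
                rxn.id,
                "" if rxn.delta_g is None else repr(rxn.delta_g),
                "1" if rxn.is_transporter else "0",
                rxn.source_confidence,
                rxn.priority_class,
            ])


def read_sidecar(path: str) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows or rows[0] != SIDECAR_COLUMNS:
        raise FormatError(
            f"{path}: sidecar header must be {SIDECAR_COLUMNS}")
    for row in rows[1:]:
        if not row:
            continue
        rxn_id, dg, transporter, confidence, priority = row
        out[rxn_id] = {
            "delta_g": None if dg == "" else float(dg),
            "is_transporter": transporter == "1",
            "source_confidence": confidence,
            "priority_class": priority,
        }
    return out


def _apply_sidecar(model: MetabolicModel, attrs: dict[str, dict]) -> None:
    for rxn in model.reactions:
        if rxn.id in attrs:
            a = attrs[rxn.id]
            rxn.delta_g = a["delta_g"]
            rxn.is_transporter = a["is_transporter"]
            rxn.source_confidence = a["source_confidence"]
            rxn.priority_class = a["priority_class"]
    model.validate()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return path + ".attrs.tsv"


def read_model(path: str, format: str = "json",
               sidecar: Optional[str] = None) -> MetabolicModel:
    """Read a model from JSON (native dialect) or SBML L3/fbc.

    For SBML the attribute sidecar ``<path>.attrs.tsv`` is merged in when
    present; missing sidecar values default to delta_g unknown, transporter
    inferred from compartments, high confidence, priority class "other".
    """
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: "
                              f"{exc.msg}") from exc
        model = _model_from_dict(doc, source=path)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValidationError(f"unknown model format {format!r}")

    sidecar_file = sidecar or _sidecar_path(path)
    if os.path.exists(sidecar_file):
        _apply_sidecar(model, read_sidecar(sidecar_file))
    return model


def write_model(model: MetabolicModel, path: str, format: str = "json") -> None:
    """Write a model; SBML additionally writes the attribute sidecar TSV."""
    model.validate()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sbml":
        _write_sbml(model, path)
        write_sidecar(model, _sidecar_path(path))
    else:
        raise ValidationError(f"unknown model format {format!r}")


# -- SBML via COBRApy -------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        cm = cobra.Metabolite(met.id, name=met.name, compartment=met.compartment)
        mets[met.id] = cm
    cmodel.add_metabolites(list(mets.values()))
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        cr.add_metabolites({mets[m]: coef
                            for m, coef in rxn.stoichiometry.items()})
        gpr_string = rxn.gpr.to_string()
        if gpr_string:
            cr.gene_reaction_rule = gpr_string
    cmodel.objective = cmodel.reactions.get_by_id(model.biomass_reaction_id)
    return cmodel


def _write_sbml(model: MetabolicModel, path: str) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), path)


def _read_sbml(path: str) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        cmodel = read_sbml_model(path)
    except Exception as exc:  # libsbml raises a mixed bag of types
        raise FormatError(f"{path}: SBML parse failed: {exc}") from exc

    metabolites = [Metabolite(id=m.id, name=m.name or "",
                              compartment=m.compartment)
                   for m in cmodel.metabolites]
    comp_of = {m.id: m.compartment for m in metabolites}
    biomass_id = None
    reactions = []
    for cr in cmodel.reactions:
        stoich = {m.id: coef for m, coef in cr.metabolites.items()}
        comps = {comp_of[m] for m in stoich}
        reactions.append(Reaction(
            id=cr.id,
            stoichiometry=stoich,
            lower_bound=cr.lower_bound,
            upper_bound=cr.upper_bound,
            gpr=GprExpression.parse(cr.gene_reaction_rule),
            is_transporter=(comps == {"c", "e"}),
        ))
        if cr.objective_coefficient:
            biomass_id = cr.id
    if biomass_id is None:
        raise ValidationError(f"{path}: no objective (biomass) reaction in SBML")
    return MetabolicModel(id=cmodel.id or "model", metabolites=metabolites,
                          reactions=reactions, biomass_reaction_id=biomass_id)


# ---------------------------------------------------------------------------
# Misc helpers
# ---------------------------------------------------------------------------

def almost_equal(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
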