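"""Read, modify, and write a minimal-but-faithful subset of SBML.

Supports SBML Level 2 Version 4 and Level 3 Version 2 core documents
containing compartments, species, global parameters, and reactions with
kinetic laws drawn from the arithmetic MathML subset in :mod:`aspasia.expr`.
Species initialisation is normalised to concentration on read
(``initialAmount`` is divided by the compartment size). Unsupported
constructs (events, assignment/algebraic rules, function definitions) are
collected as warnings on the returned document rather than silently dropped;
events are never modified or rewritten.

Numeric values are serialised with :func:`repr`, i.e. shortest string that
round-trips the IEEE double, so write -> parse preserves every value
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from xml.etree import ElementTree as ET

from .expr import MATHML_NS, Expr, ExprError, from_mathml, to_mathml

ASP_NS = "urn:aspasia:annotations"

SBML_NS = {
    "L2V4": "http://www.sbml.org/sbml/level2/version4",
    "L3V2": "http://www.sbml.org/sbml/level3/version2/core",
}
_NS_TO_LV = {v: k for k, v in SBML_NS.items()}


class SBMLParseError(ValueError):
    """Malformed XML or document outside the supported SBML subset."""


class SBMLValidationError(ValueError):
    """Document violates a ModelDocument invariant."""


@dataclass(frozen=True)
class SpeciesRecord:
    id: str
    compartment: str
    initial_concentration: float
    boundary: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.initial_concentration) or self.initial_concentration < 0:
            raise SBMLValidationError(
                f"species {self.id!r}: initial concentration must be finite and "
                f">= 0, got {self.initial_concentration!r}"
            )


@dataclass(frozen=True)
class ReactionRecord:
    id: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    kinetic_law: Expr

    def __post_init__(self) -> None:
        for sid, stoich in (*self.reactants, *self.products):
            if stoich <= 0:
                raise SBMLValidationError(
                    f"reaction {self.id!r}: stoichiometry for {sid!r} must be > 0"
                )


@dataclass(frozen=True)
class ModelDocument:
    """In-memory SBML model: the subset the toolkit reads, perturbs, writes."""

    model_id: str
    level_version: str = "L3V2"
    compartments: tuple[tuple[str, float], ...] = (("default", 1.0),)
    species: tuple[SpeciesRecord, ...] = ()
    parameters: tuple[tuple[str, float, bool], ...] = ()
    reactions: tuple[ReactionRecord, ...] = ()
    annotations: tuple[tuple[str, str], ...] = ()  # free-form (key, value) notes
    warnings: tuple[str, ...] = field(default=(), compare=False)

    # -- lookups ------------------------------------------------------------
    def parameter_ids(self) -> list[str]:
        return [p[0] for p in self.parameters]

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def compartment_ids(self) -> list[str]:
        return [c[0] for c in self.compartments]

    def get_parameter(self, pid: str) -> float:
        for p, v, _ in self.parameters:
            if p == pid:
                return v
        raise KeyError(pid)

    def get_species(self, sid: str) -> SpeciesRecord:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def compartment_size(self, cid: str) -> float:
        for c, size in self.compartments:
            if c == cid:
                return size
        raise KeyError(cid)

    def validate(self) -> None:
        """Check invariants; raise SBMLValidationError on the first failure."""
        ids = self.parameter_ids() + self.species_ids()
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise SBMLValidationError(f"duplicate id {i!r}")
            seen.add(i)
        known = seen | set(self.compartment_ids())
        for rxn in self.reactions:
            unknown = sorted(rxn.kinetic_law.symbols() - known)
            if unknown:
                raise SBMLValidationError(
                    f"kinetic law of reaction {rxn.id!r} references undeclared "
                    f"symbol(s): {', '.join(unknown)}"
                )
            for sid, _ in (*rxn.reactants, *rxn.products):
                if sid not in set(self.species_ids()):
                    raise SBMLValidationError(
                        f"reaction {rxn.id!r} references unknown species {sid!r}"
                    )


# ---------------------------------------------------------------------------
# parsing


def parse_model(xml_text: str) -> ModelDocument:
    """Parse an SBML (L2V4 / L3V2) document string into a ModelDocument."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise SBMLParseError(f"malformed XML: {exc}") from None

    ns_uri = root.tag[1:].split("}", 1)[0] if root.tag.startswith("{") else ""
    if ns_uri not in _NS_TO_LV:
        raise SBMLParseError(
            f"unsupported or missing SBML namespace {ns_uri!r}; "
            f"supported: {sorted(SBML_NS.values())}"
        )
    lv = _NS_TO_LV[ns_uri]
    ns = f"{{{ns_uri}}}"

    model_el = root.find(ns + "model")
    if model_el is None:
        raise SBMLParseError("document has no <model> element")

    warnings: list[str] = []
    for unsupported in ("listOfEvents", "listOfRules", "listOfFunctionDefinitions",
                        "listOfConstraints", "listOfInitialAssignments"):
        if model_el.find(ns + unsupported) is not None:
            warnings.append(
                f"<{unsupported}> present but outside the supported subset; "
                "preserved semantics are NOT guaranteed and the construct is "
                "not rewritten"
            )

    compartments = []
    for c in model_el.iterfind(f"{ns}listOfCompartments/{ns}compartment"):
        size = c.get("size", c.get("volume", "1"))
        compartments.append((c.get("id"), float(size)))
    if not compartments:
        compartments = [("default", 1.0)]
    comp_size = dict(compartments)

    species = []
    for s in model_el.iterfind(f"{ns}listOfSpecies/{ns}species"):
        sid = s.get("id")
        comp = s.get("compartment", compartments[0][0])
        if s.get("initialConcentration") is not None:
            init = float(s.get("initialConcentration"))
        elif s.get("initialAmount") is not None:
            init = float(s.get("initialAmount")) / comp_size.get(comp, 1.0)
        else:
            init = 0.0
        boundary = s.get("boundaryCondition", "false") == "true"
        species.append(SpeciesRecord(sid, comp, init, boundary))

    parameters = []
    for p in model_el.iterfind(f"{ns}listOfParameters/{ns}parameter"):
        value = float(p.get("value", "nan"))
        constant = p.get("constant", "true") == "true"
        parameters.append((p.get("id"), value, constant))

    reactions = []
    for r in model_el.iterfind(f"{ns}listOfReactions/{ns}reaction"):
        rid = r.get("id")
        reactants = tuple(
            (sr.get("species"), float(sr.get("stoichiometry", "1")))
            for sr in r.iterfind(f"{ns}listOfReactants/{ns}speciesReference")
        )
        products = tuple(
            (sr.get("species"), float(sr.get("stoichiometry", "1")))
            for sr in r.iterfind(f"{ns}listOfProducts/{ns}speciesReference")
        )
        kl = r.find(f"{ns}kineticLaw")
        if kl is None:
            raise SBMLParseError(f"reaction {rid!r} has no kineticLaw")
        math_el = kl.find(f"{{{MATHML_NS}}}math")
        if math_el is None:
            raise SBMLParseError(f"reaction {rid!r} kineticLaw has no <math>")
        if kl.find(f"{ns}listOfLocalParameters") is not None or kl.find(
            f"{ns}listOfParameters"
        ) is not None:
            warnings.append(
                f"reaction {rid!r}: local kineticLaw parameters are outside the "
                "supported subset and were ignored"
            )
        try:
            law = from_mathml(math_el)
        except ExprError as exc:
            raise SBMLParseError(f"reaction {rid!r}: {exc}") from None
        reactions.append(ReactionRecord(rid, reactants, products, law))

    annotations = []
    for note in model_el.iterfind(f"{ns}annotation/{{{ASP_NS}}}provenance"):
        for item in note:
            annotations.append((item.tag.rsplit("}", 1)[-1], (item.text or "").strip()))

    doc = ModelDocument(
        model_id=model_el.get("id", "model"),
        level_version=lv,
        compartments=tuple(compartments),
        species=tuple(species),
        parameters=tuple(parameters),
        reactions=tuple(reactions),
        annotations=tuple(annotations),
        warnings=tuple(warnings),
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the double."""
    return repr(float(x))


def write_model(doc: ModelDocument) -> str:
    """Serialise a ModelDocument to an SBML XML string of its level/version."""
    doc.validate()
    ns_uri = SBML_NS[doc.level_version]
    ET.register_namespace("", ns_uri)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("asp", ASP_NS)
    ns = f"{{{ns_uri}}}"

    attrs = {"level": "2", "version": "4"} if doc.level_version == "L2V4" else {
        "level": "3", "version": "2"}
    root = ET.Element(ns + "sbml", attrs)
    model = ET.SubElement(root, ns + "model", {"id": doc.model_id})

    if doc.annotations:
        ann = ET.SubElement(model, ns + "annotation")
        holder = ET.SubElement(ann, f"{{{ASP_NS}}}provenance")
        for key, value in doc.annotations:
            item = ET.SubElement(holder, f"{{{ASP_NS}}}{key}")
            item.text = value

    loc = ET.SubElement(model, ns + "listOfCompartments")
    for cid, size in doc.compartments:
        c_attrs = {"id": cid, "size": _fmt(size)}
        if doc.level_version == "L3V2":
            c_attrs["constant"] = "true"
        ET.SubElement(loc, ns + "compartment", c_attrs)

    los = ET.SubElement(model, ns + "listOfSpecies")
    for sp in doc.species:
        s_attrs = {
            "id": sp.id,
            "compartment": sp.compartment,
            "initialConcentration": _fmt(sp.initial_concentration),
            "boundaryCondition": "true" if sp.boundary else "false",
        }
        if doc.level_version == "L3V2":
            s_attrs["hasOnlySubstanceUnits"] = "false"
            s_attrs["constant"] = "false"
        ET.SubElement(los, ns + "species", s_attrs)

    if doc.parameters:
        lop = ET.SubElement(model, ns + "listOfParameters")
        for pid, value, constant in doc.parameters:
            ET.SubElement(
                lop, ns + "parameter",
                {"id": pid, "value": _fmt(value),
                 "constant": "true" if constant else "false"},
            )

    if doc.reactions:
        lor = ET.SubElement(model, ns + "listOfReactions")
        for rxn in doc.reactions:
            r_attrs = {"id": rxn.id, "reversible": "false"}
            if doc.level_version == "L2V4":
                r_attrs["fast"] = "false"
            r_el = ET.SubElement(lor, ns + "reaction", r_attrs)
            for list_tag, refs in (
                ("listOfReactants", rxn.reactants),
                ("listOfProducts", rxn.products),
            ):
                if not refs:
                    continue
                l_el = ET.SubElement(r_el, ns + list_tag)
                for sid, stoich in refs:
                    sr_attrs = {"species": sid, "stoichiometry": _fmt(stoich)}
                    if doc.level_version == "L3V2":
                        sr_attrs["constant"] = "true"
                    ET.SubElement(l_el, ns + "speciesReference", sr_attrs)
            kl = ET.SubElement(r_el, ns + "kineticLaw")
            kl.append(to_mathml(rxn.kinetic_law))

    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    )


# ---------------------------------------------------------------------------
# targeted edits


def set_value(doc: ModelDocument, target_id: str, value: float) -> ModelDocument:
    """Return a copy of *doc* with one parameter value or species initial
    concentration replaced; everything else is untouched."""
    param_ids = doc.parameter_ids()
    if target_id in param_ids:
        new_params = tuple(
            (pid, value if pid == target_id else v, const)
            for pid, v, const in doc.parameters
        )
        return replace(doc, parameters=new_params)
    species_ids = doc.species_ids()
    if target_id in species_ids:
        new_species = tuple(
            replace(sp, initial_concentration=value) if sp.id == target_id else sp
            for sp in doc.species
        )
        return replace(doc, species=new_species)
    available = ", ".join(param_ids + species_ids)
    raise KeyError(
        f"unknown target {target_id!r}; available parameters/species: {available}"
    )


def with_annotation(doc: ModelDocument, key: str, value: str) -> ModelDocument:
    return replace(doc, annotations=doc.annotations + ((key, str(value)),))
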