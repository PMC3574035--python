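"""SBML interchange: export the model as an SBML Level 3 document and read
such documents back.

Every flux in the reaction table becomes an SBML reaction with a content-
MathML kinetic law; the seven enzyme/receptor activities and dietary
cholesterol are species with ``boundaryCondition="true"``.  Unit annotations
carry the model's mixed units (tissue pools in mg, plasma in mg/dL) verbatim;
no plasma-volume conversion is invented, so the document reproduces the
published parameterisation rather than a dimensionally homogeneous one.

The writer and reader are self-contained (lxml for XML, sympy for the rate
expressions).  ``validate_sbml`` performs structural validation: namespace
and level, unique identifiers, declared references, one kinetic law per
reaction.  The CETP mode and bile-return mode are recorded in a
machine-readable annotation so both printed-equation variants remain
exchangeable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Mapping

import sympy
from lxml import etree

from .config import ModelDocument, document_from_model, model_from_document
from .model import Model

__all__ = [
    "export_sbml",
    "import_sbml",
    "validate_sbml",
    "document_rhs_evaluator",
    "SBML_NS",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:cholsim:model-modes"

_SBML = "{%s}" % SBML_NS
_MML = "{%s}" % MATHML_NS

#: physiological compartments of the network diagram
_COMPARTMENTS = {
    "intake": ("DC",),
    "intestinal": ("IC", "IBS"),
    "excreted": ("EC", "EBS"),
    "hepatic": ("HBS", "HFC", "HCE", "HLDLR", "HLDLRD", "ACAT", "CEH"),
    "plasma": ("VLDLC", "IDLC", "LDLC", "HDLC", "NHDL",
               "LPL", "HSL", "LCAT", "CETP", "SRB1"),
    "peripheral": ("PLDLR", "PLDLRD", "PFC", "PCE", "PSS"),
}
_SPECIES_COMPARTMENT = {
    sp: comp for comp, names in _COMPARTMENTS.items() for sp in names
}


class SBMLError(ValueError):
    """Raised for malformed or unsupported SBML input/output."""


# ---------------------------------------------------------------------------
# MathML <-> sympy
# ---------------------------------------------------------------------------


def _expr_to_mathml(expr: sympy.Expr, parent: etree._Element) -> None:
    if isinstance(expr, sympy.Symbol):
        ci = etree.SubElement(parent, _MML + "ci")
        ci.text = f" {expr.name} "
        return
    if expr.is_Number:
        cn = etree.SubElement(parent, _MML + "cn")
        if expr.is_Integer:
            cn.set("type", "integer")
            cn.text = f" {int(expr)} "
        elif expr.is_Rational and not expr.is_Integer:
            # emit rationals as real numbers; kinetic laws here never need
            # exact rational arithmetic
            cn.text = f" {float(expr)!r} "
        else:
            cn.text = f" {float(expr)!r} "
        return
    apply_ = etree.SubElement(parent, _MML + "apply")
    if isinstance(expr, sympy.Add):
        etree.SubElement(apply_, _MML + "plus")
        for arg in expr.args:
            _expr_to_mathml(arg, apply_)
    elif isinstance(expr, sympy.Mul):
        num, den = expr.as_numer_denom()
        if den != 1:
            etree.SubElement(apply_, _MML + "divide")
            _expr_to_mathml(num, apply_)
            _expr_to_mathml(den, apply_)
        else:
            etree.SubElement(apply_, _MML + "times")
            for arg in expr.args:
                _expr_to_mathml(arg, apply_)
    elif isinstance(expr, sympy.Pow):
        etree.SubElement(apply_, _MML + "power")
        _expr_to_mathml(expr.base, apply_)
        _expr_to_mathml(expr.exp, apply_)
    else:
        raise SBMLError(f"cannot serialise expression node {expr!r}")


def _mathml_to_expr(node: etree._Element) -> sympy.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLError("math element must have exactly one child")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return sympy.Symbol(node.text.strip())
    if tag == "cn":
        return sympy.Float(node.text.strip()) if "." in node.text or "e" in \
            node.text.lower() else sympy.Integer(node.text.strip())
    if tag != "apply":
        raise SBMLError(f"unsupported MathML element <{tag}>")
    children = [c for c in node if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = [_mathml_to_expr(c) for c in children[1:]]
    if op == "plus":
        return sympy.Add(*args)
    if op == "times":
        return sympy.Mul(*args)
    if op == "minus":
        if len(args) == 1:
            return -args[0]
        return args[0] - args[1]
    if op == "divide":
        if len(args) != 2:
            raise SBMLError("divide takes exactly two operands")
        return args[0] / args[1]
    if op == "power":
        return sympy.Pow(*args)
    raise SBMLError(f"unsupported MathML operator <{op}>")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_sbml(model: Model) -> str:
    """Serialise a Model to an SBML Level 3 Version 1 document (XML string)."""
    doc = document_from_model(model)
    nsmap = {None: SBML_NS}
    sbml = etree.Element(_SBML + "sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    mod = etree.SubElement(sbml, _SBML + "model")
    mod.set("id", doc.metadata.get("name", "model"))
    mod.set("name", "Whole-body cholesterol metabolism")

    annot = etree.SubElement(mod, _SBML + "annotation")
    modes_el = etree.SubElement(annot, "{%s}modes" % ANNOT_NS,
                                nsmap={"cholsim": ANNOT_NS})
    for key, value in doc.modes.items():
        modes_el.set(key, str(bool(value)).lower())
    for key, value in doc.metadata.items():
        modes_el.set(key, str(value))

    comps = etree.SubElement(mod, _SBML + "listOfCompartments")
    for comp in _COMPARTMENTS:
        c = etree.SubElement(comps, _SBML + "compartment")
        c.set("id", comp)
        c.set("size", "1")
        c.set("constant", "true")

    species_el = etree.SubElement(mod, _SBML + "listOfSpecies")
    for s in doc.species:
        el = etree.SubElement(species_el, _SBML + "species")
        el.set("id", s["id"])
        el.set("compartment", _SPECIES_COMPARTMENT[s["id"]])
        el.set("initialAmount", repr(float(s["initial_value"])))
        el.set("hasOnlySubstanceUnits", "true")
        el.set("boundaryCondition",
               "true" if s["role"] == "boundary" else "false")
        el.set("constant", "false")
        el.set("name", f"{s['id']} [{s['unit']}] ({s['role']})")

    params_el = etree.SubElement(mod, _SBML + "listOfParameters")
    for p in doc.parameters:
        el = etree.SubElement(params_el, _SBML + "parameter")
        el.set("id", p["id"])
        el.set("value", repr(float(p["value"])))
        el.set("constant", "true")
        el.set("name", f"{p['id']} [{p['unit']}] ({p['provenance']})")

    rxns_el = etree.SubElement(mod, _SBML + "listOfReactions")
    param_ids = {p["id"] for p in doc.parameters}
    for r in doc.reactions:
        el = etree.SubElement(rxns_el, _SBML + "reaction")
        el.set("id", r["id"])
        el.set("name", r["name"])
        el.set("reversible", "false")
        el.set("fast", "false")
        reactants = {k: -v for k, v in r["stoichiometry"].items() if v < 0}
        products = {k: v for k, v in r["stoichiometry"].items() if v > 0}
        expr = sympy.sympify(r["rate"])
        rate_species = {str(s) for s in expr.free_symbols} - param_ids
        modifiers = sorted(rate_species - set(reactants) - set(products))
        if reactants:
            lst = etree.SubElement(el, _SBML + "listOfReactants")
            for sp, stoich in reactants.items():
                ref = etree.SubElement(lst, _SBML + "speciesReference")
                ref.set("species", sp)
                ref.set("stoichiometry", repr(float(stoich)))
                ref.set("constant", "true")
        if products:
            lst = etree.SubElement(el, _SBML + "listOfProducts")
            for sp, stoich in products.items():
                ref = etree.SubElement(lst, _SBML + "speciesReference")
                ref.set("species", sp)
                ref.set("stoichiometry", repr(float(stoich)))
                ref.set("constant", "true")
        if modifiers:
            lst = etree.SubElement(el, _SBML + "listOfModifiers")
            for sp in modifiers:
                ref = etree.SubElement(lst, _SBML + "modifierSpeciesReference")
                ref.set("species", sp)
        kl = etree.SubElement(el, _SBML + "kineticLaw")
        math = etree.SubElement(kl, _MML + "math",
                                nsmap={None: MATHML_NS})
        try:
            _expr_to_mathml(expr, math)
        except SBMLError as exc:
            raise SBMLError(f"reaction {r['id']!r}: {exc}") from exc

    return etree.tostring(sbml, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------


def _parse(source: str | Path) -> etree._Element:
    if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source
            and source.endswith((".xml", ".sbml"))):
        tree = etree.parse(str(source))
        return tree.getroot()
    try:
        return etree.fromstring(source.encode())
    except etree.XMLSyntaxError as exc:
        raise SBMLError(f"malformed XML: {exc}") from exc


def import_sbml(source: str | Path) -> ModelDocument:
    """Read an SBML document into a ModelDocument.

    Species, parameters and reactions (with kinetic laws) are reconstructed;
    constructs this model family does not use (rules, events, function
    definitions, initial assignments) are reported in ``doc.warnings`` rather
    than silently dropped.  References to undeclared identifiers raise an
    error naming the id.
    """
    root = _parse(source)
    if etree.QName(root).namespace != SBML_NS:
        raise SBMLError(
            f"not an SBML Level 3 document (namespace {etree.QName(root).namespace!r})")
    mod = root.find(_SBML + "model")
    if mod is None:
        raise SBMLError("document has no <model> element")

    doc = ModelDocument(species=[], parameters=[], reactions=[],
                        modes={}, metadata={})

    modes_el = mod.find(f"{_SBML}annotation/{{{ANNOT_NS}}}modes")
    if modes_el is not None:
        for key in ("strict_paper_cetp", "bilinear_bile_return"):
            if key in modes_el.attrib:
                doc.modes[key] = modes_el.get(key) == "true"
        for key in ("name", "biomodels_id"):
            if key in modes_el.attrib:
                doc.metadata[key] = modes_el.get(key)

    for el in mod.findall(f"{_SBML}listOfSpecies/{_SBML}species"):
        name = el.get("name", "")
        unit = name[name.find("[") + 1:name.find("]")] if "[" in name else ""
        boundary = el.get("boundaryCondition") == "true"
        role = "boundary" if boundary else (
            name[name.find("(") + 1:name.find(")")] if "(" in name else "dynamic")
        doc.species.append({
            "id": el.get("id"),
            "initial_value": float(el.get("initialAmount", "0")),
            "unit": unit,
            "role": role,
        })
    for el in mod.findall(f"{_SBML}listOfParameters/{_SBML}parameter"):
        name = el.get("name", "")
        unit = name[name.find("[") + 1:name.find("]")] if "[" in name else ""
        prov = name[name.find("(") + 1:name.find(")")] if "(" in name else "user"
        doc.parameters.append({
            "id": el.get("id"),
            "value": float(el.get("value")),
            "unit": unit,
            "provenance": prov,
        })

    declared = {s["id"] for s in doc.species} | {p["id"] for p in doc.parameters}
    for el in mod.findall(f"{_SBML}listOfReactions/{_SBML}reaction"):
        rid = el.get("id")
        stoich: dict[str, float] = {}
        for ref in el.findall(f"{_SBML}listOfReactants/{_SBML}speciesReference"):
            sp = ref.get("species")
            if sp not in declared:
                raise SBMLError(
                    f"reaction {rid!r} references undeclared species {sp!r}")
            stoich[sp] = stoich.get(sp, 0.0) - float(ref.get("stoichiometry", "1"))
        for ref in el.findall(f"{_SBML}listOfProducts/{_SBML}speciesReference"):
            sp = ref.get("species")
            if sp not in declared:
                raise SBMLError(
                    f"reaction {rid!r} references undeclared species {sp!r}")
            stoich[sp] = stoich.get(sp, 0.0) + float(ref.get("stoichiometry", "1"))
        for ref in el.findall(f"{_SBML}listOfModifiers/"
                              f"{_SBML}modifierSpeciesReference"):
            sp = ref.get("species")
            if sp not in declared:
                raise SBMLError(
                    f"reaction {rid!r} references undeclared species {sp!r}")
        math = el.find(f"{_SBML}kineticLaw/{_MML}math")
        if math is None:
            raise SBMLError(f"reaction {rid!r} has no kinetic law")
        expr = _mathml_to_expr(math)
        used = {str(s) for s in expr.free_symbols}
        missing = used - declared
        if missing:
            raise SBMLError(
                f"reaction {rid!r} kinetic law references undeclared "
                f"identifiers: {sorted(missing)}")
        doc.reactions.append({
            "id": rid,
            "name": el.get("name", rid),
            "rate": str(expr),
            "stoichiometry": stoich,
        })

    handled = {"listOfCompartments", "listOfSpecies", "listOfParameters",
               "listOfReactions", "annotation", "notes"}
    for child in mod:
        if not isinstance(child.tag, str):
            continue
        tag = etree.QName(child).localname
        if tag not in handled:
            doc.warnings.append(f"unsupported SBML construct ignored: <{tag}>")

    return doc


def import_sbml_model(source: str | Path) -> Model:
    """Import SBML and rebuild a full Model (our own exports only)."""
    return model_from_document(import_sbml(source))


# ---------------------------------------------------------------------------
# Validation and evaluation helpers
# ---------------------------------------------------------------------------


def validate_sbml(document: str) -> list[str]:
    """Structural validation; returns a list of problems (empty = valid)."""
    issues: list[str] = []
    try:
        root = _parse(document)
    except SBMLError as exc:
        return [str(exc)]
    if etree.QName(root).namespace != SBML_NS:
        issues.append("root element not in the SBML Level 3 core namespace")
        return issues
    if root.get("level") != "3":
        issues.append("missing or wrong 'level' attribute")
    mod = root.find(_SBML + "model")
    if mod is None:
        return issues + ["no <model> element"]
    ids: list[str] = []
    for path in ("listOfCompartments/compartment", "listOfSpecies/species",
                 "listOfParameters/parameter", "listOfReactions/reaction"):
        parent, child = path.split("/")
        for el in mod.findall(f"{_SBML}{parent}/{_SBML}{child}"):
            if el.get("id") is None:
                issues.append(f"<{child}> without id")
            else:
                ids.append(el.get("id"))
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            issues.append(f"duplicate id {i!r}")
        seen.add(i)
    comp_ids = {el.get("id") for el in
                mod.findall(f"{_SBML}listOfCompartments/{_SBML}compartment")}
    for el in mod.findall(f"{_SBML}listOfSpecies/{_SBML}species"):
        if el.get("compartment") not in comp_ids:
            issues.append(
                f"species {el.get('id')!r} in undeclared compartment")
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if el.get(attr) not in ("true", "false"):
                issues.append(f"species {el.get('id')!r} missing {attr}")
    for el in mod.findall(f"{_SBML}listOfReactions/{_SBML}reaction"):
        if el.find(f"{_SBML}kineticLaw/{_MML}math") is None:
            issues.append(f"reaction {el.get('id')!r} lacks a kinetic law")
    try:
        import_sbml(document)
    except SBMLError as exc:
        issues.append(str(exc))
    return issues


def document_rhs_evaluator(doc: ModelDocument) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Compile a document's reactions into a derivative evaluator.

    Returns a function mapping {identifier: value} (species and boundary
    values; parameters are baked in) to {species: d/dt}.  Used to check that
    an exported-and-reimported model reproduces the native right-hand side.
    """
    param_vals = {p["id"]: float(p["value"]) for p in doc.parameters}
    dynamic = [s["id"] for s in doc.species if s["role"] != "boundary"]
    compiled = []
    for r in doc.reactions:
        expr = sympy.sympify(r["rate"]).subs(
            {sympy.Symbol(k): v for k, v in param_vals.items()})
        syms = sorted(expr.free_symbols, key=lambda s: s.name)
        fn = sympy.lambdify(syms, expr, "math")
        compiled.append((fn, [s.name for s in syms], r["stoichiometry"]))
    def rhs(values: Mapping[str, float]) -> dict[str, float]:
        dy = {sp: 0.0 for sp in dynamic}
        for fn, names, stoich in compiled:
            rate = fn(*(values[n] for n in names))
            for sp, coef in stoich.items():
                if sp in dy:
                    dy[sp] += coef * rate
        return dy

    return rhs
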