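"""SBML Level 3 qualitative-models (qual) import/export, Boolean dialect.

The dialect written here is the one exported by common logical-modeling
tools for Boolean networks:

* every qualitative species has ``maxLevel="1"``;
* external (environment-driven) nodes are species with no transition;
* each internal node has one transition whose function terms are MathML
  ``and``/``or``/``not`` over ``eq(species, 1)`` comparisons, with
  ``defaultTerm`` result level 0;
* constant-1 rules are encoded as a function term ``<true/>``, constant-0
  rules as a transition with only the default term.

Multi-valued species (``maxLevel > 1``) are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

from lxml import etree

from .network import EXTERNAL, INTERNAL, LogicalNetwork, NodeSpec
from .rules import And, Const, Expr, LogicRule, Not, Or, Var

__all__ = ["SbmlQualError", "read_sbml_qual", "write_sbml_qual"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"

_NSMAP = {None: SBML_NS, "qual": QUAL_NS}


class SbmlQualError(ValueError):
    """File is not a supported Boolean SBML-qual document."""


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATH_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _math_of(expr: Expr, parent: etree._Element) -> None:
    if isinstance(expr, Var):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("eq"))
        ci = etree.SubElement(apply, _m("ci"))
        ci.text = f" {expr.name} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = " 1 "
    elif isinstance(expr, Const):
        etree.SubElement(parent, _m("true" if expr.value else "false"))
    elif isinstance(expr, Not):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("not"))
        _math_of(expr.child, apply)
    elif isinstance(expr, (And, Or)):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("and" if isinstance(expr, And) else "or"))
        _math_of(expr.left, apply)
        _math_of(expr.right, apply)
    else:  # pragma: no cover - closed expression hierarchy
        raise TypeError(f"cannot serialize expression node {type(expr).__name__}")


def write_sbml_qual(network: LogicalNetwork, path) -> None:
    """Write ``network`` to ``path`` as Boolean SBML-qual."""
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(_q("required"), "true")

    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", _sanitize_id(network.name) or "model")
    if network.name:
        model.set("name", network.name)

    compartments = etree.SubElement(root.find(f"{{{SBML_NS}}}model"),
                                    f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(compartments, f"{{{SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("constant", "true")

    species_list = etree.SubElement(model, _q("listOfQualitativeSpecies"))
    for name in network.names:
        spec = network[name]
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), name)
        sp.set(_q("compartment"), "cell")
        sp.set(_q("constant"), "true" if spec.kind == EXTERNAL else "false")
        sp.set(_q("maxLevel"), "1")

    transitions = etree.SubElement(model, _q("listOfTransitions"))
    for name in network.internal_names:
        rule = network[name].rule
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{name}")
        if rule.regulators:
            inputs = etree.SubElement(tr, _q("listOfInputs"))
            for reg in rule.regulators:
                inp = etree.SubElement(inputs, _q("input"))
                inp.set(_q("qualitativeSpecies"), reg)
                inp.set(_q("transitionEffect"), "none")
        outputs = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs, _q("output"))
        out.set(_q("qualitativeSpecies"), name)
        out.set(_q("transitionEffect"), "assignmentLevel")

        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        default = etree.SubElement(terms, _q("defaultTerm"))
        default.set(_q("resultLevel"), "0")
        if not (isinstance(rule.expression, Const) and rule.expression.value == 0):
            ft = etree.SubElement(terms, _q("functionTerm"))
            ft.set(_q("resultLevel"), "1")
            math = etree.SubElement(ft, _m("math"), nsmap={None: MATH_NS})
            _math_of(rule.expression, math)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8")


def _sanitize_id(text: str) -> str:
    import re

    return re.sub(r"[^A-Za-z0-9_]", "_", text or "")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _expr_from_math(el: etree._Element) -> Expr:
    tag = etree.QName(el).localname
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        if not children:
            raise SbmlQualError("unparseable MathML: empty apply")
        op = etree.QName(children[0]).localname
        args = children[1:]
        if op == "eq":
            if len(args) != 2:
                raise SbmlQualError("unparseable MathML: eq arity")
            ci, cn = args
            if etree.QName(ci).localname != "ci" or etree.QName(cn).localname != "cn":
                raise SbmlQualError("unparseable MathML: eq operands")
            name = (ci.text or "").strip()
            level = int(float((cn.text or "").strip()))
            if level not in (0, 1):
                raise SbmlQualError("multi-valued species unsupported")
            return Var(name) if level == 1 else Not(Var(name))
        if op == "not":
            if len(args) != 1:
                raise SbmlQualError("unparseable MathML: not arity")
            return Not(_expr_from_math(args[0]))
        if op in ("and", "or"):
            if not args:
                raise SbmlQualError(f"unparseable MathML: empty {op}")
            cls = And if op == "and" else Or
            expr = _expr_from_math(args[0])
            for arg in args[1:]:
                expr = cls(expr, _expr_from_math(arg))
            return expr
        raise SbmlQualError(f"unparseable MathML: operator {op!r}")
    if tag == "ci":  # bare species reference, treated as eq(species, 1)
        return Var((el.text or "").strip())
    if tag == "true":
        return Const(1)
    if tag == "false":
        return Const(0)
    raise SbmlQualError(f"unparseable MathML: element {tag!r}")


def read_sbml_qual(path) -> LogicalNetwork:
    """Read a Boolean SBML-qual file into a :class:`LogicalNetwork`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbmlQualError(f"not an XML file: {exc}") from exc
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise SbmlQualError("no SBML level-3 model element found")

    species_list = model.find(_q("listOfQualitativeSpecies"))
    if species_list is None:
        raise SbmlQualError("no qualitative species (not an SBML-qual file?)")

    order: List[str] = []
    for sp in species_list.findall(_q("qualitativeSpecies")):
        name = sp.get(_q("id"))
        max_level = sp.get(_q("maxLevel"))
        if max_level is not None and int(max_level) > 1:
            raise SbmlQualError(
                f"multi-valued species unsupported (species {name!r} has "
                f"maxLevel {max_level})")
        order.append(name)

    rules: dict = {}
    transitions = model.find(_q("listOfTransitions"))
    if transitions is not None:
        for tr in transitions.findall(_q("transition")):
            outputs = tr.find(_q("listOfOutputs"))
            if outputs is None:
                raise SbmlQualError("transition without output")
            out_species = [o.get(_q("qualitativeSpecies"))
                           for o in outputs.findall(_q("output"))]
            if len(out_species) != 1:
                raise SbmlQualError("transition must have exactly one output")
            target = out_species[0]

            terms = tr.find(_q("listOfFunctionTerms"))
            if terms is None or terms.find(_q("defaultTerm")) is None:
                raise SbmlQualError(f"missing default term for {target!r}")
            default = terms.find(_q("defaultTerm"))
            if default.get(_q("resultLevel")) != "0":
                raise SbmlQualError(
                    f"default term of {target!r} must have result level 0 "
                    "in the Boolean dialect")

            exprs: List[Expr] = []
            for ft in terms.findall(_q("functionTerm")):
                if ft.get(_q("resultLevel")) != "1":
                    raise SbmlQualError(
                        f"function term of {target!r} with result level "
                        f"{ft.get(_q('resultLevel'))!r}: multi-valued species "
                        "unsupported")
                math = ft.find(_m("math"))
                if math is None:
                    raise SbmlQualError(f"function term of {target!r} has no math")
                body = [c for c in math if isinstance(c.tag, str)]
                if len(body) != 1:
                    raise SbmlQualError("unparseable MathML: math arity")
                exprs.append(_expr_from_math(body[0]))
            if not exprs:
                expr: Expr = Const(0)
            else:
                expr = exprs[0]
                for e in exprs[1:]:
                    expr = Or(expr, e)
            rules[target] = LogicRule(expr)

    nodes = []
    for name in order:
        if name in rules:
            nodes.append(NodeSpec(name, INTERNAL, rules[name]))
        else:
            nodes.append(NodeSpec(name, EXTERNAL))
    model_name = model.get("name") or model.get("id") or Path(str(path)).stem
    return LogicalNetwork(nodes, name=model_name)
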