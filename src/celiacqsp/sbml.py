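"""Minimal SBML Level 3 Version 2 export of the reaction network.

One species per state variable, one reaction per network process, kinetic
laws as content MathML built from each reaction's rate formula.  A matching
reader re-evaluates an exported document (species, parameters,
stoichiometry, kinetic laws) so the round trip can be verified numerically
against the native right-hand side.

The writer covers exactly the expression grammar used by the model's rate
laws: ``+ - * / **``, unary minus, names, numbers and ``max()``.
"""

from __future__ import annotations

import ast
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

from .network import SPECIES_COMPARTMENT, ReactionNetwork
from .parameters import ParameterSet

__all__ = ["export_sbml", "import_sbml", "ImportedModel", "SbmlError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SbmlError(ValueError):
    """Unsupported construct during SBML export or import."""


# ---------------------------------------------------------------------------
# infix formula -> content MathML
# ---------------------------------------------------------------------------

_OP_TAGS = {
    ast.Add: "plus",
    ast.Sub: "minus",
    ast.Mult: "times",
    ast.Div: "divide",
    ast.Pow: "power",
}


def _math_el(tag: str) -> ET.Element:
    return ET.Element(f"{{{MATHML_NS}}}{tag}")


def _node_to_mathml(node: ast.expr) -> ET.Element:
    if isinstance(node, ast.Expression):
        return _node_to_mathml(node.body)
    if isinstance(node, ast.Constant):
        cn = _math_el("cn")
        cn.text = repr(float(node.value))
        return cn
    if isinstance(node, ast.Name):
        ci = _math_el("ci")
        ci.text = node.id
        return ci
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        apply = _math_el("apply")
        apply.append(_math_el("minus"))
        apply.append(_node_to_mathml(node.operand))
        return apply
    if isinstance(node, ast.BinOp):
        tag = _OP_TAGS.get(type(node.op))
        if tag is None:
            raise SbmlError(f"unsupported operator {ast.dump(node.op)}")
        apply = _math_el("apply")
        apply.append(_math_el(tag))
        apply.append(_node_to_mathml(node.left))
        apply.append(_node_to_mathml(node.right))
        return apply
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id != "max":
            raise SbmlError("only max() calls are supported in rate laws")
        apply = _math_el("apply")
        apply.append(_math_el("max"))
        for arg in node.args:
            apply.append(_node_to_mathml(arg))
        return apply
    raise SbmlError(f"unsupported expression node {type(node).__name__}")


def formula_to_mathml(formula: str) -> ET.Element:
    """Content-MathML ``<math>`` element for an infix rate expression."""
    tree = ast.parse(formula, mode="eval")
    math = _math_el("math")
    math.append(_node_to_mathml(tree))
    return math


def _eval_mathml(el: ET.Element, env: dict[str, float]) -> float:
    tag = el.tag.split("}")[-1]
    if tag == "math":
        (child,) = list(el)
        return _eval_mathml(child, env)
    if tag == "cn":
        return float(el.text)
    if tag == "ci":
        name = el.text.strip()
        try:
            return env[name]
        except KeyError:
            raise SbmlError(f"undefined symbol {name!r} in kinetic law") from None
    if tag == "apply":
        children = list(el)
        op = children[0].tag.split("}")[-1]
        args = [_eval_mathml(c, env) for c in children[1:]]
        if op == "plus":
            return sum(args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "times":
            out = 1.0
            for a in args:
                out *= a
            return out
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "max":
            return max(args)
        raise SbmlError(f"unsupported MathML operator {op!r}")
    raise SbmlError(f"unsupported MathML element {tag!r}")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sbml(net: ReactionNetwork, params: ParameterSet | None = None) -> str:
    """Serialise a network as an SBML L3V2 document (XML string).

    Unsupported rate expressions raise :class:`SbmlError` naming the
    reaction.
    """
    if params is None:
        params = net.params
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {
        "id": f"celiac_{net.variant.value}",
        "name": f"celiac disease immune response ({net.variant.value})",
    })

    compartments = sorted({SPECIES_COMPARTMENT[s] for s in net.species})
    loc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in compartments:
        ET.SubElement(loc, f"{{{SBML_NS}}}compartment", {
            "id": comp, "size": "1", "constant": "true",
        })

    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        ET.SubElement(los, f"{{{SBML_NS}}}species", {
            "id": s,
            "compartment": SPECIES_COMPARTMENT[s],
            "initialConcentration": "0",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false",
            "constant": "false",
        })

    lop = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in params:
        ET.SubElement(lop, f"{{{SBML_NS}}}parameter", {
            "id": name, "value": repr(params[name]), "constant": "true",
        })

    lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in net.reactions:
        r_el = ET.SubElement(lor, f"{{{SBML_NS}}}reaction", {
            "id": rxn.rid, "name": rxn.name, "reversible": "false",
        })
        reactants = {s: -c for s, c in rxn.stoich.items() if c < 0}
        products = {s: c for s, c in rxn.stoich.items() if c > 0}
        if reactants:
            lo_re = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
            for s, c in reactants.items():
                ET.SubElement(lo_re, f"{{{SBML_NS}}}speciesReference", {
                    "species": s, "stoichiometry": str(c), "constant": "true",
                })
        if products:
            lo_pr = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
            for s, c in products.items():
                ET.SubElement(lo_pr, f"{{{SBML_NS}}}speciesReference", {
                    "species": s, "stoichiometry": str(c), "constant": "true",
                })
        kl = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        try:
            kl.append(formula_to_mathml(rxn.formula))
        except SbmlError as err:
            raise SbmlError(
                f"reaction {rxn.rid} has an unsupported rate expression: {err}"
            ) from err

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# import (for round-trip verification)
# ---------------------------------------------------------------------------

@dataclass
class ImportedReaction:
    rid: str
    stoich: dict[str, int]
    math: ET.Element


@dataclass
class ImportedModel:
    """Just enough of an SBML model to re-evaluate the dynamics."""

    species: tuple[str, ...]
    parameters: dict[str, float]
    reactions: list[ImportedReaction]

    @property
    def N(self) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        n = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for s, c in rxn.stoich.items():
                n[idx[s], j] = c
        return n

    def rates(self, x: np.ndarray) -> np.ndarray:
        env = dict(self.parameters)
        env.update(zip(self.species, np.asarray(x, dtype=float)))
        return np.array([_eval_mathml(r.math, env) for r in self.reactions])

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.N @ self.rates(x)


def import_sbml(document: str) -> ImportedModel:
    """Parse a document produced by :func:`export_sbml`."""
    root = ET.fromstring(document)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise SbmlError("document has no <model>")
    species = tuple(
        el.attrib["id"]
        for el in model.iter(f"{{{SBML_NS}}}species")
    )
    parameters = {
        el.attrib["id"]: float(el.attrib["value"])
        for el in model.iter(f"{{{SBML_NS}}}parameter")
    }
    reactions = []
    for r_el in model.iter(f"{{{SBML_NS}}}reaction"):
        stoich: dict[str, int] = {}
        for side, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
            lst = r_el.find(f"{{{SBML_NS}}}{side}")
            if lst is None:
                continue
            for ref in lst.findall(f"{{{SBML_NS}}}speciesReference"):
                coeff = int(float(ref.attrib.get("stoichiometry", "1")))
                sp = ref.attrib["species"]
                stoich[sp] = stoich.get(sp, 0) + sign * coeff
        kl = r_el.find(f"{{{SBML_NS}}}kineticLaw")
        math = None if kl is None else kl.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise SbmlError(f"reaction {r_el.attrib.get('id')} has no math")
        reactions.append(
            ImportedReaction(rid=r_el.attrib["id"], stoich=stoich, math=math)
        )
    return ImportedModel(species=species, parameters=parameters,
                         reactions=reactions)
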