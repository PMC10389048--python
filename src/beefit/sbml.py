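"""Minimal SBML level-2/3 import hook.

Reads species, compartments, global parameters and reaction kinetic laws
(MathML converted to an infix string) into plain dataclasses, so externally
curated kinetic models can be inspected and wired to the generic optimizer
interface. The bundled glucose subsystem does not require this hook, and
the hook deliberately does not rebuild full-model dynamics — it is an
import surface, not a general SBML simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import InvalidInputError


@dataclass(frozen=True)
class SBMLCompartment:
    id: str
    size: float | None


@dataclass(frozen=True)
class SBMLSpecies:
    id: str
    name: str | None
    compartment: str | None
    initial_concentration: float | None


@dataclass(frozen=True)
class SBMLParameter:
    id: str
    value: float | None


@dataclass(frozen=True)
class SBMLReaction:
    id: str
    reactants: tuple
    products: tuple
    kinetic_law: str | None  # infix rendering of the MathML
    local_parameters: tuple  # of SBMLParameter


@dataclass(frozen=True)
class SBMLModel:
    id: str | None
    level: int
    version: int
    compartments: tuple
    species: tuple
    parameters: tuple
    reactions: tuple


_MATHML_OPS = {
    "plus": " + ",
    "minus": " - ",
    "times": " * ",
    "divide": " / ",
    "power": " ^ ",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_infix(node) -> str:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise InvalidInputError("malformed MathML: expected one root expression")
        return _mathml_to_infix(children[0])
    if tag == "ci":
        return (node.text or "").strip()
    if tag == "cn":
        text = (node.text or "").strip()
        # scientific notation uses <sep/> between mantissa and exponent
        sep = [c for c in node if _local(c.tag) == "sep"]
        if sep:
            return f"{text}e{(sep[0].tail or '').strip()}"
        return text
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op, args = children[0], children[1:]
        op_name = _local(op.tag)
        rendered = [_mathml_to_infix(a) for a in args]
        if op_name in _MATHML_OPS:
            if op_name == "minus" and len(rendered) == 1:
                return f"(-{rendered[0]})"
            return "(" + _MATHML_OPS[op_name].join(rendered) + ")"
        return f"{op_name}({', '.join(rendered)})"
    raise InvalidInputError(f"unsupported MathML element <{tag}>")


def _float_attr(el, *names) -> float | None:
    for name in names:
        raw = el.get(name)
        if raw is not None:
            return float(raw)
    return None


def read_sbml(path) -> SBMLModel:
    """Parse an SBML file into the lightweight model description."""
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise InvalidInputError(f"{path} is not an SBML document (root <{_local(root.tag)}>)")
    level = int(root.get("level", "0"))
    version = int(root.get("version", "0"))
    model_el = next((c for c in root if _local(c.tag) == "model"), None)
    if model_el is None:
        raise InvalidInputError(f"{path} has no <model> element")

    def children_of(list_name: str, child_name: str):
        for lst in model_el.iter():
            if _local(lst.tag) == list_name and lst.getparent() is model_el:
                return [c for c in lst if _local(c.tag) == child_name]
        return []

    compartments = tuple(
        SBMLCompartment(id=c.get("id"), size=_float_attr(c, "size", "volume"))
        for c in children_of("listOfCompartments", "compartment")
    )
    species = tuple(
        SBMLSpecies(
            id=s.get("id"),
            name=s.get("name"),
            compartment=s.get("compartment"),
            initial_concentration=_float_attr(s, "initialConcentration", "initialAmount"),
        )
        for s in children_of("listOfSpecies", "species")
    )
    parameters = tuple(
        SBMLParameter(id=p.get("id"), value=_float_attr(p, "value"))
        for p in children_of("listOfParameters", "parameter")
    )

    reactions = []
    for r in children_of("listOfReactions", "reaction"):
        reactants, products, law, local_params = [], [], None, []
        for part in r:
            part_tag = _local(part.tag)
            if part_tag in ("listOfReactants", "listOfProducts"):
                refs = [c.get("species") for c in part if _local(c.tag) == "speciesReference"]
                (reactants if part_tag == "listOfReactants" else products).extend(refs)
            elif part_tag == "kineticLaw":
                for sub in part.iter():
                    sub_tag = _local(sub.tag)
                    if sub_tag == "math":
                        law = _mathml_to_infix(sub)
                    elif sub_tag in ("parameter", "localParameter"):
                        local_params.append(
                            SBMLParameter(id=sub.get("id"), value=_float_attr(sub, "value"))
                        )
        reactions.append(
            SBMLReaction(
                id=r.get("id"),
                reactants=tuple(reactants),
                products=tuple(products),
                kinetic_law=law,
                local_parameters=tuple(local_params),
            )
        )
    return SBMLModel(
        id=model_el.get("id"),
        level=level,
        version=version,
        compartments=compartments,
        species=species,
        parameters=parameters,
        reactions=tuple(reactions),
    )
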