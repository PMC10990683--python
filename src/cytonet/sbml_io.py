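"""Read and write Reactome-dialect SBML into an in-memory reaction network.

The parser is namespace-agnostic: elements are matched on their local names so
that SBML level/version drift (and the RDF annotation blocks Reactome embeds)
does not break loading.  The in-memory model is a plain bipartite structure:
species nodes on one side, reaction nodes with reactant/product/modifier
participant lists on the other.

Kinetic-law rate expressions are held as Python-syntax infix text.  On output
they are serialized as content MathML; on input the supported MathML operator
set (times, divide, plus, minus, power, ci, cn) is converted back to canonical
infix.  Anything outside that set is preserved verbatim as a ``custom`` law.
"""

from __future__ import annotations

import ast
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

SBO_PATTERN = re.compile(r"^SBO:\d{7}$")
SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

ROLE_REACTANT = "reactant"
ROLE_PRODUCT = "product"
ROLE_MODIFIER = "modifier"
PARTICIPANT_ROLES = (ROLE_REACTANT, ROLE_PRODUCT, ROLE_MODIFIER)


class SbmlError(ValueError):
    """Base class for SBML reading/writing problems."""


class SbmlParseError(SbmlError):
    """Malformed XML; the message names the offending line."""


class SbmlStructureError(SbmlError):
    """Well-formed XML that is not a usable SBML model."""


class SbmlResolutionError(SbmlError):
    """A participant references a species id absent from listOfSpecies."""


class SbmlWriteError(SbmlError):
    """The in-memory model violates an invariant needed for serialization."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class KineticLaw:
    """A rate law attached to a reaction.

    ``expression`` is Python-syntax infix over species ids and parameter
    names (e.g. ``"k_f * A**2 * B"``) except for ``custom`` laws, where it
    holds the raw MathML the file carried.
    """

    law_type: str  # "mass_action" | "michaelis_menten" | "custom"
    expression: str
    parameters: dict[str, float] = field(default_factory=dict)


@dataclass
class SpeciesNode:
    species_id: str
    display_name: str = ""
    compartment: str = ""
    sbo_term: str | None = None
    annotation_uris: list[str] = field(default_factory=list)
    initial_amount: float | None = None

    def __post_init__(self) -> None:
        if self.sbo_term is not None and not SBO_PATTERN.match(self.sbo_term):
            raise SbmlStructureError(
                f"species {self.species_id!r}: malformed SBO term {self.sbo_term!r}"
            )
        if self.initial_amount is not None and self.initial_amount < 0:
            raise SbmlStructureError(
                f"species {self.species_id!r}: negative initial amount"
            )


@dataclass
class ParticipantRef:
    species_id: str
    stoichiometry: float = 1.0
    role: str = ROLE_REACTANT

    def __post_init__(self) -> None:
        if self.role not in PARTICIPANT_ROLES:
            raise SbmlStructureError(f"unknown participant role {self.role!r}")
        if self.role == ROLE_MODIFIER:
            self.stoichiometry = 1.0  # modifiers carry no stoichiometry semantics
        elif self.stoichiometry <= 0:
            raise SbmlStructureError(
                f"participant {self.species_id!r}: non-positive stoichiometry"
            )


@dataclass
class ReactionNode:
    reaction_id: str
    display_name: str = ""
    reactants: list[ParticipantRef] = field(default_factory=list)
    products: list[ParticipantRef] = field(default_factory=list)
    modifiers: list[ParticipantRef] = field(default_factory=list)
    reversible: bool = False
    kinetic_law: KineticLaw | None = None

    def participants(self) -> list[ParticipantRef]:
        return [*self.reactants, *self.products, *self.modifiers]


@dataclass
class PathwayModel:
    model_id: str
    model_name: str = ""
    species: dict[str, SpeciesNode] = field(default_factory=dict)
    reactions: list[ReactionNode] = field(default_factory=list)
    compartments: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check participant closure and id uniqueness; raise on violation."""
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.reaction_id in seen:
                raise SbmlStructureError(f"duplicate reaction id {rxn.reaction_id!r}")
            seen.add(rxn.reaction_id)
            if not rxn.participants():
                raise SbmlStructureError(
                    f"reaction {rxn.reaction_id!r} has no participants"
                )
            for ref in rxn.participants():
                if ref.species_id not in self.species:
                    raise SbmlResolutionError(
                        f"reaction {rxn.reaction_id!r} references unknown species "
                        f"{ref.species_id!r}"
                    )


# ---------------------------------------------------------------------------
# Infix <-> content MathML
# ---------------------------------------------------------------------------

_MATHML_OPS = {"times": "*", "divide": "/", "plus": "+", "minus": "-", "power": "**"}
# precedence used by the canonical printer: higher binds tighter
_PRECEDENCE = {"+": 1, "-": 1, "*": 2, "/": 2, "**": 3}


def _ast_to_mathml(node: ast.AST) -> ET.Element:
    if isinstance(node, ast.Expression):
        return _ast_to_mathml(node.body)
    if isinstance(node, ast.Name):
        ci = ET.Element(f"{{{MATHML_NS}}}ci")
        ci.text = f" {node.id} "
        return ci
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        cn = ET.Element(f"{{{MATHML_NS}}}cn")
        cn.text = f" {node.value} "
        return cn
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        apply = ET.Element(f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply, f"{{{MATHML_NS}}}minus")
        apply.append(_ast_to_mathml(node.operand))
        return apply
    if isinstance(node, ast.BinOp):
        op_name = {
            ast.Mult: "times", ast.Div: "divide", ast.Add: "plus",
            ast.Sub: "minus", ast.Pow: "power",
        }.get(type(node.op))
        if op_name is not None:
            apply = ET.Element(f"{{{MATHML_NS}}}apply")
            ET.SubElement(apply, f"{{{MATHML_NS}}}{op_name}")
            apply.append(_ast_to_mathml(node.left))
            apply.append(_ast_to_mathml(node.right))
            return apply
    raise SbmlWriteError(f"unsupported construct in rate expression: {ast.dump(node)}")


def expression_to_mathml(expression: str) -> ET.Element:
    """Render a Python-syntax rate expression as a content-MathML <math> tree."""
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise SbmlWriteError(f"cannot parse rate expression {expression!r}: {exc}")
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_ast_to_mathml(tree))
    return math


def _mathml_to_infix(elem: ET.Element) -> tuple[str, int]:
    """Return (text, precedence) for a MathML node; raises KeyError on foreign ops."""
    tag = _local(elem.tag)
    if tag == "ci":
        return (elem.text or "").strip(), 9
    if tag == "cn":
        text = (elem.text or "").strip()
        try:
            value = int(text)
        except ValueError:
            value = float(text)
        return repr(value), 9
    if tag == "apply":
        children = list(elem)
        op = _MATHML_OPS[_local(children[0].tag)]  # KeyError -> custom law
        args = children[1:]
        if op == "-" and len(args) == 1:
            text, prec = _mathml_to_infix(args[0])
            return f"-{text if prec >= 2 else f'({text})'}", 2
        prec = _PRECEDENCE[op]
        parts: list[str] = []
        for i, arg in enumerate(args):
            text, child_prec = _mathml_to_infix(arg)
            # left-assoc chain: first operand tolerates equal precedence,
            # later operands need strictly higher (power is right-assoc, treat
            # symmetrically strict on the left instead)
            if op == "**":
                needs = child_prec < prec if i > 0 else child_prec <= prec
            else:
                needs = child_prec < prec if i == 0 else child_prec <= prec
            parts.append(f"({text})" if needs else text)
        return f" {op} ".join(parts) if op != "**" else "**".join(parts), prec
    raise KeyError(tag)


def mathml_to_expression(math: ET.Element) -> str | None:
    """Convert a <math> element to canonical infix, or None if unsupported."""
    children = list(math)
    if len(children) != 1:
        return None
    try:
        text, _ = _mathml_to_infix(children[0])
    except (KeyError, IndexError, ValueError):
        return None
    return text


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_child(elem: ET.Element, name: str) -> ET.Element | None:
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _iter_named(elem: ET.Element, name: str):
    for child in elem:
        if _local(child.tag) == name:
            yield child


def _harvest_annotation_uris(species_elem: ET.Element) -> list[str]:
    """Collect rdf resource URIs from a species annotation block, in order."""
    annotation = _find_child(species_elem, "annotation")
    if annotation is None:
        return []
    uris: list[str] = []
    for node in annotation.iter():
        for attr_name, value in node.attrib.items():
            if _local(attr_name) == "resource":
                uris.append(value)
    return uris


def _parse_kinetic_law(law_elem: ET.Element) -> KineticLaw:
    parameters: dict[str, float] = {}
    for list_name in ("listOfLocalParameters", "listOfParameters"):
        plist = _find_child(law_elem, list_name)
        if plist is None:
            continue
        for param in plist:
            pid = param.get("id")
            if pid is not None:
                parameters[pid] = float(param.get("value", "0"))
    math = _find_child(law_elem, "math")
    law_type = law_elem.get("{%s}lawType" % SBML_NS) or law_elem.get("lawType")
    if math is None:
        return KineticLaw(law_type or "custom", "", parameters)
    expression = mathml_to_expression(math)
    if expression is None:
        raw = ET.tostring(math, encoding="unicode")
        return KineticLaw("custom", raw, parameters)
    return KineticLaw(law_type or "custom", expression, parameters)


def _parse_participants(rxn_elem: ET.Element) -> tuple[list, list, list]:
    groups = {
        "listOfReactants": (ROLE_REACTANT, []),
        "listOfProducts": (ROLE_PRODUCT, []),
        "listOfModifiers": (ROLE_MODIFIER, []),
    }
    for list_name, (role, refs) in groups.items():
        container = _find_child(rxn_elem, list_name)
        if container is None:
            continue
        for ref_elem in container:
            sid = ref_elem.get("species")
            if sid is None:
                continue
            stoich = float(ref_elem.get("stoichiometry", "1"))
            refs.append(ParticipantRef(sid, stoich, role))
    return (
        groups["listOfReactants"][1],
        groups["listOfProducts"][1],
        groups["listOfModifiers"][1],
    )


def parse_sbml(xml_text: str) -> PathwayModel:
    """Parse SBML text into a :class:`PathwayModel`.

    Raises :class:`SbmlParseError` for malformed XML (naming the line),
    :class:`SbmlStructureError` when listOfSpecies/listOfReactions are missing
    or empty, and :class:`SbmlResolutionError` for dangling species references.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, column = exc.position
        raise SbmlParseError(
            f"malformed XML at line {line}, column {column}: {exc}"
        ) from exc

    model_elem = root if _local(root.tag) == "model" else None
    if model_elem is None:
        for node in root.iter():
            if _local(node.tag) == "model":
                model_elem = node
                break
    if model_elem is None:
        raise SbmlStructureError("no <model> element found in document")

    for block in ("annotation", "notes"):
        if _find_child(model_elem, block) is not None:
            logger.warning(
                "model-level <%s> block dropped; network structure unaffected",
                block,
            )

    model = PathwayModel(
        model_id=model_elem.get("id", ""),
        model_name=model_elem.get("name", ""),
    )

    compartments = _find_child(model_elem, "listOfCompartments")
    if compartments is not None:
        model.compartments = [c.get("id", "") for c in compartments if c.get("id")]

    species_list = _find_child(model_elem, "listOfSpecies")
    if species_list is None or len(species_list) == 0:
        raise SbmlStructureError("missing or empty listOfSpecies")
    for sp_elem in species_list:
        sid = sp_elem.get("id")
        if sid is None:
            continue
        if sid in model.species:
            raise SbmlStructureError(f"duplicate species id {sid!r}")
        amount_attr = sp_elem.get("initialConcentration") or sp_elem.get("initialAmount")
        model.species[sid] = SpeciesNode(
            species_id=sid,
            display_name=sp_elem.get("name", ""),
            compartment=sp_elem.get("compartment", ""),
            sbo_term=sp_elem.get("sboTerm"),
            annotation_uris=_harvest_annotation_uris(sp_elem),
            initial_amount=float(amount_attr) if amount_attr is not None else None,
        )

    reaction_list = _find_child(model_elem, "listOfReactions")
    if reaction_list is None or len(reaction_list) == 0:
        raise SbmlStructureError("missing or empty listOfReactions")
    for rxn_elem in reaction_list:
        rid = rxn_elem.get("id")
        if rid is None:
            continue
        reactants, products, modifiers = _parse_participants(rxn_elem)
        law_elem = _find_child(rxn_elem, "kineticLaw")
        model.reactions.append(ReactionNode(
            reaction_id=rid,
            display_name=rxn_elem.get("name", ""),
            reactants=reactants,
            products=products,
            modifiers=modifiers,
            reversible=rxn_elem.get("reversible", "false").lower() == "true",
            kinetic_law=_parse_kinetic_law(law_elem) if law_elem is not None else None,
        ))

    model.validate()
    return model


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _species_to_element(sp: SpeciesNode) -> ET.Element:
    elem = ET.Element(f"{{{SBML_NS}}}species", {
        "id": sp.species_id,
        "constant": "false",
        "hasOnlySubstanceUnits": "false",
        "boundaryCondition": "false",
    })
    if sp.display_name:
        elem.set("name", sp.display_name)
    if sp.compartment:
        elem.set("compartment", sp.compartment)
    if sp.sbo_term:
        elem.set("sboTerm", sp.sbo_term)
    if sp.initial_amount is not None:
        elem.set("initialConcentration", repr(sp.initial_amount))
    if sp.annotation_uris:
        annotation = ET.SubElement(elem, f"{{{SBML_NS}}}annotation")
        rdf = ET.SubElement(annotation, f"{{{RDF_NS}}}RDF")
        desc = ET.SubElement(rdf, f"{{{RDF_NS}}}Description")
        bag = ET.SubElement(desc, f"{{{RDF_NS}}}Bag")
        for uri in sp.annotation_uris:
            ET.SubElement(bag, f"{{{RDF_NS}}}li", {f"{{{RDF_NS}}}resource": uri})
    return elem


def _law_to_element(law: KineticLaw) -> ET.Element:
    elem = ET.Element(f"{{{SBML_NS}}}kineticLaw")
    if law.law_type and law.law_type != "custom":
        elem.set("lawType", law.law_type)
    if law.law_type == "custom" and law.expression.lstrip().startswith("<"):
        try:
            elem.append(ET.fromstring(law.expression))
        except ET.ParseError as exc:
            raise SbmlWriteError(f"custom law carries invalid MathML: {exc}")
    elif law.expression:
        elem.append(expression_to_mathml(law.expression))
    if law.parameters:
        plist = ET.SubElement(elem, f"{{{SBML_NS}}}listOfLocalParameters")
        for name, value in law.parameters.items():
            ET.SubElement(plist, f"{{{SBML_NS}}}localParameter", {
                "id": name, "value": repr(value),
            })
    return elem


def write_sbml(model: PathwayModel) -> str:
    """Serialize a model to SBML Level 3 text; ``parse_sbml`` inverts it."""
    if not model.species:
        raise SbmlWriteError("model has no species; refusing to serialize")
    if not model.reactions:
        raise SbmlWriteError("model has no reactions; refusing to serialize")
    model.validate()

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("rdf", RDF_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model_elem = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": model.model_id})
    if model.model_name:
        model_elem.set("name", model.model_name)

    if model.compartments:
        clist = ET.SubElement(model_elem, f"{{{SBML_NS}}}listOfCompartments")
        for cid in model.compartments:
            ET.SubElement(clist, f"{{{SBML_NS}}}compartment", {
                "id": cid, "constant": "true",
            })

    slist = ET.SubElement(model_elem, f"{{{SBML_NS}}}listOfSpecies")
    for sp in model.species.values():
        slist.append(_species_to_element(sp))

    rlist = ET.SubElement(model_elem, f"{{{SBML_NS}}}listOfReactions")
    ref_tags = {
        ROLE_REACTANT: ("listOfReactants", "speciesReference"),
        ROLE_PRODUCT: ("listOfProducts", "speciesReference"),
        ROLE_MODIFIER: ("listOfModifiers", "modifierSpeciesReference"),
    }
    for rxn in model.reactions:
        rxn_elem = ET.SubElement(rlist, f"{{{SBML_NS}}}reaction", {
            "id": rxn.reaction_id,
            "reversible": "true" if rxn.reversible else "false",
            "fast": "false",
        })
        if rxn.display_name:
            rxn_elem.set("name", rxn.display_name)
        for role, refs in (
            (ROLE_REACTANT, rxn.reactants),
            (ROLE_PRODUCT, rxn.products),
            (ROLE_MODIFIER, rxn.modifiers),
        ):
            if not refs:
                continue
            list_name, ref_name = ref_tags[role]
            container = ET.SubElement(rxn_elem, f"{{{SBML_NS}}}{list_name}")
            for ref in refs:
                attrs = {"species": ref.species_id}
                if role != ROLE_MODIFIER:
                    attrs["stoichiometry"] = repr(ref.stoichiometry)
                    attrs["constant"] = "true"
                ET.SubElement(container, f"{{{SBML_NS}}}{ref_name}", attrs)
        if rxn.kinetic_law is not None:
            rxn_elem.append(_law_to_element(rxn.kinetic_law))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
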