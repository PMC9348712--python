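"""Import of externally-built ODE models from SBML (Level 2/3).

Users with a full QSP model exported as SBML can plug it in as the
whole-patient part of the hybrid simulator instead of the built-in reduced
model.  This module implements a deliberately small, self-contained reader
for the ODE core of SBML: compartments, species, global parameters,
reactions with mass-balance stoichiometry and MathML kinetic laws, and rate
rules.  Events, function definitions, algebraic rules, units and delays are
out of scope and raise.

The imported model satisfies the same right-hand-side contract as the
built-in model: ``SBMLModel.rhs(t, y)`` returns dy/dt over the species
vector, and a user-supplied name map ties SBML species identifiers to the
five tumor species the agent-based model couples to.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

#: tumor-coupled species the hybrid simulator understands
COUPLED_SPECIES = ("C", "T1", "Texh", "T0", "MDSC")


class SBMLParseError(ValueError):
    """Raised when a file is not valid (supported) SBML; no partial model
    is ever returned."""


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_MATHML_NS = "{http://www.w3.org/1998/Math/MathML}"

_BINARY = {"divide": "/", "power": "**"}
_NARY = {"plus": "+", "times": "*", "minus": "-"}
_FUNCS = {"exp": "exp", "ln": "log", "abs": "abs", "floor": "floor",
          "ceiling": "ceil", "root": "sqrt", "sin": "sin", "cos": "cos",
          "tan": "tan"}
_CONSTANTS = {"pi": "pi", "exponentiale": "e", "true": "True", "false": "False"}

_SAFE_ENV = {
    "exp": math.exp, "log": math.log, "log10": math.log10, "sqrt": math.sqrt,
    "abs": abs, "floor": math.floor, "ceil": math.ceil, "pi": math.pi,
    "e": math.e, "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "min": min, "max": max, "pow": pow,
}


def _math_to_expr(node: ET.Element, known: set[str]) -> str:
    """Translate a content-MathML node to a Python expression string."""
    tag = _strip(node.tag)
    if tag == "math":
        kids = list(node)
        if len(kids) != 1:
            raise SBMLParseError("<math> must contain exactly one expression")
        return _math_to_expr(kids[0], known)
    if tag == "cn":
        sub = list(node)
        if sub:  # e-notation: <cn type="e-notation">1<sep/>-3</cn>
            mant = (node.text or "").strip()
            exp10 = (sub[0].tail or "").strip()
            return f"({mant}e{exp10})"
        return f"({(node.text or '').strip()})"
    if tag == "ci":
        name = (node.text or "").strip()
        if name not in known:
            raise SBMLParseError(f"unknown identifier '{name}' in kinetic math")
        return f"_v['{name}']"
    if tag == "csymbol":
        if "time" in (node.get("definitionURL") or ""):
            return "_t"
        raise SBMLParseError("unsupported csymbol")
    if tag in _CONSTANTS:
        return _CONSTANTS[tag]
    if tag == "apply":
        kids = list(node)
        op = _strip(kids[0].tag)
        args = [_math_to_expr(k, known) for k in kids[1:]]
        if op in _NARY:
            if op == "minus" and len(args) == 1:
                return f"(-{args[0]})"
            return "(" + f" {_NARY[op]} ".join(args) + ")"
        if op in _BINARY:
            if len(args) != 2:
                raise SBMLParseError(f"operator {op} needs two operands")
            return f"({args[0]} {_BINARY[op]} {args[1]})"
        if op in _FUNCS:
            if len(args) != 1:
                raise SBMLParseError(f"function {op} needs one operand")
            return f"{_FUNCS[op]}({args[0]})"
        raise SBMLParseError(f"unsupported MathML operator '{op}'")
    raise SBMLParseError(f"unsupported MathML element '{tag}'")


@dataclass
class _Reaction:
    expr: str
    stoich: dict[str, float]  # species id -> net stoichiometry


@dataclass
class SBMLModel:
    """An ODE model imported from SBML.

    ``species`` orders the state vector; ``rhs(t, y)`` is the vector field;
    ``name_map`` ties coupled-species names ("C", "T1", ...) to SBML ids.
    """

    species: list[str]
    initial: np.ndarray
    name_map: dict[str, str] = field(default_factory=dict)
    _reactions: list[_Reaction] = field(default_factory=list)
    _rate_rules: dict[str, str] = field(default_factory=dict)
    _constants: dict[str, float] = field(default_factory=dict)
    _boundary: set[str] = field(default_factory=set)

    def initial_state(self) -> np.ndarray:
        return self.initial.copy()

    def index_of(self, coupled_name: str) -> int:
        sid = self.name_map[coupled_name]
        return self.species.index(sid)

    def validate_coupling(self) -> None:
        missing = [n for n in COUPLED_SPECIES if n not in self.name_map]
        if missing:
            raise ValueError(
                f"SBML coupling refused: name map lacks {missing}; every "
                f"coupled tumor species {COUPLED_SPECIES} must be mapped")
        for n, sid in self.name_map.items():
            if sid not in self.species:
                raise ValueError(f"mapped species '{sid}' (for {n}) not in model")

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        env = dict(self._constants)
        env.update(zip(self.species, y))
        scope = {"_v": env, "_t": t, **_SAFE_ENV}
        dy = np.zeros(len(self.species))
        for rxn in self._reactions:
            rate = eval(rxn.expr, {"__builtins__": {}}, scope)  # noqa: S307
            for sid, nu in rxn.stoich.items():
                dy[self.species.index(sid)] += nu * rate
        for sid, expr in self._rate_rules.items():
            dy[self.species.index(sid)] = eval(expr, {"__builtins__": {}}, scope)  # noqa: S307
        for sid in self._boundary:
            dy[self.species.index(sid)] = 0.0
        return dy


def load_sbml_model(path: str, name_map: dict[str, str] | None = None) -> SBMLModel:
    """Parse an SBML Level 2/3 file into an :class:`SBMLModel`.

    ``name_map`` maps the coupled tumor species names to SBML species ids;
    it may be omitted or partial, but the coupling layer will refuse to
    start until :meth:`SBMLModel.validate_coupling` passes.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SBMLParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if _strip(root.tag) != "sbml":
        raise SBMLParseError("root element is not <sbml>")
    level = root.get("level")
    if level not in ("2", "3"):
        raise SBMLParseError(f"unsupported SBML level {level!r}")
    model = root.find("./{*}model")
    if model is None:
        raise SBMLParseError("no <model> element")
    for unsupported in ("listOfEvents", "listOfFunctionDefinitions",
                        "listOfConstraints"):
        if model.find(f"./{{*}}{unsupported}") is not None:
            raise SBMLParseError(f"{unsupported} is not supported")

    constants: dict[str, float] = {}
    for comp in model.findall("./{*}listOfCompartments/{*}compartment"):
        size = comp.get("size", comp.get("volume", "1"))
        constants[comp.get("id")] = float(size)
    for par in model.findall("./{*}listOfParameters/{*}parameter"):
        constants[par.get("id")] = float(par.get("value", "0"))

    species: list[str] = []
    initial: list[float] = []
    boundary: set[str] = set()
    for sp in model.findall("./{*}listOfSpecies/{*}species"):
        sid = sp.get("id")
        if sid is None:
            raise SBMLParseError("species without id")
        amount = sp.get("initialAmount")
        conc = sp.get("initialConcentration")
        if amount is not None:
            y0 = float(amount)
        elif conc is not None:
            y0 = float(conc) * constants.get(sp.get("compartment"), 1.0)
        else:
            y0 = 0.0
        species.append(sid)
        initial.append(y0)
        if sp.get("boundaryCondition") in ("true", "1"):
            boundary.add(sid)

    known = set(species) | set(constants)

    reactions: list[_Reaction] = []
    for rxn in model.findall("./{*}listOfReactions/{*}reaction"):
        stoich: dict[str, float] = {}
        for ref in rxn.findall("./{*}listOfReactants/{*}speciesReference"):
            stoich[ref.get("species")] = (stoich.get(ref.get("species"), 0.0)
                                          - float(ref.get("stoichiometry", "1")))
        for ref in rxn.findall("./{*}listOfProducts/{*}speciesReference"):
            stoich[ref.get("species")] = (stoich.get(ref.get("species"), 0.0)
                                          + float(ref.get("stoichiometry", "1")))
        klaw = rxn.find("./{*}kineticLaw")
        if klaw is None:
            raise SBMLParseError(f"reaction {rxn.get('id')} lacks a kineticLaw")
        local = dict(constants)
        local_ids = set(known)
        for lp in klaw.findall(".//{*}listOfLocalParameters/{*}localParameter"):
            local[lp.get("id")] = float(lp.get("value", "0"))
            local_ids.add(lp.get("id"))
        for lp in klaw.findall("./{*}listOfParameters/{*}parameter"):  # L2 style
            local[lp.get("id")] = float(lp.get("value", "0"))
            local_ids.add(lp.get("id"))
        math_el = klaw.find(f"./{_MATHML_NS}math")
        if math_el is None:
            raise SBMLParseError(f"reaction {rxn.get('id')} has no MathML")
        expr = _math_to_expr(math_el, local_ids)
        # fold local parameters into the expression environment via constants:
        # locals shadow globals, so bake them in by name where they are new
        reactions.append(_Reaction(expr=expr, stoich=stoich))
        for k, v in local.items():
            constants.setdefault(k, v)

    rate_rules: dict[str, str] = {}
    for rule in model.findall("./{*}listOfRules/{*}rateRule"):
        var = rule.get("variable")
        if var not in species:
            raise SBMLParseError(f"rate rule for unknown species {var!r}")
        math_el = rule.find(f"./{_MATHML_NS}math")
        if math_el is None:
            raise SBMLParseError("rate rule without MathML")
        rate_rules[var] = _math_to_expr(math_el, known)
    if model.find("./{*}listOfRules/{*}algebraicRule") is not None:
        raise SBMLParseError("algebraic rules are not supported")

    return SBMLModel(species=species, initial=np.array(initial, dtype=float),
                     name_map=dict(name_map or {}), _reactions=reactions,
                     _rate_rules=rate_rules, _constants=constants,
                     _boundary=boundary)
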