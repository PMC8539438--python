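"""SBML exchange for the SMS network (Level 3 Version 2).

Each reversible reaction is encoded as a single SBML reaction whose kinetic
law is the explicit net mass-action expression, e.g.

    k1 * pc * e - k1r * ep * dag

with the two rate constants as global parameters.  Import reconstructs the
network and rejects documents whose kinetic laws are not recognisably of
this two-term mass-action form.

python-libsbml is used when available (including schema/consistency
checking); otherwise a self-contained XML reader/writer handles the same
L3V2 subset.
"""

from __future__ import annotations

import re

import numpy as np

from .network import (
    SPECIES,
    NetworkModel,
    RateConstants,
    ValidationError,
    build_sms_network,
)

try:  # pragma: no cover - exercised implicitly by whichever backend is present
    import libsbml

    HAVE_LIBSBML = True
except ImportError:  # pragma: no cover
    libsbml = None
    HAVE_LIBSBML = False

__all__ = ["write_sbml", "read_sbml", "parse_mass_action_sbml", "HAVE_LIBSBML"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_PARAM_NAMES = ("k1", "k1r", "k2", "k2r")
# (reaction id, reactants, products, forward param, reverse param)
_REACTIONS = (
    ("phosphorylation", ("pc", "e"), ("ep", "dag"), "k1", "k1r"),
    ("transfer", ("cer", "ep"), ("e", "sm"), "k2", "k2r"),
)


def _formula(rxn) -> str:
    rid, reactants, products, kf, kr = rxn
    return f"{kf} * {' * '.join(reactants)} - {kr} * {' * '.join(products)}"


# ---------------------------------------------------------------------------
# libsbml backend
# ---------------------------------------------------------------------------

def _write_libsbml(net: NetworkModel, path: str) -> None:
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("sms_cycle")

    comp = model.createCompartment()
    comp.setId("membrane")
    comp.setSize(1.0)
    comp.setConstant(True)
    comp.setSpatialDimensions(3)

    y0 = net.initial_state.to_array()
    for name, amount in zip(SPECIES, y0):
        sp = model.createSpecies()
        sp.setId(name)
        sp.setCompartment("membrane")
        sp.setInitialAmount(float(amount))
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for pname, value in zip(_PARAM_NAMES, net.rc.as_tuple()):
        par = model.createParameter()
        par.setId(pname)
        par.setValue(float(value))
        par.setConstant(True)

    for rxn in _REACTIONS:
        rid, reactants, products, kf, kr = rxn
        r = model.createReaction()
        r.setId(rid)
        r.setReversible(True)
        for s in reactants:
            ref = r.createReactant()
            ref.setSpecies(s)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for s in products:
            ref = r.createProduct()
            ref.setSpecies(s)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula(_formula(rxn)))

    doc.checkConsistency()
    n_errors = doc.getNumErrors()
    fatal = any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(n_errors)
    )
    if fatal:  # pragma: no cover - document construction is fixed above
        raise ValidationError(doc.getErrorLog().toString())
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


_MASS_ACTION_RE = re.compile(
    r"^\s*(?P<kf>\w+)((\s*\*\s*\w+)+)\s*-\s*(?P<kr>\w+)((\s*\*\s*\w+)+)\s*$"
)


def _parse_mass_action(formula: str, rid: str) -> tuple[str, list[str], str, list[str]]:
    """Split 'kf * A * B - kr * C * D' into constants and species factors."""
    m = _MASS_ACTION_RE.match(formula)
    if not m:
        raise ValidationError(
            f"reaction {rid!r}: kinetic law {formula!r} is not a recognisable "
            "two-term mass-action expression (expected 'kf*A*... - kr*B*...')"
        )
    fwd_terms = [t.strip() for t in formula.split("-")[0].split("*")]
    rev_terms = [t.strip() for t in formula.split("-")[1].split("*")]
    return fwd_terms[0], fwd_terms[1:], rev_terms[0], rev_terms[1:]


def _read_libsbml(path: str):
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValidationError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"{path} contains no SBML model")

    species = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        species[sp.getId()] = sp.getInitialAmount()

    params = {}
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        params[par.getId()] = par.getValue()

    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None:
            raise ValidationError(f"reaction {r.getId()!r} has no kinetic law")
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            params[lp.getId()] = lp.getValue()
        formula = libsbml.formulaToL3String(kl.getMath())
        reactions.append(
            (
                r.getId(),
                [r.getReactant(j).getSpecies() for j in range(r.getNumReactants())],
                [r.getProduct(j).getSpecies() for j in range(r.getNumProducts())],
                formula,
            )
        )
    return species, params, reactions


# ---------------------------------------------------------------------------
# plain-XML fallback backend (same L3V2 subset)
# ---------------------------------------------------------------------------

def _mathml_mass_action(rxn) -> str:
    rid, reactants, products, kf, kr = rxn

    def prod(factors):
        cis = "".join(f"<ci> {f} </ci>" for f in factors)
        return f"<apply><times/>{cis}</apply>"

    return (
        f'<math xmlns="{_MATHML_NS}"><apply><minus/>'
        f"{prod((kf, *reactants))}{prod((kr, *products))}"
        "</apply></math>"
    )


def _write_fallback(net: NetworkModel, path: str) -> None:
    y0 = net.initial_state.to_array()
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<sbml xmlns="{_SBML_NS}" level="3" version="2">',
        '  <model id="sms_cycle">',
        "    <listOfCompartments>",
        '      <compartment id="membrane" size="1" spatialDimensions="3" constant="true"/>',
        "    </listOfCompartments>",
        "    <listOfSpecies>",
    ]
    for name, amount in zip(SPECIES, y0):
        lines.append(
            f'      <species id="{name}" compartment="membrane" '
            f'initialAmount="{float(amount)!r}" hasOnlySubstanceUnits="true" '
            'boundaryCondition="false" constant="false"/>'
        )
    lines.append("    </listOfSpecies>")
    lines.append("    <listOfParameters>")
    for pname, value in zip(_PARAM_NAMES, net.rc.as_tuple()):
        lines.append(f'      <parameter id="{pname}" value="{float(value)!r}" constant="true"/>')
    lines.append("    </listOfParameters>")
    lines.append("    <listOfReactions>")
    for rxn in _REACTIONS:
        rid, reactants, products, kf, kr = rxn
        lines.append(f'      <reaction id="{rid}" reversible="true">')
        lines.append("        <listOfReactants>")
        for s in reactants:
            lines.append(f'          <speciesReference species="{s}" stoichiometry="1" constant="true"/>')
        lines.append("        </listOfReactants>")
        lines.append("        <listOfProducts>")
        for s in products:
            lines.append(f'          <speciesReference species="{s}" stoichiometry="1" constant="true"/>')
        lines.append("        </listOfProducts>")
        lines.append("        <kineticLaw>")
        lines.append("          " + _mathml_mass_action(rxn))
        lines.append("        </kineticLaw>")
        lines.append("      </reaction>")
    lines.append("    </listOfReactions>")
    lines.append("  </model>")
    lines.append("</sbml>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _mathml_to_formula(node) -> str:
    """Render the MathML subset used here (times/minus/ci/cn) as infix."""
    tag = node.tag.split("}")[-1]
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValidationError("unsupported MathML structure")
        return _mathml_to_formula(children[0])
    if tag == "ci":
        return node.text.strip()
    if tag == "cn":
        return node.text.strip()
    if tag == "apply":
        op = list(node)[0].tag.split("}")[-1]
        args = [_mathml_to_formula(ch) for ch in list(node)[1:]]
        if op == "times":
            return " * ".join(args)
        if op == "minus" and len(args) == 2:
            return f"{args[0]} - {args[1]}"
        raise ValidationError(f"unsupported MathML operator {op!r}")
    raise ValidationError(f"unsupported MathML element {tag!r}")


def _read_fallback(path: str):
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"SBML parse error: {exc}") from exc
    root = tree.getroot()
    ns = {"s": _SBML_NS, "m": _MATHML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise ValidationError(f"{path} contains no SBML model")

    species = {
        sp.get("id"): float(sp.get("initialAmount", "0"))
        for sp in model.findall("s:listOfSpecies/s:species", ns)
    }
    params = {
        p.get("id"): float(p.get("value"))
        for p in model.findall("s:listOfParameters/s:parameter", ns)
    }
    reactions = []
    for r in model.findall("s:listOfReactions/s:reaction", ns):
        for lp in r.findall(".//s:localParameter", ns):
            params[lp.get("id")] = float(lp.get("value"))
        math = r.find("s:kineticLaw/m:math", ns)
        if math is None:
            raise ValidationError(f"reaction {r.get('id')!r} has no kinetic law")
        formula = _mathml_to_formula(math)
        reactions.append(
            (
                r.get("id"),
                [x.get("species") for x in r.findall("s:listOfReactants/s:speciesReference", ns)],
                [x.get("species") for x in r.findall("s:listOfProducts/s:speciesReference", ns)],
                formula,
            )
        )
    return species, params, reactions


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def write_sbml(net: NetworkModel, path) -> None:
    """Export the network as SBML L3V2 with explicit mass-action kinetics."""
    if HAVE_LIBSBML:
        _write_libsbml(net, str(path))
    else:
        _write_fallback(net, str(path))


def parse_mass_action_sbml(path):
    """Parse any SBML document with two-term mass-action kinetic laws.

    Returns ``(species, reactions)`` where ``species`` maps id -> initial
    amount and each reaction is ``(id, reactants, products, kf, kr)``.
    Raises with a diagnostic on malformed documents or unsupported rate laws.
    """
    if HAVE_LIBSBML:
        species, params, reactions = _read_libsbml(str(path))
    else:
        species, params, reactions = _read_fallback(str(path))

    parsed = []
    for rid, reactants, products, formula in reactions:
        kf_name, fwd_species, kr_name, rev_species = _parse_mass_action(formula, rid)
        for name in (kf_name, kr_name):
            if name not in params:
                raise ValidationError(
                    f"reaction {rid!r}: rate constant {name!r} not defined as a parameter"
                )
        if sorted(fwd_species) != sorted(reactants) or sorted(rev_species) != sorted(products):
            raise ValidationError(
                f"reaction {rid!r}: kinetic-law species do not match the "
                "declared reactants/products (not simple mass action)"
            )
        parsed.append((rid, tuple(reactants), tuple(products),
                       params[kf_name], params[kr_name]))
    return species, parsed


def read_sbml(path) -> NetworkModel:
    """Reconstruct the SMS NetworkModel from an SBML file.

    Requires the six-species SMS topology (two reversible reactions whose
    kinetic laws are two-term mass action); use
    :func:`parse_mass_action_sbml` for other mass-action documents.
    """
    species, parsed = parse_mass_action_sbml(path)

    missing = set(SPECIES) - set(species)
    if missing:
        raise ValidationError(
            f"not an SMS network document: missing species {sorted(missing)}"
        )
    if len(parsed) != 2:
        raise ValidationError(
            f"expected the 2-reaction SMS topology, found {len(parsed)} reactions"
        )

    by_pair = {frozenset(r[1]): r for r in parsed}
    try:
        r1 = by_pair[frozenset(("pc", "e"))]
        r2 = by_pair[frozenset(("cer", "ep"))]
    except KeyError:
        raise ValidationError("reactions do not match the SMS ping-pong topology")
    rc = RateConstants(k1=r1[3], k1r=r1[4], k2=r2[3], k2r=r2[4])

    enzyme_total = species["e"] + species["ep"]
    net = build_sms_network(
        rc,
        (species["pc"], species["cer"], species["dag"], species["sm"]),
        enzyme_total=enzyme_total if enzyme_total > 0 else 0.0,
    )
    # preserve an imported phosphoenzyme split if the document has one
    if species["ep"] != 0:
        y0 = net.initial_state.to_array()
        y0[SPECIES.index("e")] = species["e"]
        y0[SPECIES.index("ep")] = species["ep"]
        from .network import SpeciesState

        net.initial_state = SpeciesState.from_array(y0)
        net.conserved_moieties[3] = (
            ("pc", "sm", "ep"),
            species["pc"] + species["sm"] + species["ep"],
        )
    return net
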