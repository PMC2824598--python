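"""SBML Level 3 export/import of the reaction network.

The document carries one compartment, one species per model species,
one global parameter per rate symbol and one reaction per table row
with an explicit mass-action kinetic law (MathML product of the rate
constant and the reactant concentrations).  Import reconstructs the
network and parameter values from such a document; the pair round-trips
(identical stoichiometry and identical derivatives).

Written against the SBML L3 core schema directly (elements produced
here are the subset any SBML-aware tool reads); the delayed-feedback
model variant is not representable and is refused.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from lxml import etree

from .network import MassActionSystem, Reaction, ReactionNetwork, Species, build_network
from .parameters import ALL_SYMBOLS, ParameterSet

__all__ = ["export_sbml", "import_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def export_sbml(
    network: ReactionNetwork,
    params: ParameterSet,
    model_id: str = "p53_mdm2_mdmx",
    initial_state: np.ndarray | None = None,
) -> str:
    """Serialise the network and rate constants to SBML L3 text."""
    if any(rx.delay > 0 for rx in network.reactions):
        raise ValueError(
            "the delayed Mdm2-production variant cannot be represented in "
            "core SBML; export the undelayed network instead")
    missing = [rx.rate_symbol for rx in network.reactions
               if params[rx.rate_symbol] is None]
    if missing:
        raise ValueError(f"incomplete parameter set: missing {missing}")

    if initial_state is None:
        initial_state = np.zeros(network.n_species)
        initial_state[network.species_position(13)] = params.promoter_total

    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS},
                         level="3", version="1")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model", id=model_id,
                             name=f"p53-Mdm2-MdmX ({network.variant} variant)")

    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell",
                     spatialDimensions="3", size="1", constant="true")

    sps = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        etree.SubElement(
            sps, f"{{{SBML_NS}}}species", id=f"x{sp.index}", name=sp.name,
            compartment="cell",
            initialConcentration=repr(float(initial_state[network.species_position(sp.index)])),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")

    pars = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    used = sorted({rx.rate_symbol for rx in network.reactions},
                  key=lambda s: int(s[1:]))
    for sym in used:
        etree.SubElement(pars, f"{{{SBML_NS}}}parameter", id=sym,
                         value=repr(float(params[sym])), constant="true")

    rxs = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rx in network.reactions:
        el = etree.SubElement(rxs, f"{{{SBML_NS}}}reaction", id=f"r{rx.id}",
                              reversible="false", fast="false")
        for tag, members in (("listOfReactants", rx.reactants),
                             ("listOfProducts", rx.products)):
            if not members:
                continue
            lst = etree.SubElement(el, f"{{{SBML_NS}}}{tag}")
            for idx, count in sorted(Counter(members).items()):
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                                 species=f"x{idx}", stoichiometry=str(count),
                                 constant="true")
        law = etree.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(law, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        factors = [rx.rate_symbol] + [f"x{i}" for i in rx.reactants]
        if len(factors) == 1:
            ci = etree.SubElement(math, f"{{{MATHML_NS}}}ci")
            ci.text = f" {factors[0]} "
        else:
            apply = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(apply, f"{{{MATHML_NS}}}times")
            for f in factors:
                ci = etree.SubElement(apply, f"{{{MATHML_NS}}}ci")
                ci.text = f" {f} "

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def import_sbml(document: str) -> tuple[ReactionNetwork, dict[str, float], np.ndarray]:
    """Rebuild (network, rate constants, initial state) from SBML text.

    Returns the network, a symbol -> value mapping covering k1-k38
    (symbols absent from the document are 0) and the initial
    concentrations in species order.
    """
    root = etree.fromstring(document.encode())
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise ValueError("not an SBML document: no model element")

    species = []
    init = []
    for el in model.findall("s:listOfSpecies/s:species", ns):
        idx = int(el.get("id")[1:])
        species.append(idx)
        init.append(float(el.get("initialConcentration", "0")))
    variant = "full" if 15 in species or 16 in species else "simple"

    values = {s: 0.0 for s in ALL_SYMBOLS}
    for el in model.findall("s:listOfParameters/s:parameter", ns):
        values[el.get("id")] = float(el.get("value"))

    reactions = []
    for el in model.findall("s:listOfReactions/s:reaction", ns):
        rid = int(el.get("id")[1:])
        def members(tag):
            out = []
            for ref in el.findall(f"s:{tag}/s:speciesReference", ns):
                idx = int(ref.get("species")[1:])
                out.extend([idx] * int(float(ref.get("stoichiometry", "1"))))
            return tuple(out)
        cis = el.findall("s:kineticLaw//m:ci", {**ns, "m": MATHML_NS})
        symbols = [c.text.strip() for c in cis if c.text.strip().startswith("k")]
        if len(symbols) != 1:
            raise ValueError(f"reaction r{rid}: expected exactly one rate symbol")
        reactions.append(Reaction(rid, members("listOfReactants"),
                                  members("listOfProducts"), symbols[0]))

    ref = build_network(variant)
    by_index = {sp.index: sp for sp in ref.species}
    sp_objs = tuple(by_index[i] for i in species)
    pos = {i: p for p, i in enumerate(species)}
    S = np.zeros((len(species), len(reactions)), dtype=int)
    for j, rx in enumerate(reactions):
        for i in rx.reactants:
            S[pos[i], j] -= 1
        for i in rx.products:
            S[pos[i], j] += 1
    net = ReactionNetwork(variant, sp_objs, tuple(reactions), S)
    return net, values, np.asarray(init)
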