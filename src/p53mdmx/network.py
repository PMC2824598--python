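"""Reaction network of the p53-Mdm2-MdmX DNA-damage response model.

The model couples the p53-Mdm2 negative feedback loop with the
non-enzymatic p53:MdmX and Mdm2:MdmX heterodimer interactions.  Two
variants are supported:

* ``simple`` -- 14 species (x1-x14).  Promoter-bound p53 tetramers
  (x14) produce Mdm2 directly (reaction 33); no mRNA species and no
  basal p53 transcription activity.  Time is in arbitrary units.
* ``full`` -- 16 species (x1-x16) adding Mdm2 mRNA (x15) and the
  p53-monomer:promoter complex (x16) that provides basal transcription.
  Time is in minutes.

Every reaction is elementary mass action of order <= 2; the network is
compiled to a vectorised derivative function plus an analytic Jacobian
(:class:`MassActionSystem`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "MassActionSystem",
    "build_network",
    "rhs",
]

# index, name, p53 subunits, Mdm2 units, MdmX units
_SPECIES_TABLE = [
    (1, "p53", 1, 0, 0),
    (2, "p53P", 1, 0, 0),
    (3, "Mdm2", 0, 1, 0),
    (4, "Mdm2P", 0, 1, 0),
    (5, "MdmX", 0, 0, 1),
    (6, "MdmXP", 0, 0, 1),
    (7, "p53:Mdm2", 1, 1, 0),
    (8, "Mdm2:MdmXP", 0, 1, 1),
    (9, "Mdm2:MdmX", 0, 1, 1),
    (10, "p53:MdmX", 1, 0, 1),
    (11, "p53P dimer", 2, 0, 0),
    (12, "p53P tetramer", 4, 0, 0),
    (13, "promoter", 0, 0, 0),
    (14, "tetramer:promoter", 4, 0, 0),
    (15, "mRNA", 0, 0, 0),
    (16, "p53:promoter", 1, 0, 0),
]

# id, reactants, products, rate symbol.  Rows 33 and 34 share the
# printed symbol "k33": row 33 (simple variant) is direct Mdm2
# production by the promoter-bound tetramer, row 34 (full variant) is
# mRNA production from the same complex.
_REACTION_TABLE = [
    (1, (), (1,), "k1"),
    (2, (1,), (), "k2"),
    (3, (1,), (2,), "k3"),
    (4, (2,), (1,), "k4"),
    (5, (2,), (), "k5"),
    (6, (), (3,), "k6"),
    (7, (3,), (), "k7"),
    (8, (3,), (4,), "k8"),
    (9, (4,), (3,), "k9"),
    (10, (4,), (), "k10"),
    (11, (1, 3), (7,), "k11"),
    (12, (7,), (1, 3), "k12"),
    (13, (7,), (3,), "k13"),
    (14, (7,), (1,), "k14"),
    (15, (), (5,), "k15"),
    (16, (5,), (), "k16"),
    (17, (5,), (6,), "k17"),
    (18, (6,), (5,), "k18"),
    (19, (6,), (), "k19"),
    (20, (3, 6), (8,), "k20"),
    (21, (8,), (3, 6), "k21"),
    (22, (8,), (3,), "k22"),
    (23, (3, 5), (9,), "k23"),
    (24, (9,), (3, 5), "k24"),
    (25, (1, 5), (10,), "k25"),
    (26, (10,), (1, 5), "k26"),
    (27, (2, 2), (11,), "k27"),
    (28, (11,), (2, 2), "k28"),
    (29, (11, 11), (12,), "k29"),
    (30, (12,), (11, 11), "k30"),
    (31, (12, 13), (14,), "k31"),
    (32, (14,), (12, 13), "k32"),
    (33, (14,), (3, 14), "k33"),
    (34, (14,), (14, 15), "k33"),
    (35, (15,), (), "k37"),
    (36, (15,), (3, 15), "k38"),
    (37, (1, 13), (16,), "k34"),
    (38, (16,), (1, 13), "k35"),
    (39, (16,), (15, 16), "k36"),
]

#: Default delay (time units) on reaction 33 in the delayed-feedback variant.
DEFAULT_DELAY = 50.0


@dataclass(frozen=True)
class Species:
    """One molecular species with its moiety subunit weights."""

    index: int
    name: str
    p53_subunits: int
    mdm2_units: int
    mdmx_units: int


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction (order <= 2)."""

    id: int
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate_symbol: str
    delay: float = 0.0

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ValueError(f"reaction {self.id}: mass-action order > 2")
        if self.delay < 0:
            raise ValueError(f"reaction {self.id}: negative delay")


@dataclass(frozen=True)
class ReactionNetwork:
    """Ordered reaction list plus the species x reaction stoichiometry."""

    variant: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    stoichiometry: np.ndarray = field(repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_position(self, index: int) -> int:
        """Map a species index (x1 = 1, ...) to its row in the state vector."""
        for pos, sp in enumerate(self.species):
            if sp.index == index:
                return pos
        raise KeyError(f"species x{index} not in {self.variant} network")

    def moiety_weights(self, moiety: str) -> np.ndarray:
        """Subunit-count weights for a moiety: 'p53', 'Mdm2' or 'MdmX'."""
        attr = {"p53": "p53_subunits", "mdm2": "mdm2_units", "mdmx": "mdmx_units"}
        key = moiety.lower()
        if key not in attr:
            raise KeyError(f"unknown moiety {moiety!r}")
        return np.array([getattr(sp, attr[key]) for sp in self.species], float)

    @property
    def promoter_rows(self) -> np.ndarray:
        """State positions of promoter-containing species (conserved moiety)."""
        idx = [13, 14] if self.variant == "simple" else [13, 14, 16]
        return np.array([self.species_position(i) for i in idx])


def build_network(variant: str = "simple", delay_on: bool = False) -> ReactionNetwork:
    """Build the simple (x1-x14, reactions 1-33) or full (x1-x16,
    reactions 1-32 and 34-39) network.

    ``delay_on`` puts a transcription/translation delay of
    :data:`DEFAULT_DELAY` time units on reaction 33 (the p53-driven Mdm2
    production of the simple model); it is meaningless for the full
    model, where the delay is realised by the explicit mRNA species.
    """
    if variant not in ("simple", "full"):
        raise ValueError(f"unknown variant {variant!r}; expected 'simple' or 'full'")
    if delay_on and variant != "simple":
        raise ValueError("delayed Mdm2 production is only defined for the simple variant")

    if variant == "simple":
        keep_species = range(1, 15)
        keep_rows = set(range(1, 34))
    else:
        keep_species = range(1, 17)
        keep_rows = set(range(1, 33)) | set(range(34, 40))

    species = tuple(Species(*row) for row in _SPECIES_TABLE if row[0] in keep_species)
    reactions = []
    for rid, reac, prod, sym in _REACTION_TABLE:
        if rid not in keep_rows:
            continue
        delay = DEFAULT_DELAY if (delay_on and rid == 33) else 0.0
        reactions.append(Reaction(rid, reac, prod, sym, delay))
    reactions = tuple(reactions)

    pos = {sp.index: i for i, sp in enumerate(species)}
    S = np.zeros((len(species), len(reactions)), dtype=int)
    for j, rx in enumerate(reactions):
        for i in rx.reactants:
            S[pos[i], j] -= 1
        for i in rx.products:
            S[pos[i], j] += 1
    return ReactionNetwork(variant, species, reactions, S)


class MassActionSystem:
    """Network + rate constants compiled to fast derivative/Jacobian calls.

    Rates are resolved from a :class:`~p53mdmx.parameters.ParameterSet`
    (or any mapping of symbol -> value).  Homodimerisation reactions use
    the deterministic convention flux = k * x**2.
    """

    def __init__(self, network: ReactionNetwork, params) -> None:
        self.network = network
        nr = network.n_reactions
        self._r1 = np.full(nr, -1, dtype=int)
        self._r2 = np.full(nr, -1, dtype=int)
        pos = {sp.index: i for i, sp in enumerate(network.species)}
        for j, rx in enumerate(network.reactions):
            if len(rx.reactants) >= 1:
                self._r1[j] = pos[rx.reactants[0]]
            if len(rx.reactants) == 2:
                self._r2[j] = pos[rx.reactants[1]]
        self._S = network.stoichiometry.astype(float)
        self.k = np.array([float(params[rx.rate_symbol]) for rx in network.reactions])

    def set_rate(self, symbol: str, value: float) -> None:
        for j, rx in enumerate(self.network.reactions):
            if rx.rate_symbol == symbol:
                self.k[j] = value

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        f = self.k.copy()
        has1 = self._r1 >= 0
        f[has1] *= x[self._r1[has1]]
        has2 = self._r2 >= 0
        f[has2] *= x[self._r2[has2]]
        return f

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self._S @ self.fluxes(np.asarray(x, float))

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        nr = self.network.n_reactions
        dF = np.zeros((nr, self.network.n_species))
        for j in range(nr):
            i1, i2 = self._r1[j], self._r2[j]
            if i1 < 0:
                continue
            if i2 < 0:
                dF[j, i1] += self.k[j]
            else:
                dF[j, i1] += self.k[j] * x[i2]
                dF[j, i2] += self.k[j] * x[i1]
        return self._S @ dF


def reaction_table(network: ReactionNetwork):
    """The reaction list as a tidy table (for audit / export)."""
    import pandas as pd

    def side(ids):
        return " + ".join(f"x{i}" for i in ids) if ids else "0"

    return pd.DataFrame([
        {"id": rx.id, "reactants": side(rx.reactants), "products": side(rx.products),
         "rate_symbol": rx.rate_symbol, "delay": rx.delay}
        for rx in network.reactions
    ])


def rhs(state: np.ndarray, params, network: ReactionNetwork) -> np.ndarray:
    """Mass-action derivative: stoichiometry . flux at ``state``.

    Convenience wrapper; hot loops should build a
    :class:`MassActionSystem` once and reuse it.
    """
    state = np.asarray(state, float)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state length {state.shape} does not match {network.n_species} species"
        )
    return MassActionSystem(network, params).rhs(0.0, state)
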