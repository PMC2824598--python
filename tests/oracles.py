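"""Independent oracles shared by the test modules."""

from collections import Counter

import numpy as np


def brute_force_rhs(state, params, network):
    """Flux-by-flux accumulation over the printed reaction list."""
    dx = np.zeros(network.n_species)
    pos = {sp.index: i for i, sp in enumerate(network.species)}
    for rx in network.reactions:
        flux = params[rx.rate_symbol]
        for i in rx.reactants:
            flux *= state[pos[i]]
        for i, c in Counter(rx.reactants).items():
            dx[pos[i]] -= c * flux
        for i, c in Counter(rx.products).items():
            dx[pos[i]] += c * flux
    return dx
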