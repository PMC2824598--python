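"""Steady-state branches, linear stability and Hopf analysis.

The promoter moiety (free promoter + promoter complexes) is conserved
by every reaction, so the full-state Jacobian always carries one
structural zero eigenvalue and Newton iterations on the full state are
singular at a root.  All root solving and eigenvalue analysis is
therefore done in *reduced coordinates* in which the free promoter is
eliminated through the conservation law; the structural zero disappears
and stability flags reflect the dynamics on the invariant stoichiometric
subspace.

Hopf points are localised by bisection on the leading complex
eigenvalue pair along a continuation branch.  Sub/supercritical
classification uses the defining hysteresis property: a trajectory
seeded on the oscillatory attractor is continued just past onset onto
the stable-steady-state side, where a subcritical point sustains the
large-amplitude cycle while a supercritical one lets the envelope decay
to the focus.  (The square-root amplitude law near a supercritical
onset is available separately in :func:`classify_amplitude_scaling`;
critical slowing down makes it far more expensive to measure reliably
on this network.)  Unstable limit cycles are computed with a
single-period shooting method seeded from the linearised oscillation at
the Hopf point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .network import MassActionSystem, ReactionNetwork
from .parameters import ParameterSet

__all__ = [
    "BifurcationBranch",
    "PeriodicOrbit",
    "solve_steady_state",
    "stability",
    "trace_branch",
    "limit_cycle",
    "shoot_periodic",
    "classify_hopf",
    "classify_amplitude_scaling",
    "mdmx_bifurcation",
]


class ReducedSystem:
    """Mass-action system with the free promoter eliminated.

    State ``y`` omits x13; x13 is recovered from the promoter total and
    the promoter-complex concentrations.
    """

    def __init__(self, system: MassActionSystem, promoter_total: float) -> None:
        net = system.network
        self.system = system
        self.promoter_total = float(promoter_total)
        self.i13 = net.species_position(13)
        self.keep = np.array([i for i in range(net.n_species) if i != self.i13])
        complexes = [14] if net.variant == "simple" else [14, 16]
        self.dep_full = np.array([net.species_position(i) for i in complexes])
        # positions of the promoter complexes inside the reduced vector
        self.dep_red = np.array([np.searchsorted(self.keep, i) for i in self.dep_full])

    def to_full(self, y: np.ndarray) -> np.ndarray:
        x = np.empty(self.system.network.n_species)
        x[self.keep] = y
        x[self.i13] = self.promoter_total - y[self.dep_red].sum()
        return x

    def to_reduced(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float)[self.keep]

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return self.system.rhs(0.0, self.to_full(y))[self.keep]

    def jac(self, y: np.ndarray) -> np.ndarray:
        J = self.system.jacobian(0.0, self.to_full(y))
        Jr = J[np.ix_(self.keep, self.keep)]
        # chain rule through x13 = P - sum(promoter complexes)
        Jr[:, self.dep_red] -= J[self.keep][:, [self.i13]]
        return Jr


def _safe_div(num: float, den: float, what: str) -> float:
    if den > 0:
        return num / den
    if num == 0:
        return 0.0
    raise RuntimeError(f"{what} has inflow but no outflow; no finite steady state")


def steady_state_reduction(
    params: ParameterSet,
    network: ReactionNetwork,
    promoter_total: float | None = None,
    x1_cap: float = 1e18,
) -> np.ndarray:
    """Steady state from the scalar-reduction of the network.

    At steady state the phosphorylation/oligomerisation cascade is in
    detailed balance (dimers, tetramers and the promoter complex have
    no sink other than dissociation), the heterodimer reservoirs
    satisfy flux balance, and Mdm2 is an explicit function of free p53;
    the whole system therefore reduces to a single scalar balance for
    free p53, solved by bracketed root finding.  The MdmX block does
    not feed back into that scalar equation -- steady levels of all
    non-MdmX species are independent of k15.

    This is exact for both variants and any damage level, provided the
    scalar balance is monotone over the bracket (true away from folds
    of the steady-state branch).
    """
    p = params
    P = params.promoter_total if promoter_total is None else promoter_total
    full = network.variant == "full"

    c2 = _safe_div(p["k3"], p["k4"] + p["k5"], "phosphorylated p53")  # x2 = c2*x1
    r11 = _safe_div(p["k27"], p["k28"], "p53P dimer")
    r12 = _safe_div(p["k29"], p["k30"], "p53P tetramer")
    r14 = _safe_div(p["k31"], p["k32"], "tetramer:promoter")
    r16 = _safe_div(p["k34"], p["k35"], "p53:promoter") if full else 0.0

    def oligo(x1: float) -> tuple[float, float, float]:
        x2 = c2 * x1
        x11 = r11 * x2 * x2
        x12 = r12 * x11 * x11
        return x2, x11, x12

    def promoter(x1: float) -> tuple[float, float, float]:
        _, _, x12 = oligo(x1)
        load = 1.0 + r14 * x12 + r16 * x1
        x13 = P / load
        return x13, r14 * x12 * x13, r16 * x1 * x13  # x13, x14, x16

    c7 = p["k12"] + p["k13"] + p["k14"]
    drain1_7 = _safe_div(p["k11"] * p["k13"], c7, "p53:Mdm2") if p["k11"] else 0.0
    drain3_7 = _safe_div(p["k11"] * p["k14"], c7, "p53:Mdm2") if p["k11"] else 0.0
    drain3_4 = _safe_div(p["k8"] * p["k10"], p["k9"] + p["k10"], "Mdm2P") if p["k8"] else 0.0

    def mdm2(x1: float) -> float:
        x13, x14, x16 = promoter(x1)
        if full:
            # x15 balance: k33*x14 + k36*x16 = k37*x15
            x15 = _safe_div(p["k33"] * x14 + p["k36"] * x16, p["k37"], "mRNA")
            source = p["k6"] + p["k38"] * x15
        else:
            source = p["k6"] + p["k33"] * x14
        return _safe_div(source, p["k7"] + drain3_4 + drain3_7 * x1, "Mdm2")

    drain1_2 = c2 * p["k5"]  # net p53 loss through the phospho branch

    def p53_balance(x1: float) -> float:
        return p["k1"] - (p["k2"] + drain1_2) * x1 - drain1_7 * x1 * mdm2(x1)

    if p["k1"] == 0:
        x1 = 0.0
    else:
        if p["k2"] + drain1_2 + drain1_7 == 0:
            raise RuntimeError("p53 has inflow but no outflow; no steady state")
        from scipy.optimize import brentq

        hi = 1.0
        while p53_balance(hi) > 0:
            hi *= 10.0
            if hi > x1_cap:
                raise RuntimeError("p53 balance does not close below the cap")
        x1 = brentq(p53_balance, 0.0, hi, rtol=8.9e-16, maxiter=200)

    x2, x11, x12 = oligo(x1)
    x13, x14, x16 = promoter(x1)
    x3 = mdm2(x1)
    x4 = _safe_div(p["k8"] * x3, p["k9"] + p["k10"], "Mdm2P")
    x7 = _safe_div(p["k11"] * x1 * x3, c7, "p53:Mdm2") if p["k11"] else 0.0

    # MdmX block: x6 and x8 drain MdmX; x9/x10 are flux-balanced.
    q8 = _safe_div(p["k20"] * x3 * p["k22"], p["k21"] + p["k22"], "Mdm2:MdmXP")
    c6 = _safe_div(p["k17"], p["k18"] + p["k19"] + q8, "MdmXP")  # x6 = c6*x5
    x5 = _safe_div(p["k15"], p["k16"] + c6 * (p["k19"] + q8), "MdmX")
    x6 = c6 * x5
    x8 = _safe_div(p["k20"] * x3 * x6, p["k21"] + p["k22"], "Mdm2:MdmXP")
    x9 = _safe_div(p["k23"] * x3 * x5, p["k24"], "Mdm2:MdmX")
    x10 = _safe_div(p["k25"] * x1 * x5, p["k26"], "p53:MdmX")

    vals = {1: x1, 2: x2, 3: x3, 4: x4, 5: x5, 6: x6, 7: x7, 8: x8,
            9: x9, 10: x10, 11: x11, 12: x12, 13: x13, 14: x14}
    if full:
        x15 = _safe_div(p["k33"] * x14 + p["k36"] * x16, p["k37"], "mRNA")
        vals.update({15: x15, 16: x16})
    x = np.zeros(network.n_species)
    for idx, v in vals.items():
        x[network.species_position(idx)] = v
    return x


def solve_steady_state(
    params: ParameterSet,
    network: ReactionNetwork,
    guess: np.ndarray,
    tol: float = 1e-11,
) -> np.ndarray:
    """Quasi-Newton steady-state solve from ``guess``.

    The promoter total is read off the guess (conserved quantity).
    Raises on non-convergence or on convergence to a negative state.
    """
    guess = np.asarray(guess, float)
    if guess.min() < -1e-9:
        raise ValueError("negative entries in steady-state guess")
    system = MassActionSystem(network, params)
    P = guess[network.promoter_rows].sum()
    red = ReducedSystem(system, P)

    def ok(x: np.ndarray) -> bool:
        resid = np.max(np.abs(system.rhs(0.0, x)))
        return resid <= tol * (1.0 + np.max(np.abs(x)))

    sol = root(red.rhs, red.to_reduced(guess), jac=red.jac, method="hybr",
               options={"xtol": 1e-13})
    x = red.to_full(sol.x)
    if not ok(x):
        # Species magnitudes can span >10 decades (oligomer pools at high
        # p53 production); rescale each Newton step by the current state
        # and damp it to preserve nonnegativity.
        y = np.clip(red.to_reduced(guess), 0.0, None)
        for _ in range(80):
            f = red.rhs(y)
            s = np.maximum(np.abs(y), 1e-12)
            try:
                d = np.linalg.solve(red.jac(y) * s[None, :], -f)
            except np.linalg.LinAlgError:
                break
            step = s * d
            lam = 1.0
            base = np.linalg.norm(f / np.maximum(s, 1.0))
            for _ in range(40):
                y_new = y + lam * step
                if y_new.min() >= -1e-13:
                    y_new = np.clip(y_new, 0.0, None)
                    if np.linalg.norm(red.rhs(y_new) / np.maximum(s, 1.0)) < base:
                        break
                lam *= 0.5
            else:
                break
            y = y_new
            if ok(red.to_full(y)):
                break
        # final polish
        sol = root(red.rhs, y, jac=red.jac, method="hybr", options={"xtol": 1e-13})
        x = red.to_full(sol.x)
        if not ok(x):
            x = red.to_full(y)
    if not ok(x):
        resid = np.max(np.abs(system.rhs(0.0, x)))
        raise RuntimeError(f"steady-state solve did not converge (residual {resid:.3g})")
    if x.min() < -1e-9:
        raise RuntimeError("steady-state solve converged to a negative state")
    return np.clip(x, 0.0, None)


def stability(
    state: np.ndarray,
    params: ParameterSet,
    network: ReactionNetwork,
    check_residual: bool = True,
) -> tuple[np.ndarray, bool]:
    """Eigenvalue spectrum of the reduced Jacobian and a stability flag.

    The Jacobian is the analytic derivative of the mass-action fluxes;
    the flag is True when every eigenvalue has negative real part.
    """
    state = np.asarray(state, float)
    system = MassActionSystem(network, params)
    if check_residual:
        resid = np.max(np.abs(system.rhs(0.0, state)))
        if resid > 1e-6 * (1.0 + np.max(np.abs(state))):
            raise ValueError(f"state is not steady (residual {resid:.3g})")
    red = ReducedSystem(system, state[network.promoter_rows].sum())
    eig = np.linalg.eigvals(red.jac(red.to_reduced(state)))
    return eig, bool(np.all(eig.real < 0))


def _leading_complex_real(eig: np.ndarray) -> float:
    """Max real part over the complex-conjugate eigenvalue pairs."""
    complex_part = eig[np.abs(eig.imag) > 1e-9]
    if complex_part.size == 0:
        return -np.inf
    return float(complex_part.real.max())


@dataclass
class BifurcationBranch:
    """Steady states along a control parameter with stability data."""

    control: str
    grid: np.ndarray
    steady_states: np.ndarray  # (n_points, n_species)
    eigenvalues: list = field(repr=False, default_factory=list)
    stable: np.ndarray | None = None
    hopf_points: list = field(default_factory=list)
    cycle_min: np.ndarray | None = None
    cycle_max: np.ndarray | None = None
    cycle_stable: np.ndarray | None = None

    def activity(self, network: ReactionNetwork, species: int = 14) -> np.ndarray:
        return self.steady_states[:, network.species_position(species)]


def _seed_steady_state(
    params: ParameterSet,
    network: ReactionNetwork,
    t_seed: float,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Guess a steady state by long integration (time-average of the tail)."""
    from .simulate import default_initial_state, integrate

    system = MassActionSystem(network, params)
    x0 = default_initial_state(network, params.promoter_total)
    grid = np.linspace(0, t_seed, 400)
    sol = integrate(system, x0, (0.0, t_seed), t_grid=grid, rtol=rtol, atol=atol)
    return sol.y[:, 200:].mean(axis=1)


def trace_branch(
    params: ParameterSet,
    network: ReactionNetwork,
    control: str,
    grid: np.ndarray,
    guess: np.ndarray | None = None,
    seed_from: str = "high",
    t_seed: float = 4e4,
    hopf_rtol: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> BifurcationBranch:
    """Continuation of the steady-state branch over a control parameter.

    Each solution seeds the Newton solve at the next grid point; on
    failure the continuation step is halved (up to 8 times).  Hopf
    points are bracketed by sign changes of the leading complex
    eigenvalue pair and refined by bisection to ``hopf_rtol`` relative
    accuracy on the control value.
    """
    grid = np.asarray(grid, float)
    order = np.argsort(grid)
    if seed_from == "high":
        order = order[::-1]
    n = grid.size
    nsp = network.n_species
    states = np.full((n, nsp), np.nan)
    eigs: list = [None] * n
    stab = np.zeros(n, bool)

    def solve_at(cval: float, g: np.ndarray | None) -> np.ndarray:
        p = params.with_rates(**{control: cval})
        try:
            return steady_state_reduction(p, network)
        except RuntimeError:
            if g is None:
                raise
            return solve_steady_state(p, network, g)

    if guess is None:
        try:
            guess = solve_at(grid[order[0]], None)
        except RuntimeError:
            guess = _seed_steady_state(
                params.with_rates(**{control: grid[order[0]]}), network,
                t_seed, rtol, atol)
            guess = solve_steady_state(
                params.with_rates(**{control: grid[order[0]]}), network, guess)

    prev = guess
    prev_c = grid[order[0]]
    for idx in order:
        cval = grid[idx]
        # halve the continuation step on Newton failure
        sub_from, x = prev_c, prev
        for attempt in range(9):
            try:
                steps = 2 ** attempt
                xa = x
                for s in range(1, steps + 1):
                    cs = sub_from + (cval - sub_from) * s / steps
                    xa = solve_at(cs, xa)
                x = xa
                break
            except RuntimeError:
                if attempt == 8:
                    raise
        states[idx] = x
        p = params.with_rates(**{control: cval})
        eig, flag = stability(x, p, network)
        eigs[idx] = eig
        stab[idx] = flag
        prev, prev_c = x, cval

    branch = BifurcationBranch(control, grid, states, eigs, stab)

    # localise Hopf points between consecutive grid points
    lead = np.array([_leading_complex_real(e) for e in eigs])
    for a in range(n - 1):
        la, lb = lead[a], lead[a + 1]
        if np.isfinite(la) and np.isfinite(lb) and la * lb < 0:
            lo, hi = grid[a], grid[a + 1]
            xlo = states[a].copy()
            flo = la
            while abs(hi - lo) > hopf_rtol * max(abs(lo), abs(hi)):
                mid = 0.5 * (lo + hi)
                xm = solve_at(mid, xlo)
                em, _ = stability(xm, params.with_rates(**{control: mid}), network)
                fm = _leading_complex_real(em)
                if flo * fm <= 0:
                    hi = mid
                else:
                    lo, xlo, flo = mid, xm, fm
            branch.hopf_points.append(0.5 * (lo + hi))
    branch.hopf_points.sort()
    return branch


def limit_cycle(
    params: ParameterSet,
    network: ReactionNetwork,
    control: str | None = None,
    control_value: float | None = None,
    species: int = 14,
    x0: np.ndarray | None = None,
    t_end: float = 1e5,
    dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> dict:
    """Limit-cycle extrema of a monitored species by long integration.

    The first half of the run is discarded as transient; returns the
    min/max of the monitored species over the second half, the median
    peak period (None when fewer than 3 peaks survive), and the final
    state (a point on/near the attractor).
    """
    from .metrics import detect_peaks
    from .simulate import default_initial_state, integrate

    p = params if control is None else params.with_rates(**{control: control_value})
    system = MassActionSystem(network, p)
    if x0 is None:
        x0 = default_initial_state(network, p.promoter_total)
    grid = np.arange(0.0, t_end + dt / 2, dt)
    sol = integrate(system, x0, (0.0, t_end), t_grid=grid, rtol=rtol, atol=atol)
    half = sol.t.size // 2
    t_tail = sol.t[half:]
    y_tail = sol.y[network.species_position(species), half:]
    peaks = detect_peaks(t_tail, y_tail, discard_frac=0.0)
    return {
        "min": float(y_tail.min()),
        "max": float(y_tail.max()),
        "amplitude": float(y_tail.max() - y_tail.min()),
        "period": peaks.period,
        "oscillating": peaks.oscillating,
        "final_state": sol.y[:, -1],
    }


@dataclass
class PeriodicOrbit:
    """A single-period orbit from the shooting method."""

    period: float
    initial_state: np.ndarray
    times: np.ndarray
    profile: np.ndarray  # (n_samples, n_species)
    floquet_multipliers: np.ndarray
    floquet_stable: bool
    residual: float


def _flow(red: ReducedSystem, y0: np.ndarray, T: float, rtol: float, atol: float,
          n_out: int = 2) -> tuple[np.ndarray, np.ndarray]:
    from scipy.integrate import solve_ivp

    sol = solve_ivp(lambda t, y: red.rhs(y), (0.0, T), y0, method="LSODA",
                    jac=lambda t, y: red.jac(y),
                    t_eval=np.linspace(0.0, T, n_out), rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"flow integration failed: {sol.message}")
    return sol.t, sol.y.T


def shoot_periodic(
    params: ParameterSet,
    network: ReactionNetwork,
    guess_state: np.ndarray,
    guess_period: float,
    tol: float = 1e-8,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    n_profile: int = 200,
) -> PeriodicOrbit:
    """Newton shooting for a periodic orbit with periodic boundary
    conditions over a single period.

    Unknowns are the reduced initial state and the period; the phase is
    pinned by requiring the correction to be orthogonal to the flow
    direction at the guess.  Works equally for stable and unstable
    cycles (the Newton iteration does not care about orbital
    stability); Floquet multipliers of the monodromy matrix report the
    stability.
    """
    if guess_period is None or guess_period <= 0:
        raise ValueError("shooting needs a positive guess period")
    system = MassActionSystem(network, params)
    P = np.asarray(guess_state, float)[network.promoter_rows].sum()
    red = ReducedSystem(system, P)
    y_ref = red.to_reduced(guess_state)
    f_ref = red.rhs(y_ref)
    nrm = np.linalg.norm(f_ref)
    if nrm == 0:
        raise ValueError("guess state is an equilibrium; cannot anchor the phase")
    f_ref = f_ref / nrm
    m = y_ref.size

    def residual(z: np.ndarray) -> np.ndarray:
        y0, T = z[:m], z[m]
        if T <= 0:
            return np.full(m + 1, 1e3)
        _, ys = _flow(red, y0, T, rtol, atol)
        r = np.empty(m + 1)
        r[:m] = ys[-1] - y0
        r[m] = f_ref @ (y0 - y_ref)
        return r

    z0 = np.concatenate([y_ref, [guess_period]])
    sol = root(residual, z0, method="hybr",
               options={"xtol": 1e-12, "maxfev": 200 * (m + 2)})
    res = np.max(np.abs(residual(sol.x)))
    scale = max(1.0, float(np.max(np.abs(sol.x[:m]))))
    if res > tol * scale:
        raise RuntimeError(f"shooting did not converge (residual {res:.3g})")
    y0, T = sol.x[:m], float(sol.x[m])

    # monodromy by forward differences around the converged orbit
    _, base = _flow(red, y0, T, rtol, atol)
    M = np.empty((m, m))
    h0 = 1e-7 * max(1.0, np.max(np.abs(y0)))
    for j in range(m):
        yp = y0.copy()
        yp[j] += h0
        _, ysp = _flow(red, yp, T, rtol, atol)
        M[:, j] = (ysp[-1] - base[-1]) / h0
    mult = np.linalg.eigvals(M)
    # drop the trivial multiplier (closest to +1)
    trivial = np.argmin(np.abs(mult - 1.0))
    nontrivial = np.delete(mult, trivial)
    stable_flag = bool(np.all(np.abs(nontrivial) < 1.0 + 1e-6))

    ts, prof_red = _flow(red, y0, T, rtol, atol, n_out=n_profile)
    profile = np.array([red.to_full(y) for y in prof_red])
    return PeriodicOrbit(T, red.to_full(y0), ts, profile, mult, stable_flag, res)


def classify_amplitude_scaling(deltas: np.ndarray, amplitudes: np.ndarray,
                               jump_ratio: float = 0.6) -> str:
    """Classify a Hopf point from cycle amplitudes at distances past onset.

    A supercritical Hopf obeys amplitude ~ sqrt(distance): halving the
    distance shrinks the amplitude by ~sqrt(2) and the extrapolated
    amplitude at onset is ~0.  A subcritical point shows an O(1) jump:
    the amplitude barely depends on the distance.  The discriminator is
    the ratio amplitude(smallest delta) / amplitude(largest delta)
    compared against the square-root prediction.
    """
    deltas = np.asarray(deltas, float)
    amplitudes = np.asarray(amplitudes, float)
    order = np.argsort(deltas)
    deltas, amplitudes = deltas[order], amplitudes[order]
    if np.any(amplitudes <= 0):
        return "supercritical"  # cycle vanished at small distance
    observed = amplitudes[0] / amplitudes[-1]
    predicted = np.sqrt(deltas[0] / deltas[-1])
    # midpoint (in ratio space) between sqrt-law and no-shrinkage
    threshold = predicted + jump_ratio * (1.0 - predicted)
    return "supercritical" if observed < threshold else "subcritical"


def _peak_amplitudes(times: np.ndarray, series: np.ndarray) -> np.ndarray:
    """Per-cycle amplitude envelope (successive peak minus trough)."""
    from scipy.signal import find_peaks

    rng = series.max() - series.min()
    if rng <= 0:
        return np.array([])
    hi, _ = find_peaks(series, prominence=1e-4 * rng)
    lo, _ = find_peaks(-series, prominence=1e-4 * rng)
    n = min(hi.size, lo.size)
    if n == 0:
        return np.array([])
    return np.abs(series[hi[:n]] - series[lo[:n]])


def classify_hopf(
    params: ParameterSet,
    network: ReactionNetwork,
    control: str,
    hopf_value: float,
    species: int = 14,
    rel_seed: float = 0.10,
    rel_probe: float = 0.02,
    n_cycles: float = 50.0,
    decay_factor: float = 2.0,
    dt: float = 5.0,
) -> dict:
    """Sub/supercritical classification of a localised Hopf point.

    Exploits the defining hysteresis property.  A trajectory started on
    the large-amplitude oscillatory attractor (seeded at ``rel_seed``
    into the unstable-steady-state side) is continued with the control
    parameter moved just past onset onto the *stable*-steady-state side
    (``rel_probe``).  At a subcritical point a stable large cycle
    coexists with the stable steady state there, so the oscillation
    persists; at a supercritical point the cycle has collapsed through
    the Hopf point and the oscillation envelope decays to the focus.
    The envelope is classified as decaying when it shrinks by more than
    ``decay_factor`` over ~``n_cycles`` periods.
    """
    from .simulate import integrate

    # find the unstable side by probing the leading complex pair
    sides = {}
    for s in (+1, -1):
        cval = hopf_value * (1 + s * rel_probe)
        p = params.with_rates(**{control: cval})
        ss = steady_state_reduction(p, network)
        eig, _ = stability(ss, p, network)
        sides[s] = _leading_complex_real(eig)
    if max(sides.values()) < 0:
        raise RuntimeError("no unstable side found near the putative Hopf point")
    us = +1 if sides[+1] > sides[-1] else -1

    # seed the oscillatory attractor well inside the unstable region
    seed = limit_cycle(params, network, control,
                       hopf_value * (1 + us * rel_seed),
                       species=species, t_end=2e5, dt=dt)
    if not seed["oscillating"]:
        raise RuntimeError("no oscillation found on the unstable side; "
                           "cannot classify (inconclusive)")
    period = seed["period"]

    # continue on the stable side from the large-amplitude state
    cval = hopf_value * (1 - us * rel_probe)
    p = params.with_rates(**{control: cval})
    system = MassActionSystem(network, p)
    t_probe = n_cycles * period
    grid = np.arange(0.0, t_probe, dt)
    sol = integrate(system, seed["final_state"], (0.0, t_probe), t_grid=grid,
                    rtol=1e-8, atol=1e-12)
    y = sol.y[network.species_position(species)]
    envelope = _peak_amplitudes(sol.t, y)
    if envelope.size < 4:
        # no full cycles survived at all: clear collapse
        ratio = 0.0
    else:
        k = max(1, envelope.size // 4)
        ratio = float(np.median(envelope[-k:]) / np.median(envelope[:k]))
    kind = "supercritical" if ratio < 1.0 / decay_factor else "subcritical"
    return {
        "classification": kind,
        "control": control,
        "hopf_value": hopf_value,
        "unstable_side": us,
        "seed_amplitude": seed["amplitude"],
        "envelope_ratio": ratio,
        "period": period,
    }


def mdmx_bifurcation(
    params: ParameterSet,
    network: ReactionNetwork,
    k15_grid: np.ndarray | None = None,
    **kwargs,
) -> BifurcationBranch:
    """Steady-state branch over the MdmX basal production rate k15.

    Locates the k15 value above which the damage-phase oscillation
    gives way to a stable steady state (the memory-effect boundary).
    """
    if k15_grid is None:
        base = params["k15"]
        k15_grid = np.logspace(np.log10(base), np.log10(100 * base), 25)
    k15_grid = np.atleast_1d(np.asarray(k15_grid, float))
    p = params.for_phase(damage=True)
    if k15_grid.size == 1:
        g = _seed_steady_state(p.with_rates(k15=k15_grid[0]), network, 4e4, 1e-8, 1e-12)
        ss = solve_steady_state(p.with_rates(k15=k15_grid[0]), network, g)
        eig, flag = stability(ss, p.with_rates(k15=k15_grid[0]), network)
        return BifurcationBranch("k15", k15_grid, ss[None, :], [eig],
                                 np.array([flag]))
    return trace_branch(p, network, "k15", k15_grid, **kwargs)
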