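"""Simulation protocols for the p53-Mdm2-MdmX model.

DNA damage is represented by switching the three damage-kinase
phosphorylation rate constants (k3 = k8 = k17) from zero to a common
positive value, held constant thereafter (ATM activity saturates
quickly and stays on).  Early-response studies pre-equilibrate the
damage-free system first so that the heterodimer reservoirs are at
their resting levels; late-response (oscillation) studies start from
the documented default initial state instead, since the limit cycle
does not depend on the transient.

Protocols implemented here:

* :func:`pre_equilibrate` -- damage-free steady state.
* :func:`run_damage` -- the standard damage response (early or late).
* :func:`run_delay` -- simple model with a transcription/translation
  delay on Mdm2 production (method of steps).
* :func:`run_nutlin` -- blockade of p53-Mdm2 binding (k11 = 0) without
  damage; returns total-protein fold changes.
* :func:`run_pulse` -- piecewise schedule of the MdmX basal production
  rate (memory-effect protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import MassActionSystem, ReactionNetwork, build_network
from .parameters import ParameterSet

__all__ = [
    "DamageProtocol",
    "PulseSchedule",
    "Trajectory",
    "default_initial_state",
    "integrate",
    "pre_equilibrate",
    "run_damage",
    "run_delay",
    "run_nutlin",
    "run_pulse",
]

#: Default relative/absolute integration tolerances.  The absolute
#: tolerance must sit far below the smallest dynamically relevant
#: concentrations (mRNA in the fitted sets is O(1e-4)).
RTOL = 1e-8
ATOL = 1e-12


class SimulationError(RuntimeError):
    """Integration or equilibration failure, with protocol context."""


@dataclass(frozen=True)
class DamageProtocol:
    """Configuration of a DNA-damage simulation.

    ``phospho_rate=None`` keeps the parameter set's own k3/k8/k17
    values (the fitted full-model sets carry the damage-phase rates in
    their columns); an explicit value overrides all three.
    """

    phospho_rate: float | None = None
    t_end: float = 180.0
    pre_equilibrate: bool = True
    feedback_off: bool = False
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.phospho_rate is not None and self.phospho_rate < 0:
            raise ValueError("phospho_rate must be >= 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass(frozen=True)
class PulseSchedule:
    """Contiguous phases of (duration, k15 multiplier)."""

    phases: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("empty pulse schedule")
        if any(d <= 0 for d, _ in self.phases):
            raise ValueError("phase durations must be positive")


@dataclass
class Trajectory:
    """Time grid, species matrix and protocol provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    network: ReactionNetwork
    protocol: str = ""
    units: str = "AU"
    phase_marks: tuple[tuple[float, float], ...] = ()

    def series(self, species_index: int) -> np.ndarray:
        """Concentration time series of species ``x<species_index>``."""
        return self.states[:, self.network.species_position(species_index)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, species, value, protocol)."""
        recs = []
        for sp in self.network.species:
            recs.append(pd.DataFrame({
                "time": self.times,
                "species": f"x{sp.index}",
                "value": self.states[:, self.network.species_position(sp.index)],
            }))
        out = pd.concat(recs, ignore_index=True)
        out["protocol"] = self.protocol
        return out


def default_initial_state(network: ReactionNetwork, promoter_total: float = 1.0) -> np.ndarray:
    """All species zero except free promoter at ``promoter_total``."""
    x0 = np.zeros(network.n_species)
    x0[network.species_position(13)] = promoter_total
    return x0


def _zero_damage(params: ParameterSet) -> ParameterSet:
    return params.for_phase(damage=False).with_rates(k3=0.0, k8=0.0, k17=0.0)


def _damage_rates(params: ParameterSet, phospho_rate: float | None) -> ParameterSet:
    p = params.for_phase(damage=True)
    if phospho_rate is not None:
        p = p.with_rates(k3=phospho_rate, k8=phospho_rate, k17=phospho_rate)
    return p


def integrate(
    system: MassActionSystem,
    x0: np.ndarray,
    t_span: tuple[float, float],
    t_grid: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    dense: bool = False,
):
    """Stiff integration of a compiled system with its analytic Jacobian."""
    if t_grid is None:
        t_grid = np.arange(t_span[0], t_span[1] + 0.5, 1.0)
    sol = solve_ivp(
        system.rhs, t_span, np.asarray(x0, float), method="LSODA",
        jac=system.jacobian, t_eval=None if dense else t_grid,
        dense_output=dense, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    return sol


def pre_equilibrate(
    params: ParameterSet,
    network: ReactionNetwork,
    x0: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> np.ndarray:
    """Damage-free steady state (k3 = k8 = k17 = 0, pre-damage k1).

    Uses the scalar steady-state reduction (exact for this network;
    see :func:`p53mdmx.bifurcation.steady_state_reduction` -- with the
    damage kinases off every phosphorylated species vanishes and the
    reduction is unconditionally valid) and verifies the residual
    ``||f||_inf < 1e-9 * (1 + ||x||_inf)``.  When a custom ``x0`` is
    given (a different basin is suspected) it falls back to stiff
    integration with Newton polish from that state.
    """
    p = _zero_damage(params)
    system = MassActionSystem(network, p)

    def residual_ok(state: np.ndarray) -> bool:
        f = system.rhs(0.0, state)
        return np.max(np.abs(f)) < 1e-9 * (1.0 + np.max(np.abs(state)))

    if x0 is None:
        from .bifurcation import steady_state_reduction

        try:
            x = steady_state_reduction(p, network)
        except RuntimeError as exc:
            raise SimulationError(f"pre-equilibration failed: {exc}") from exc
        if not residual_ok(x):
            raise SimulationError(
                f"analytic equilibrium residual too large "
                f"({np.max(np.abs(system.rhs(0.0, x))):.3g})")
        return x

    from .bifurcation import solve_steady_state

    x = np.asarray(x0, float)
    t_end = 1e4
    for _ in range(8):
        sol = integrate(system, x, (0.0, t_end), t_grid=np.array([0.0, t_end]),
                        rtol=rtol, atol=atol)
        x = sol.y[:, -1]
        try:
            x_pol = solve_steady_state(p, network, x)
            if residual_ok(x_pol):
                return x_pol
        except RuntimeError:
            pass
        if residual_ok(x):
            return x
        t_end *= 2.0
    raise SimulationError(
        "pre-equilibration did not converge; the damage-free system may be oscillatory"
    )


def run_damage(
    params: ParameterSet,
    protocol: DamageProtocol,
    network: ReactionNetwork,
    x0: np.ndarray | None = None,
    dt: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Simulate the DNA-damage response under ``protocol``.

    The damage-phase rates (k3 = k8 = k17 > 0 and, for the full model,
    the enhanced post-damage k1) are held constant for the whole run.
    """
    p = params
    if protocol.feedback_off:
        p = p.with_rates(k33=0.0, k14=0.0)
    if protocol.delay > 0:
        return run_delay(p, protocol, network, tau=protocol.delay,
                         x0=x0, dt=dt, rtol=rtol, atol=atol)
    if x0 is None:
        if protocol.pre_equilibrate:
            x0 = pre_equilibrate(p, network, rtol=rtol, atol=atol)
        else:
            x0 = default_initial_state(network, p.promoter_total)
    pd_ = _damage_rates(p, protocol.phospho_rate)
    system = MassActionSystem(network, pd_)
    grid = np.arange(0.0, protocol.t_end + dt / 2, dt)
    sol = integrate(system, x0, (0.0, protocol.t_end), t_grid=grid, rtol=rtol, atol=atol)
    units = "minutes" if network.variant == "full" else "AU"
    return Trajectory(sol.t, sol.y.T, network, protocol="damage", units=units)


def run_delay(
    params: ParameterSet,
    protocol: DamageProtocol,
    network: ReactionNetwork | None = None,
    tau: float = 50.0,
    x0: np.ndarray | None = None,
    dt: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Damage response with a delay tau on the Mdm2-production reaction.

    The p53-driven Mdm2 production flux at time t uses the promoter
    occupancy x14(t - tau) (transcription/translation lag).  Solved by
    the method of steps with the pre-damage state as constant history;
    internal step size is bounded by tau/20.  tau = 0 falls back to the
    plain ODE run.
    """
    if tau < 0:
        raise ValueError("delay tau must be >= 0")
    if network is None:
        network = build_network("simple")
    if network.variant != "simple":
        raise ValueError("the delayed feedback variant is defined for the simple model")
    p = params
    if protocol.feedback_off:
        p = p.with_rates(k33=0.0, k14=0.0)
    if x0 is None:
        if protocol.pre_equilibrate:
            x0 = pre_equilibrate(p, network, rtol=rtol, atol=atol)
        else:
            x0 = default_initial_state(network, p.promoter_total)
    if tau == 0:
        return run_damage(p, protocol, network, x0=x0, dt=dt, rtol=rtol, atol=atol)

    pd_ = _damage_rates(p, protocol.phospho_rate)
    k33 = pd_["k33"]
    system = MassActionSystem(network, pd_.with_rates(k33=0.0))
    i3 = network.species_position(3)
    i14 = network.species_position(14)
    x14_hist0 = float(x0[i14])

    t_end = protocol.t_end
    times = [np.array([0.0])]
    states = [np.asarray(x0, float)[None, :]]
    prev_interp = None  # dense solution of the previous step interval
    seg_start = 0.0
    x = np.asarray(x0, float)
    while seg_start < t_end - 1e-12:
        seg_end = min(seg_start + tau, t_end)

        if prev_interp is None:
            def x14_delayed(t):  # noqa: B023 - constant history
                return x14_hist0
        else:
            lo, hi, interp = prev_interp

            def x14_delayed(t, lo=lo, hi=hi, interp=interp):
                return float(interp(np.clip(t - tau, lo, hi))[i14])

        def rhs(t, y):
            f = system.rhs(t, y)
            f[i3] += k33 * x14_delayed(t)
            return f

        sol = solve_ivp(
            rhs, (seg_start, seg_end), x, method="LSODA", jac=system.jacobian,
            dense_output=True, max_step=tau / 20.0, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"delay integration failed at t={seg_start}: {sol.message}")
        grid = np.arange(seg_start + dt, seg_end + dt / 2, dt)
        grid = grid[grid <= seg_end + 1e-12]
        if grid.size:
            times.append(grid)
            states.append(sol.sol(grid).T)
        prev_interp = (seg_start, seg_end, sol.sol)
        x = sol.y[:, -1]
        seg_start = seg_end

    return Trajectory(np.concatenate(times), np.vstack(states), network,
                      protocol=f"damage_delay(tau={tau})", units="AU")


def run_nutlin(
    params: ParameterSet,
    network: ReactionNetwork,
    t_end: float = 1440.0,
    dt: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[pd.DataFrame, Trajectory]:
    """Simulated Nutlin treatment: block p53-Mdm2 association (k11 = 0).

    The network is pre-equilibrated without Nutlin and without damage;
    from t = 0 the association rate k11 is set to zero while every
    other rate keeps its pre-damage value.  Returns the fold change of
    total p53 / Mdm2 / MdmX relative to the pre-treatment totals (a
    DataFrame indexed by time), alongside the raw trajectory.
    """
    from .metrics import total_protein

    if params["k11"] <= 0:
        raise ValueError("Nutlin protocol requires k11 > 0 before treatment")
    x0 = pre_equilibrate(params, network, rtol=rtol, atol=atol)
    p = _zero_damage(params).with_rates(k11=0.0)
    system = MassActionSystem(network, p)
    grid = np.arange(0.0, t_end + dt / 2, dt)
    sol = integrate(system, x0, (0.0, t_end), t_grid=grid, rtol=rtol, atol=atol)
    units = "minutes" if network.variant == "full" else "AU"
    traj = Trajectory(sol.t, sol.y.T, network, protocol="nutlin", units=units)

    folds = {}
    for moiety in ("p53", "Mdm2", "MdmX"):
        tot = total_protein(traj, moiety)
        if tot[0] <= 0:
            raise ValueError(f"zero pre-treatment total {moiety}; fold change undefined")
        folds[moiety] = tot / tot[0]
    return pd.DataFrame(folds, index=pd.Index(traj.times, name="time")), traj


def run_pulse(
    params: ParameterSet,
    schedule: PulseSchedule,
    network: ReactionNetwork,
    phospho_rate: float | None = None,
    x0: np.ndarray | None = None,
    dt: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Piecewise-constant MdmX production schedule under DNA damage.

    Each phase multiplies the basal k15 by its factor; the state is
    carried continuously across phase boundaries.  Used for the
    memory-effect protocol (oscillation suppression outlasting a
    transient 100-fold MdmX pulse).
    """
    if x0 is None:
        x0 = default_initial_state(network, params.promoter_total)
    base = _damage_rates(params, phospho_rate)
    k15 = base["k15"]
    t0 = 0.0
    all_t = [np.array([0.0])]
    all_x = [np.asarray(x0, float)[None, :]]
    marks = []
    x = np.asarray(x0, float)
    for duration, mult in schedule.phases:
        marks.append((t0, mult))
        system = MassActionSystem(network, base.with_rates(k15=k15 * mult))
        grid = np.arange(t0, t0 + duration + dt / 2, dt)
        sol = integrate(system, x, (t0, t0 + duration), t_grid=grid, rtol=rtol, atol=atol)
        all_t.append(sol.t[1:])
        all_x.append(sol.y.T[1:])
        x = sol.y[:, -1]
        t0 += duration
    units = "minutes" if network.variant == "full" else "AU"
    return Trajectory(np.concatenate(all_t), np.vstack(all_x), network,
                      protocol="mdmx_pulse", units=units, phase_marks=tuple(marks))
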