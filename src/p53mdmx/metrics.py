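"""Response readouts: p53 activity, switch and dampening measures,
peak/period detection, heterodimer reservoir ratios and the
MdmX-effect classification.

p53 activity is promoter occupancy by p53 tetramers (x14) in the
simple model and p53-induced mRNA (x15) in the full model.  Totals are
subunit-weighted sums (dimers count twice, tetramers four times) so
that pure binding dynamics conserve them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .network import ReactionNetwork, build_network
from .parameters import ParameterSet
from .simulate import DamageProtocol, Trajectory, run_damage

__all__ = [
    "total_protein",
    "early_activity",
    "delta_A",
    "delta_M",
    "PeakResult",
    "detect_peaks",
    "period",
    "EffectClassification",
    "classify_effect",
    "reservoir_log_ratio",
]

#: Early-response readout time of the simple model (AU).
EARLY_READOUT_SIMPLE = 55.0
#: Early-response window of the full model (minutes).
EARLY_WINDOW_FULL = (0.0, 180.0)
#: Late-response window of the full model (minutes).
LATE_WINDOW_FULL = (10020.0, 10980.0)


def total_protein(trajectory: Trajectory, moiety: str) -> np.ndarray:
    """Subunit-weighted total of a moiety (p53, Mdm2 or MdmX) over time."""
    w = trajectory.network.moiety_weights(moiety)
    return trajectory.states @ w


def early_activity(trajectory: Trajectory, variant: str | None = None) -> float:
    """Early-response p53 activity.

    Simple model: promoter occupancy x14 at t = 55 AU (the system has
    not yet reached steady state there; the readout captures the
    reservoir-driven transient).  Full model: maximum mRNA x15 over
    0-180 min, the first rise of p53 activity after damage.
    """
    variant = variant or trajectory.network.variant
    t = trajectory.times
    if variant == "simple":
        if t[-1] < EARLY_READOUT_SIMPLE:
            raise ValueError("trajectory does not cover t = 55 AU")
        return float(np.interp(EARLY_READOUT_SIMPLE, t, trajectory.series(14)))
    lo, hi = EARLY_WINDOW_FULL
    mask = (t >= lo) & (t <= hi)
    if not mask.any() or t[-1] < hi:
        raise ValueError("trajectory does not cover the 0-180 min window")
    return float(trajectory.series(15)[mask].max())


def delta_A(
    params: ParameterSet,
    k15_value: float,
    network: ReactionNetwork | None = None,
    phospho_rate: float | None = None,
    **rate_overrides: float,
) -> float:
    """Switch measure: early activity with MdmX minus without.

    Both arms run the identical pre-equilibrated, feedback-off early
    protocol; only k15 differs (0 vs ``k15_value``).  Positive when the
    p53:MdmX reservoir dominates (low Mdm2), negative when the
    Mdm2:MdmX reservoir dominates (high Mdm2).
    """
    network = network or build_network("simple")
    proto = DamageProtocol(phospho_rate=phospho_rate, t_end=60.0,
                           pre_equilibrate=True, feedback_off=True)
    acts = {}
    for k15 in (0.0, k15_value):
        p = params.with_rates(k15=k15, **rate_overrides)
        acts[k15] = early_activity(run_damage(p, proto, network))
    return acts[k15_value] - acts[0.0]


def delta_M(
    params: ParameterSet,
    k15_value: float,
    network: ReactionNetwork | None = None,
    window: tuple[float, float] = (50_000.0, 100_000.0),
    phospho_rate: float | None = None,
    dt: float = 5.0,
    **rate_overrides: float,
) -> float:
    """Dampening measure: late-window maximum with MdmX minus without.

    The run covers the full window without pre-equilibration (the
    long-term attractor does not depend on the transient); the maximum
    of p53 activity is taken over the last half of the simulated
    period.  Negative values mean MdmX reduces the oscillation peaks.
    """
    network = network or build_network("simple")
    proto = DamageProtocol(phospho_rate=phospho_rate, t_end=window[1],
                           pre_equilibrate=False)
    species = 14 if network.variant == "simple" else 15
    maxima = {}
    for k15 in (0.0, k15_value):
        p = params.with_rates(k15=k15, **rate_overrides)
        traj = run_damage(p, proto, network, dt=dt)
        mask = (traj.times >= window[0]) & (traj.times <= window[1])
        maxima[k15] = float(traj.series(species)[mask].max())
    return maxima[k15_value] - maxima[0.0]


@dataclass
class PeakResult:
    """Detected oscillation peaks of a time series."""

    times: np.ndarray
    heights: np.ndarray
    period: float | None
    oscillating: bool


def detect_peaks(
    times: np.ndarray,
    series: np.ndarray,
    prominence_frac: float = 0.05,
    discard_frac: float = 0.2,
) -> PeakResult:
    """Local maxima above a prominence threshold, after a transient.

    The first ``discard_frac`` of the window is dropped; the prominence
    threshold is ``prominence_frac`` of the remaining series range (this
    rejects the small-amplitude ripple near Hopf points).  The period is
    the median of successive peak-time differences; it is ``None`` (and
    ``oscillating`` False) with fewer than 3 peaks.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    start = int(discard_frac * times.size)
    t, y = times[start:], series[start:]
    rng = y.max() - y.min()
    if rng <= 0:
        return PeakResult(np.array([]), np.array([]), None, False)
    idx, _ = find_peaks(y, prominence=prominence_frac * rng)
    pk_t, pk_h = t[idx], y[idx]
    if idx.size < 3:
        return PeakResult(pk_t, pk_h, None, False)
    per = float(np.median(np.diff(pk_t)))
    return PeakResult(pk_t, pk_h, per, True)


def period(times: np.ndarray, series: np.ndarray, **kwargs) -> float:
    """Median peak-to-peak interval; raises if oscillation is not detected."""
    res = detect_peaks(times, series, **kwargs)
    if not res.oscillating:
        raise ValueError("fewer than 3 peaks detected; period undefined")
    return res.period


@dataclass
class EffectClassification:
    """MdmX-effect flags per the survey's classification thresholds."""

    dependency_increase: bool
    dampening: bool
    no_dampening: bool
    mdmx_folds_tested: tuple[float, ...]
    early_table: "object" = None  # pandas DataFrame (k6, fold, pct change)
    late_table: "object" = None   # pandas DataFrame (fold, late max, pct change)

    def __post_init__(self) -> None:
        if self.dampening and self.no_dampening:
            raise ValueError("dampening and no_dampening are mutually exclusive")


def _early_max_mrna(params: ParameterSet, network: ReactionNetwork,
                    rtol: float, atol: float) -> float:
    proto = DamageProtocol(t_end=EARLY_WINDOW_FULL[1], pre_equilibrate=True)
    traj = run_damage(params, proto, network, rtol=rtol, atol=atol)
    return early_activity(traj, "full")


def late_window_max(
    params: ParameterSet,
    network: ReactionNetwork,
    window: tuple[float, float] = LATE_WINDOW_FULL,
    dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> float:
    """Maximum mRNA over the late window, from the default initial state."""
    proto = DamageProtocol(t_end=window[1] + 20.0, pre_equilibrate=False)
    traj = run_damage(params, proto, network, dt=dt, rtol=rtol, atol=atol)
    mask = (traj.times >= window[0]) & (traj.times <= window[1])
    return float(traj.series(15)[mask].max())


def classify_effect(
    params: ParameterSet,
    network: ReactionNetwork | None = None,
    k15_folds: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
    k6_grid: np.ndarray | None = None,
    late_window: tuple[float, float] = LATE_WINDOW_FULL,
    late_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> EffectClassification:
    """Classify the MdmX effect for a full-model parameter set.

    * ``dependency_increase`` -- some MdmX fold raises the early
      maximum mRNA by >5% at some low-k6 grid point AND lowers it by
      >5% at some high-k6 point (switch-like increase of the Mdm2
      dependency).
    * ``dampening`` -- some fold reduces the late-window oscillation
      maximum by >30% relative to the no-MdmX run.
    * ``no_dampening`` -- every fold reduces it by <5%.

    The k6 grid spans two decades below and above the set's baseline;
    the criteria are evaluated as "exists on the scan grid".
    """
    import pandas as pd

    network = network or build_network("full")
    if network.variant != "full":
        raise ValueError("effect classification is defined for the full model")
    base_k6 = params["k6"]
    base_k15 = params["k15"]
    if k6_grid is None:
        k6_grid = np.logspace(np.log10(base_k6) - 2, np.log10(base_k6) + 2, 9)

    early_recs = []
    for k6 in k6_grid:
        ref = _early_max_mrna(params.with_rates(k6=k6, k15=0.0), network, rtol, atol)
        for fold in k15_folds:
            val = _early_max_mrna(
                params.with_rates(k6=k6, k15=base_k15 * fold), network, rtol, atol)
            pct = np.inf if ref == 0 else 100.0 * (val - ref) / ref
            early_recs.append({"k6": k6, "fold": fold, "pct_change": pct})
    early = pd.DataFrame(early_recs)
    low = early[early.k6 < base_k6]
    high = early[early.k6 > base_k6]
    dependency = bool((low["pct_change"] > 5.0).any()
                      and (high["pct_change"] < -5.0).any())

    late_ref = late_window_max(params.with_rates(k15=0.0), network,
                               late_window, late_dt, rtol, atol)
    late_recs = []
    for fold in k15_folds:
        val = late_window_max(params.with_rates(k15=base_k15 * fold), network,
                              late_window, late_dt, rtol, atol)
        pct = np.inf if late_ref == 0 else 100.0 * (late_ref - val) / late_ref
        late_recs.append({"fold": fold, "late_max": val, "pct_reduction": pct})
    late = pd.DataFrame(late_recs)
    dampening = bool((late.pct_reduction > 30.0).any())
    no_damp = bool((late.pct_reduction < 5.0).all())

    return EffectClassification(dependency, dampening, no_damp,
                                tuple(k15_folds), early, late)


def reservoir_log_ratio(
    params: ParameterSet,
    network: ReactionNetwork | None = None,
    scan: dict[str, np.ndarray] | None = None,
    phospho_rate: float | None = None,
    readout_time: float = EARLY_READOUT_SIMPLE,
) -> "object":
    """Field of log10(x10/x9) -- p53:MdmX vs Mdm2:MdmX reservoir size.

    Evaluated at the early readout time after damage, pre-equilibrated,
    feedback off.  ``scan`` maps one or two rate symbols to grids (for
    example ``{"k23": ..., "k25": ...}`` or ``{"k6": ...}``).  Cells
    where either reservoir is exactly zero are flagged NaN; an error is
    raised if both are zero everywhere.
    """
    import itertools

    import pandas as pd

    network = network or build_network("simple")
    if scan is None:
        scan = {"k6": np.logspace(-3, 0.7, 10)}
    proto = DamageProtocol(phospho_rate=phospho_rate, t_end=readout_time + 5,
                           pre_equilibrate=True, feedback_off=True)
    symbols = list(scan)
    recs = []
    any_finite = False
    for combo in itertools.product(*(scan[s] for s in symbols)):
        p = params.with_rates(**dict(zip(symbols, combo)))
        traj = run_damage(p, proto, network)
        x9 = float(np.interp(readout_time, traj.times, traj.series(9)))
        x10 = float(np.interp(readout_time, traj.times, traj.series(10)))
        if x9 > 0 and x10 > 0:
            val = float(np.log10(x10 / x9))
            any_finite = True
        else:
            val = np.nan
        recs.append({**dict(zip(symbols, combo)), "log_ratio": val,
                     "x9": x9, "x10": x10})
    if not any_finite:
        raise ValueError("both heterodimer reservoirs are zero over the whole scan")
    return pd.DataFrame(recs)
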