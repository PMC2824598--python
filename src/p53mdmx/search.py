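"""Two-stage random survey of kinetic parameter space.

Stage 1 explores 15 rate constants of the p53-Mdm2 core (with the
remaining constants tied by fixed proportionality assumptions) for
parameter sets whose damage response reproduces the target oscillation
pattern, scored by lag-maximised normalised cross-correlation.  Stage 2
refines 11 further constants around a stage-1 hit against a composite
score that adds the Nutlin fold-change response and resting
total-protein ratios.

The search itself is a radius-growing random neighbour walk in log10
parameter space: candidates are drawn uniformly within a radius R
(decades) of the centre, the centre moves to any improvement, and R
grows after a stagnation interval up to a cap.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .network import ReactionNetwork, build_network
from .parameters import (
    STAGE1_FREE,
    STAGE2_FREE,
    ParameterSet,
    apply_search_constraints,
)
from .simulate import DamageProtocol, SimulationError, run_damage, run_nutlin
from .targets import TargetBundle

__all__ = [
    "SearchConfig",
    "SearchRecord",
    "xcorr_fitness",
    "oscillation_fitness",
    "composite_fitness",
    "neighbor_search",
    "pca_map",
]


def xcorr_fitness(
    sim: np.ndarray,
    target: np.ndarray,
    max_lag: int | None = None,
    return_lag: bool = False,
):
    """Lag-maximised normalised cross-correlation of two series.

    Both inputs must be sampled on a common grid (values only).  The
    series are mean-subtracted and the correlation at each lag is
    normalised by the norms of the overlapping segments, so the score
    lies in [-1, 1].  A zero-variance input is undefined and scores 0.
    """
    a = np.asarray(sim, float)
    b = np.asarray(target, float)
    if np.allclose(a, a.mean()) or np.allclose(b, b.mean()):
        return (0.0, None) if return_lag else 0.0
    if max_lag is None:
        max_lag = min(a.size, b.size) // 2
    best, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        # positive lag: sim shifted right relative to target
        if lag >= 0:
            n = min(a.size - lag, b.size)
            seg_a, seg_b = a[lag:lag + n], b[:n]
        else:
            n = min(a.size, b.size + lag)
            seg_a, seg_b = a[:n], b[-lag:-lag + n]
        if n < 3:
            continue
        seg_a = seg_a - seg_a.mean()
        seg_b = seg_b - seg_b.mean()
        na, nb = np.linalg.norm(seg_a), np.linalg.norm(seg_b)
        if na == 0 or nb == 0:
            continue
        c = float(seg_a @ seg_b / (na * nb))
        if c > best:
            best, best_lag = c, lag
    if not np.isfinite(best):
        return (0.0, None) if return_lag else 0.0
    return (best, best_lag) if return_lag else best


def oscillation_fitness(
    params: ParameterSet,
    targets: TargetBundle,
    network: ReactionNetwork | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> dict:
    """Cross-correlation of the simulated damage response with the
    oscillation target; also reports the p53-activity floor check.

    The model is run under damage from the default initial state over
    the target's time span; total p53 is compared (the published
    average pattern is a total-protein fluorescence trace).
    """
    from .metrics import total_protein

    network = network or build_network("full")
    tt = targets.oscillation["time"].to_numpy()
    tv = targets.oscillation["value"].to_numpy()
    dt = float(np.median(np.diff(tt)))
    try:
        traj = run_damage(params, DamageProtocol(t_end=float(tt[-1]),
                                                 pre_equilibrate=False),
                          network, dt=dt, rtol=rtol, atol=atol)
    except SimulationError as exc:
        return {"score": 0.0, "failed": str(exc), "floor_ok": False}
    sim = np.interp(tt, traj.times, total_protein(traj, "p53"))
    act = traj.series(14)
    return {
        "score": xcorr_fitness(sim, tv),
        "failed": None,
        "floor_ok": bool(act.max() > 1e-4),
    }


def composite_fitness(
    params: ParameterSet,
    targets: TargetBundle,
    network: ReactionNetwork | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> dict:
    """Composite stage-2 score in [0, 1].

    Mean (``weights``-weighted) of three [0,1]-mapped sub-scores:

    * oscillation: lag-maximised cross-correlation, mapped (s+1)/2;
    * Nutlin: RMS distance between simulated and target total p53 and
      Mdm2 fold-change curves, mapped exp(-d);
    * ratios: mean absolute log-distance of the resting Mdm2/p53 and
      MdmX/Mdm2 total-protein ratios, mapped exp(-d).

    Any simulation failure scores 0 with a diagnostic.
    """
    from .metrics import total_protein
    from .simulate import pre_equilibrate

    network = network or build_network("full")
    osc = oscillation_fitness(params, targets, network, rtol=rtol, atol=atol)
    if osc["failed"]:
        return {"score": 0.0, "failed": osc["failed"]}
    s_osc = (osc["score"] + 1.0) / 2.0

    try:
        tt = targets.nutlin["time"].to_numpy()
        folds, _ = run_nutlin(params, network, t_end=float(tt[-1]),
                              dt=max(5.0, float(np.median(np.diff(tt)))),
                              rtol=rtol, atol=atol)
        d_nut = 0.0
        for moiety in ("p53", "Mdm2"):
            sim = np.interp(tt, folds.index.to_numpy(), folds[moiety].to_numpy())
            d_nut += float(np.sqrt(np.mean((sim - targets.nutlin[moiety].to_numpy()) ** 2)))
        d_nut /= 2.0
        s_nut = float(np.exp(-d_nut))

        rest = pre_equilibrate(params, network)
        from .simulate import Trajectory

        snap = Trajectory(np.array([0.0]), rest[None, :], network)
        tot = {m: float(total_protein(snap, m)[0]) for m in ("p53", "Mdm2", "MdmX")}
        if tot["p53"] <= 0 or tot["Mdm2"] <= 0:
            return {"score": 0.0, "failed": "zero resting total protein"}
        d_rat = 0.5 * (
            abs(np.log(tot["Mdm2"] / tot["p53"] / targets.ratios["mdm2_p53"]))
            + abs(np.log(tot["MdmX"] / tot["Mdm2"] / targets.ratios["mdmx_mdm2"]))
        )
        s_rat = float(np.exp(-d_rat))
    except (SimulationError, ValueError) as exc:
        return {"score": 0.0, "failed": str(exc)}

    w = np.asarray(weights, float)
    score = float(np.array([s_osc, s_nut, s_rat]) @ w / w.sum())
    return {"score": score, "failed": None, "oscillation": s_osc,
            "nutlin": s_nut, "ratios": s_rat, "xcorr": osc["score"],
            "floor_ok": osc["floor_ok"]}


@dataclass(frozen=True)
class SearchConfig:
    """Radius-growing neighbour-search settings."""

    stage: int = 1
    free_symbols: tuple[str, ...] | None = None
    r_init: float = 0.1       # decades
    r_growth: float = 2.0
    r_max: float = 2.0
    stagnation: int = 200     # evaluations without improvement before R grows
    max_evals: int = 2000
    threshold: float | None = None  # stop when best score >= threshold
    seed: int = 0

    def symbols(self) -> tuple[str, ...]:
        if self.free_symbols is not None:
            return self.free_symbols
        return STAGE1_FREE if self.stage == 1 else STAGE2_FREE


@dataclass
class SearchRecord:
    """Evaluated candidates, best-so-far trace and provenance."""

    history: pd.DataFrame
    best_params: ParameterSet
    best_score: float
    config: SearchConfig
    origin: str = ""
    reached_threshold: bool = False

    @property
    def n_evals(self) -> int:
        return len(self.history)


def neighbor_search(
    objective: Callable[[ParameterSet], float],
    center: ParameterSet,
    config: SearchConfig,
    origin: str = "",
) -> SearchRecord:
    """Radius-growing random neighbour search in log10 parameter space.

    Free symbols are perturbed uniformly within R decades of the
    current centre; the tied constants are re-derived for every
    candidate via the stage's constraint map.  The centre moves to any
    candidate with a strictly better score; R doubles after
    ``config.stagnation`` evaluations without improvement, up to
    ``config.r_max`` decades.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    symbols = config.symbols()
    centre = apply_search_constraints(config.stage, center)
    base = np.array([centre[s] for s in symbols])
    if np.any(base <= 0):
        raise ValueError(
            f"free symbols must be positive at the search centre: "
            f"{[s for s, v in zip(symbols, base) if v <= 0]}")
    log_c = np.log10(base)

    def build(logs: np.ndarray) -> ParameterSet:
        cand = centre.with_rates(**{s: 10.0 ** v for s, v in zip(symbols, logs)})
        return apply_search_constraints(config.stage, cand)

    best_score = objective(build(log_c))
    best_logs = log_c.copy()
    rows = [{"eval": 0, "score": best_score, "best": best_score, "radius": 0.0,
             "moved": True, **{s: 10.0 ** v for s, v in zip(symbols, log_c)}}]
    R = config.r_init
    since_improve = 0
    reached = config.threshold is not None and best_score >= config.threshold
    n = 1
    while n < config.max_evals and not reached:
        logs = best_logs + R * rng.uniform(-1.0, 1.0, size=len(symbols))
        score = objective(build(logs))
        moved = score > best_score
        if moved:
            best_score, best_logs = score, logs
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.stagnation:
                R = min(R * config.r_growth, config.r_max)
                since_improve = 0
        rows.append({"eval": n, "score": score, "best": best_score, "radius": R,
                     "moved": moved, **{s: 10.0 ** v for s, v in zip(symbols, logs)}})
        reached = config.threshold is not None and best_score >= config.threshold
        n += 1
    return SearchRecord(pd.DataFrame(rows), build(best_logs), best_score,
                        config, origin, reached)


def pca_map(history: pd.DataFrame, symbols: tuple[str, ...],
            n_bins: int = 9) -> pd.DataFrame:
    """2-D principal-component map of evaluated parameter sets.

    Parameters are log10-transformed and standardised before the
    projection; scores are binned into ``n_bins`` equal-width levels
    over the observed range.  Constant parameter columns are dropped
    with a warning.
    """
    import warnings

    from sklearn.decomposition import PCA

    if len(history) < 3:
        raise ValueError("need at least 3 parameter sets for a PCA map")
    X = np.log10(history.loc[:, list(symbols)].to_numpy(float))
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [s for s, k in zip(symbols, keep) if not k]
        warnings.warn(f"dropping constant parameter columns: {dropped}")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if X.shape[1] == 0:
        coords = np.zeros((len(history), 2))
    else:
        coords = PCA(n_components=min(2, X.shape[1])).fit_transform(X)
        if coords.shape[1] == 1:
            coords = np.column_stack([coords, np.zeros(len(coords))])
    out = pd.DataFrame({"pc1": coords[:, 0], "pc2": coords[:, 1],
                        "score": history["score"].to_numpy()})
    lo, hi = out["score"].min(), out["score"].max()
    if hi > lo:
        out["level"] = np.minimum((out["score"] - lo) / (hi - lo) * n_bins,
                                  n_bins - 1).astype(int)
    else:
        out["level"] = 0
    return out
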