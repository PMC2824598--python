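"""Named reproduction recipes tying the modules together.

Each recipe runs one of the study's figure/table computations on its
published parameter column and returns a dict of tidy DataFrames; .
:func:`run_recipe` additionally writes them as TSV files together with
a JSON manifest (seed, versions, tolerances, runtime) sufficient to
re-run the computation bit-identically.

Grid sizes are scaled to single-workstation runtimes (minutes, one
core); every scan axis is explicit below, so denser grids are a matter
of passing overrides.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    classify_effect,
    delta_A,
    delta_M,
    detect_peaks,
    early_activity,
    late_window_max,
    reservoir_log_ratio,
    total_protein,
)
from .network import build_network, reaction_table
from .parameters import load_parameter_set
from .simulate import (
    DamageProtocol,
    PulseSchedule,
    run_damage,
    run_delay,
    run_nutlin,
    run_pulse,
)

__all__ = ["RECIPES", "run_recipe"]


def _fig3(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Early-response time courses over Mdm2/MdmX production rates."""
    net = build_network("simple")
    base = load_parameter_set("col4")
    proto = DamageProtocol(phospho_rate=kw.get("phospho_rate", 0.1), t_end=55.0,
                           pre_equilibrate=True, feedback_off=True)
    rows = []
    for k6 in kw.get("k6_values", (1e-3, 5e-2, 1.0)):
        for k15 in kw.get("k15_values", (0.0, 0.05, 5.0)):
            traj = run_damage(base.with_rates(k6=k6, k15=k15), proto, net)
            rows.append(pd.DataFrame({"time": traj.times, "x14": traj.series(14),
                                      "k6": k6, "k15": k15}))
    return {"timeseries": pd.concat(rows, ignore_index=True)}


def _fig4(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Early p53 activity vs damage level and vs Mdm2 production."""
    net = build_network("simple")
    base = load_parameter_set("col4")
    k15s = kw.get("k15_values", (0.0, 0.05, 5.0))
    phos = kw.get("phospho_grid", np.logspace(-3, 0, 12))
    k6s = kw.get("k6_grid", np.logspace(-3, 0.7, 12))
    rows = []
    for k15 in k15s:
        for ph in phos:
            proto = DamageProtocol(phospho_rate=float(ph), t_end=60.0,
                                   pre_equilibrate=True, feedback_off=True)
            for k6 in kw.get("k6_values", (1e-3, 5e-2, 1.0)):
                traj = run_damage(base.with_rates(k6=float(k6), k15=k15), proto, net)
                rows.append({"k15": k15, "phospho": float(ph), "k6": float(k6),
                             "activity": early_activity(traj)})
        for k6 in k6s:
            proto = DamageProtocol(phospho_rate=kw.get("phospho_rate", 0.1),
                                   t_end=60.0, pre_equilibrate=True,
                                   feedback_off=True)
            traj = run_damage(base.with_rates(k6=float(k6), k15=k15), proto, net)
            rows.append({"k15": k15, "phospho": kw.get("phospho_rate", 0.1),
                         "k6": float(k6), "activity": early_activity(traj)})
    return {"activity": pd.DataFrame(rows)}


def _fig5(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Switch measure (early activity with minus without MdmX) over the
    heterodimer association constants."""
    base = load_parameter_set("col4")
    k15 = kw.get("k15", 5.0)
    phospho = kw.get("phospho_rate", 0.1)
    rows = []
    for k6 in kw.get("k6_values", (1e-3, 1.0)):
        for k25 in kw.get("k25_grid", np.logspace(-3, 1, 7)):
            for k23 in kw.get("k23_grid", np.logspace(-3, 1, 7)):
                da = delta_A(base, k15, phospho_rate=phospho,
                             k6=float(k6), k23=float(k23), k25=float(k25))
                rows.append({"k6": k6, "k23": float(k23), "k25": float(k25),
                             "delta_A": da})
    return {"delta_A": pd.DataFrame(rows)}


def _fig6(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Late-response dampening measure over p53 production/phosphorylation."""
    base = load_parameter_set("col5")
    k15 = kw.get("k15", 10.0)
    window = kw.get("window", (50_000.0, 100_000.0))
    rows = []
    for k1 in kw.get("k1_grid", np.logspace(np.log10(0.028118), 1, 4)):
        for k3 in kw.get("k3_grid", np.logspace(-5, 1, 4)):
            dm = delta_M(base, k15, window=window, dt=kw.get("dt", 10.0),
                         k1=float(k1), k3=float(k3))
            rows.append({"k1": float(k1), "k3": float(k3), "delta_M": dm})
    return {"delta_M": pd.DataFrame(rows)}


def _fig7(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Bifurcation diagram over p53 production with Hopf classification."""
    from .bifurcation import classify_hopf, trace_branch

    net = build_network("simple")
    base = load_parameter_set("col5").with_rates(k3=kw.get("k3", 0.0086851))
    grid = kw.get("k1_grid", np.logspace(np.log10(0.028118), 1, 26))
    branches, hopfs = [], []
    for k15 in kw.get("k15_values", (0.0, 0.2, 0.6)):
        p = base.with_rates(k15=k15)
        br = trace_branch(p, net, "k1", grid)
        branches.append(pd.DataFrame({
            "k15": k15, "k1": br.grid,
            "x14": br.activity(net),
            "stable": br.stable,
            "max_real_eig": [max(e.real) for e in br.eigenvalues],
        }))
        for h in br.hopf_points:
            cl = classify_hopf(p, net, "k1", h)
            hopfs.append({"k15": k15, "k1_hopf": h,
                          "classification": cl["classification"],
                          "envelope_ratio": cl["envelope_ratio"]})
    return {"branch": pd.concat(branches, ignore_index=True),
            "hopf": pd.DataFrame(hopfs)}


def _fig9(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Full-model early response vs Mdm2 production at MdmX folds."""
    net = build_network("full")
    rows = []
    for label in kw.get("labels", ("col8", "col9")):
        base = load_parameter_set(label)
        b6 = base["k6"]
        grid = kw.get("k6_grid")
        if grid is None:
            grid = np.logspace(np.log10(b6) - 2, np.log10(b6) + 2, 15)
        for k6 in grid:
            for fold in kw.get("folds", (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)):
                p = base.with_rates(k6=float(k6), k15=base["k15"] * fold)
                traj = run_damage(p, DamageProtocol(t_end=180.0), net)
                rows.append({"set": label, "k6": float(k6), "fold": fold,
                             "early_max_mrna": early_activity(traj)})
    return {"early_response": pd.DataFrame(rows)}


def _fig10(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Late response, MdmX pulse memory effect and k15 bifurcation."""
    from .bifurcation import mdmx_bifurcation

    net = build_network("full")
    base = load_parameter_set("col8")
    out: dict[str, pd.DataFrame] = {}

    rows = []
    for fold in kw.get("folds", (0.0, 1.0, 100.0)):
        m = late_window_max(base.with_rates(k15=base["k15"] * fold), net,
                            dt=kw.get("dt", 2.0))
        rows.append({"fold": fold, "late_max_mrna": m})
    out["late_max"] = pd.DataFrame(rows)

    sched = PulseSchedule(tuple(kw.get("phases", ((2000.0, 1.0), (2000.0, 100.0),
                                                  (2000.0, 1.0)))))
    traj = run_pulse(base, sched, net, dt=kw.get("dt", 2.0))
    out["pulse"] = pd.DataFrame({"time": traj.times, "x15": traj.series(15),
                                 "total_p53": total_protein(traj, "p53")})

    br = mdmx_bifurcation(base, net,
                          k15_grid=kw.get("k15_grid"))
    out["k15_branch"] = pd.DataFrame({
        "k15": br.grid, "x15": br.activity(net, species=15),
        "stable": br.stable})
    return out


def _fig11(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Heterodimer reservoir log-ratio fields."""
    base = load_parameter_set("col4")
    phospho = kw.get("phospho_rate", 0.1)
    out = {}
    for name, k6 in (("low_mdm2", kw.get("k6_low", 1e-3)),
                     ("high_mdm2", kw.get("k6_high", 1.0))):
        field = reservoir_log_ratio(
            base.with_rates(k6=k6), phospho_rate=phospho,
            scan={"k25": kw.get("k25_grid", np.logspace(-3, 1, 7)),
                  "k23": kw.get("k23_grid", np.logspace(-3, 1, 7))})
        field["k6"] = k6
        out[name] = field
    return out


def _table2(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """MdmX-effect classification for the two fitted parameter sets."""
    net = build_network("full")
    rows, early, late = [], [], []
    for label in kw.get("labels", ("col8", "col9")):
        cl = classify_effect(load_parameter_set(label), net,
                             late_dt=kw.get("late_dt", 2.0))
        rows.append({"set": label,
                     "dependency_increase": cl.dependency_increase,
                     "dampening": cl.dampening,
                     "no_dampening": cl.no_dampening})
        cl.early_table["set"] = label
        cl.late_table["set"] = label
        early.append(cl.early_table)
        late.append(cl.late_table)
    return {"classification": pd.DataFrame(rows),
            "early_scan": pd.concat(early, ignore_index=True),
            "late_scan": pd.concat(late, ignore_index=True)}


def _s3(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Heterodimer-knockout control: late maxima vs k15 with and
    without heterodimer formation."""
    net = build_network("simple")
    base = load_parameter_set("col7")
    window = kw.get("window", (50_000.0, 100_000.0))
    dt = kw.get("dt", 10.0)
    proto = DamageProtocol(t_end=window[1], pre_equilibrate=False)
    rows = []
    for hetero, (k23, k25) in (("with", (0.1211, 0.1211)), ("without", (0.0, 0.0))):
        for k15 in kw.get("k15_values", (1e-4, 0.05, 1.0, 10.0)):
            traj = run_damage(base.with_rates(k15=k15, k23=k23, k25=k25),
                              proto, net, dt=dt)
            mask = traj.times >= window[0]
            rows.append({"heterodimers": hetero, "k15": k15,
                         "late_max": float(traj.series(14)[mask].max())})
    return {"late_max": pd.DataFrame(rows)}


def _s4(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Delayed-feedback oscillations with and without MdmX."""
    base = load_parameter_set("col6")
    proto = DamageProtocol(t_end=kw.get("t_end", 2000.0), pre_equilibrate=True)
    rows = []
    for k15 in kw.get("k15_values", (0.0, 0.1)):
        traj = run_delay(base.with_rates(k15=k15), proto, tau=kw.get("tau", 50.0))
        rows.append(pd.DataFrame({"time": traj.times, "x14": traj.series(14),
                                  "k15": k15}))
    return {"timeseries": pd.concat(rows, ignore_index=True)}


def _s5(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Nutlin fold-change responses for the fitted sets."""
    net = build_network("full")
    frames = []
    for label in kw.get("labels", ("col8", "col9")):
        folds, _ = run_nutlin(load_parameter_set(label), net,
                              t_end=kw.get("t_end", 1440.0), dt=5.0)
        f = folds.reset_index()
        f["set"] = label
        frames.append(f)
    return {"fold_change": pd.concat(frames, ignore_index=True)}


def _s7(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Local sensitivity ranking of the fitted sets."""
    from .sensitivity import local_sensitivity

    net = build_network("full")
    frames = []
    for label in kw.get("labels", ("col8", "col9")):
        tab = local_sensitivity(load_parameter_set(label), net,
                                T=kw.get("T", 180.0))
        t = tab.integrated.copy()
        t["set"] = label
        frames.append(t)
    return {"sensitivity": pd.concat(frames, ignore_index=True)}


def _period(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Sustained-oscillation period of total p53 for the fitted set."""
    net = build_network("full")
    base = load_parameter_set(kw.get("label", "col8"))
    t_end = kw.get("t_end", 10_000.0)
    traj = run_damage(base, DamageProtocol(t_end=t_end, pre_equilibrate=False),
                      net, dt=kw.get("dt", 1.0))
    tot = total_protein(traj, "p53")
    mask = traj.times >= kw.get("discard", 2000.0)
    pk = detect_peaks(traj.times[mask], tot[mask], discard_frac=0.0)
    return {"peaks": pd.DataFrame({"peak_time": pk.times, "height": pk.heights}),
            "period": pd.DataFrame([{"period_min": pk.period,
                                     "period_h": None if pk.period is None
                                     else pk.period / 60.0,
                                     "oscillating": pk.oscillating}])}


def _reactions(seed: int, **kw) -> dict[str, pd.DataFrame]:
    """Audit dump of both reaction networks."""
    return {variant: reaction_table(build_network(variant))
            for variant in ("simple", "full")}


RECIPES = {
    "fig3": _fig3,
    "fig4": _fig4,
    "fig5": _fig5,
    "fig6": _fig6,
    "fig7": _fig7,
    "fig9": _fig9,
    "fig10": _fig10,
    "fig11": _fig11,
    "table2_classify": _table2,
    "s3": _s3,
    "s4": _s4,
    "s5_nutlin": _s5,
    "s7_sensitivity": _s7,
    "period": _period,
    "reactions": _reactions,
}


def run_recipe(name: str, outdir: str | Path | None = None, seed: int = 0,
               **overrides) -> dict[str, pd.DataFrame]:
    """Run a named recipe; optionally write TSV outputs and a manifest."""
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    t0 = time.time()
    np.random.seed(seed % 2**31)  # recipes are deterministic; belt and braces
    result = RECIPES[name](seed, **overrides)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key, frame in result.items():
            frame.to_csv(out / f"{name}_{key}.tsv", sep="\t", index=False)
        import scipy

        manifest = {
            "recipe": name, "seed": seed,
            "overrides": {k: str(v) for k, v in overrides.items()},
            "package_version": __version__,
            "numpy": np.__version__, "scipy": scipy.__version__,
            "runtime_s": round(time.time() - t0, 2),
        }
        (out / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
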