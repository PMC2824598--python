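"""Synthetic calibration targets for fitness evaluation and search.

The parameter survey scores candidate models against three kinds of
experimental observations: an average p53/Mdm2 oscillation pattern
under DNA damage, total-protein fold-change curves after Nutlin
treatment, and scalar total-protein ratios.  The published originals
are figure-derived and not printed numerically, so this module
generates *synthetic stand-ins* with the field's headline features: a
pulsatile oscillation with a ~6 h (360 min) peak-to-peak interval, and
monotone saturating fold-change curves that start at 1.

The oscillation target uses raised-cosine pulses on a baseline rather
than a pure sinusoid -- damped, optionally noisy -- to resemble the
pulsatile shape of p53 dynamics in single-cell imaging.  All generators
are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TargetBundle",
    "make_oscillation_target",
    "make_nutlin_target",
    "make_ratio_target",
    "make_target_bundle",
]

#: Experimental peak-to-peak interval of damage-induced p53 pulses (min).
DEFAULT_PERIOD = 360.0


def make_oscillation_target(
    period: float = DEFAULT_PERIOD,
    n_peaks: int = 5,
    dt: float = 5.0,
    peak_width: float = 0.5,
    baseline: float = 0.1,
    amplitude: float = 1.0,
    damping: float = 0.0,
    noise_sd: float = 0.0,
    first_peak: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pulsatile oscillation series with a programmed peak spacing.

    Raised-cosine pulses of width ``peak_width * period`` centred every
    ``period`` minutes on a flat baseline; pulse height decays
    geometrically by ``damping`` per cycle; Gaussian noise with
    ``noise_sd`` (in units of the first pulse height) is added on top
    and the series is clipped at zero.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_peaks < 2:
        raise ValueError("need at least 2 peaks")
    rng = np.random.default_rng(seed)
    if first_peak is None:
        first_peak = period / 2
    t_end = first_peak + (n_peaks - 0.5) * period
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = np.full_like(t, baseline)
    half_w = peak_width * period / 2
    for i in range(n_peaks):
        centre = first_peak + i * period
        h = amplitude * (1.0 - damping) ** i
        mask = np.abs(t - centre) <= half_w
        y[mask] += h * 0.5 * (1 + np.cos(np.pi * (t[mask] - centre) / half_w))
    if noise_sd > 0:
        # correlated (smoothed) noise: fluorescence-style fluctuations,
        # not sample-to-sample jitter that would masquerade as peaks
        raw = rng.normal(0.0, noise_sd * amplitude, size=t.size)
        win = max(1, int(period / 12 / dt))
        kernel = np.ones(win) / win
        y = y + np.convolve(raw, kernel, mode="same") * np.sqrt(win)
    return pd.DataFrame({"time": t, "value": np.clip(y, 0.0, None)})


def make_nutlin_target(
    plateaus: dict[str, float] | None = None,
    rate: float = 1.0 / 240.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Monotone saturating fold-change curves after p53-Mdm2 blockade.

    Each curve is ``1 + (plateau - 1) * (1 - exp(-rate * t))``: fold
    change 1 at t = 0, rising to the plateau.  Default plateaus mimic
    the few-fold accumulation of total p53 and Mdm2 (and the weaker
    MdmX response) seen after Nutlin treatment.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if plateaus is None:
        plateaus = {"p53": 3.0, "Mdm2": 3.0, "MdmX": 1.5}
    if any(v < 1.0 for v in plateaus.values()):
        raise ValueError("fold-change plateaus must be >= 1")
    if grid is None:
        grid = np.arange(0.0, 1441.0, 10.0)
    out = {"time": grid}
    for name, plat in plateaus.items():
        out[name] = 1.0 + (plat - 1.0) * (1.0 - np.exp(-rate * grid))
    return pd.DataFrame(out)


def make_ratio_target(mdm2_p53: float = 2.0, mdmx_mdm2: float = 1.0) -> dict[str, float]:
    """Scalar resting total-protein ratios (Mdm2/p53 and MdmX/Mdm2)."""
    if mdm2_p53 <= 0 or mdmx_mdm2 <= 0:
        raise ValueError("protein ratios must be positive")
    return {"mdm2_p53": float(mdm2_p53), "mdmx_mdm2": float(mdmx_mdm2)}


@dataclass(frozen=True)
class TargetBundle:
    """The three calibration targets plus generation provenance."""

    oscillation: pd.DataFrame
    nutlin: pd.DataFrame
    ratios: dict[str, float]
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.oscillation.to_csv(d / "oscillation_target.tsv", sep="\t", index=False)
        self.nutlin.to_csv(d / "nutlin_target.tsv", sep="\t", index=False)
        manifest = {"seed": self.seed, "ratios": self.ratios, **self.meta}
        (d / "targets.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "TargetBundle":
        d = Path(directory)
        manifest = json.loads((d / "targets.json").read_text())
        return cls(
            oscillation=pd.read_csv(d / "oscillation_target.tsv", sep="\t"),
            nutlin=pd.read_csv(d / "nutlin_target.tsv", sep="\t"),
            ratios=manifest["ratios"],
            seed=manifest.get("seed", 0),
        )


def make_target_bundle(seed: int = 0, period: float = DEFAULT_PERIOD,
                       noise_sd: float = 0.0, **osc_kwargs) -> TargetBundle:
    """Assemble the default bundle used by the two-stage search."""
    return TargetBundle(
        oscillation=make_oscillation_target(period=period, noise_sd=noise_sd,
                                            seed=seed, **osc_kwargs),
        nutlin=make_nutlin_target(),
        ratios=make_ratio_target(),
        seed=seed,
        meta={"period": period, "noise_sd": noise_sd},
    )
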