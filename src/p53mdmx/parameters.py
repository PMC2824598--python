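"""Rate-constant sets for the p53-Mdm2-MdmX model.

Six published parameter columns are built in (labels ``col4`` ..
``col9``):

* ``col4`` -- initial exploratory set for the simple model (early
  damage response, heterodimer-reservoir scans).
* ``col5`` -- oscillatory simple-model set (late response, bifurcation
  diagrams over the p53 production rate k1).
* ``col6`` -- oscillatory simple-model set used with a transcription
  delay of 50 time units on the Mdm2-production reaction.
* ``col7`` -- oscillatory simple-model set for the heterodimer-knockout
  control (k23 = k25 = 0 vs 0.1211).
* ``col8`` -- full-model set fitted from the OSC1P1 search region
  (MdmX-sensitive oscillations).
* ``col9`` -- full-model set fitted from the OSC2P1 search region
  (MdmX-insensitive oscillations).

Several cells of the published table are scan ranges rather than single
numbers (the corresponding figures sweep them).  Those symbols carry a
:class:`ScanAxis` and a documented default -- the log-midpoint of the
range, or the middle element of a discrete list; every reproduction
recipe sets them explicitly.

The basal p53 production rate k1 of the full-model sets is state
dependent: 0.003 without DNA damage and 0.01 with damage (p53
translation is enhanced after damage); :class:`ParameterSet` stores both
and the simulation protocols pick the phase-appropriate value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ScanAxis",
    "ParameterSet",
    "load_parameter_set",
    "apply_search_constraints",
    "PARAMETER_LABELS",
    "ALL_SYMBOLS",
    "STAGE1_FREE",
    "STAGE2_FREE",
]

ALL_SYMBOLS = tuple(f"k{i}" for i in range(1, 39))


@dataclass(frozen=True)
class ScanAxis:
    """A symbol published as a range to be swept, with a default value."""

    lo: float
    hi: float
    n: int
    log: bool = True
    values: tuple[float, ...] | None = None  # discrete list, if printed as one

    def grid(self) -> np.ndarray:
        if self.values is not None:
            return np.asarray(self.values, float)
        if self.log:
            return np.logspace(math.log10(self.lo), math.log10(self.hi), self.n)
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def default(self) -> float:
        if self.values is not None:
            return self.values[len(self.values) // 2]
        return 10 ** ((math.log10(self.lo) + math.log10(self.hi)) / 2)


@dataclass(frozen=True)
class ParameterSet:
    """Named rate constants k1-k38 plus promoter total and damage-state k1."""

    values: Mapping[str, float]
    label: str = "custom"
    variant: str = "simple"
    promoter_total: float = 1.0
    k1_predamage: float | None = None
    k1_postdamage: float | None = None
    scan_axes: Mapping[str, ScanAxis] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = dict(self.values)
        missing = [s for s in ALL_SYMBOLS if s not in vals]
        if missing:
            raise ValueError(f"parameter set {self.label!r} missing {missing}")
        bad = [s for s, v in vals.items() if v < 0]
        if bad:
            raise ValueError(f"negative rate constants: {bad}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(ALL_SYMBOLS)

    def with_rates(self, **updates: float) -> "ParameterSet":
        """Copy with some rate constants replaced (``k6=1e-4`` style)."""
        unknown = [s for s in updates if s not in self.values]
        if unknown:
            raise KeyError(f"unknown rate symbols: {unknown}")
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)

    def for_phase(self, damage: bool) -> "ParameterSet":
        """Resolve the state-dependent basal p53 production rate k1."""
        k1 = self.k1_postdamage if damage else self.k1_predamage
        if k1 is None:
            return self
        return self.with_rates(k1=k1)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[s] for s in ALL_SYMBOLS])


def _log_axis(lo: float, hi: float, n: int) -> ScanAxis:
    return ScanAxis(lo, hi, n)


# Scan ranges printed as table footnotes.
_AX_K1_COL5 = _log_axis(0.028118, 10.0, 26)
_AX_PHOS_COL4 = _log_axis(1e-3, 1.0, 50)
_AX_K3_COL5 = _log_axis(1e-5, 10.0, 50)
_AX_K6_COL4 = _log_axis(1e-3, 10**0.7, 40)
_AX_K15_COL4 = ScanAxis(0.0, 5.0, 3, values=(0.0, 0.05, 5.0))
_AX_K15_COL7 = ScanAxis(
    1e-4, 20.0, 15,
    values=(0.0001, 0.001, 0.005, 0.01, 0.02, 0.05, 0.075, 0.1,
            0.5, 1.0, 2.0, 8.0, 10.0, 12.0, 20.0),
)
_AX_BIND_COL7 = _log_axis(1e-5, 20.0, 10)

# Published columns.  Order: k1..k38; "R" marks a scan axis (value =
# axis default), and rows printed NA contribute 0.
_COLUMNS: dict[str, dict] = {
    "col4": dict(
        variant="simple",
        axes={"k3": _AX_PHOS_COL4, "k8": _AX_PHOS_COL4, "k17": _AX_PHOS_COL4,
              "k6": _AX_K6_COL4, "k15": _AX_K15_COL4},
        k=dict(
            k1=5.000e-2, k2=2.100e-2, k4=2.000e-2, k5=1.700e-3,
            k7=5.000e-3, k9=2.000e-2, k10=2.198e1, k11=1.000e-1,
            k12=5.000e-2, k13=5.000e0, k14=0.0, k16=5.000e-3,
            k18=2.000e-2, k19=5.000e-3, k20=1.100e1, k21=3.640e-5,
            k22=7.319e0, k23=1.000e-1, k24=5.000e-2, k25=1.000e-1,
            k26=5.000e-2, k27=8.090e-1, k28=6.110e-2, k29=8.090e-1,
            k30=6.110e-2, k31=8.090e-1, k32=6.110e-2, k33=0.0,
        ),
    ),
    "col5": dict(
        variant="simple",
        axes={"k1": _AX_K1_COL5, "k3": _AX_K3_COL5},
        k=dict(
            k2=8.000e-4, k4=2.365e-2, k5=2.000e-3, k6=1.500e-3,
            k7=5.000e-4, k8=2.000e-1, k9=2.000e-2, k10=5.000e-5,
            k11=1.000e0, k12=1.750e-2, k13=2.500e0, k14=1.000e-1,
            k15=0.0, k16=3.425e-2, k17=2.000e-2, k18=2.000e-2,
            k19=3.425e-2, k20=4.150e-3, k21=8.000e-4, k22=4.825e-2,
            k23=2.500e-1, k24=3.500e-1, k25=1.211e-1, k26=1.830e-2,
            k27=5.000e-4, k28=5.000e-4, k29=2.500e-5, k30=5.000e-4,
            k31=2.500e-5, k32=5.000e-4, k33=1.000e-1,
        ),
    ),
    "col6": dict(
        variant="simple",
        axes={},
        k=dict(
            k1=1.000e-1, k2=4.400e-3, k3=1.000e0, k4=2.500e-1,
            k5=4.400e-3, k6=3.000e-3, k7=2.190e-2, k8=1.000e0,
            k9=2.500e-1, k10=8.000e0, k11=1.000e0, k12=1.000e-1,
            k13=5.000e0, k14=0.0, k15=1.000e0, k16=6.850e-2,
            k17=1.000e0, k18=2.500e-1, k19=6.850e-2, k20=2.000e0,
            k21=2.000e-3, k22=2.000e0, k23=9.372e-1, k24=2.130e-2,
            k25=3.925e-1, k26=5.000e-2, k27=1.000e0, k28=5.000e-1,
            k29=1.000e0, k30=5.000e-1, k31=1.000e0, k32=5.000e-1,
            k33=4.000e1,
        ),
    ),
    "col7": dict(
        variant="simple",
        axes={"k15": _AX_K15_COL7, "k23": _AX_BIND_COL7, "k25": _AX_BIND_COL7},
        k=dict(
            k1=5.000e-1, k2=8.000e-4, k3=1.000e-1, k4=2.365e-2,
            k5=2.000e-3, k6=1.500e-3, k7=5.000e-4, k8=2.000e-1,
            k9=2.000e-2, k10=5.000e-5, k11=5.000e-1, k12=1.750e-2,
            k13=1.000e0, k14=1.000e-1, k16=3.425e-2, k17=2.000e-2,
            k18=2.000e-2, k19=3.425e-2, k20=4.150e-3, k21=8.000e-4,
            k22=4.825e-2, k23=1.211e-1, k24=1.830e-2, k25=1.211e-1,
            k26=1.830e-2, k27=5.000e-4, k28=5.000e-4, k29=2.500e-5,
            k30=5.000e-4, k31=2.500e-5, k32=5.000e-4, k33=5.000e-1,
        ),
    ),
    "col8": dict(
        variant="full",
        axes={},
        k1_pre=0.003, k1_post=0.01,
        k=dict(
            k1=0.003, k2=3.923e-3, k3=1.578e-2, k4=3.156e-4,
            k5=1.224e-2, k6=7.994e-5, k7=7.592e-5, k8=1.578e-2,
            k9=3.156e-4, k10=1.826e-1, k11=3.056e1, k12=1.608e-1,
            k13=7.917e-1, k14=1.583e-1, k15=2.173e-5, k16=3.155e-4,
            k17=1.578e-2, k18=3.156e-4, k19=1.224e-3, k20=3.056e1,
            k21=1.608e-1, k22=7.917e-1, k23=3.427e2, k24=1.608e-1,
            k25=2.596e-1, k26=1.608e-1, k27=4.206e-1, k28=7.918e-1,
            k29=1.543e0, k30=1.016e-1, k31=4.715e-1, k32=2.555e-1,
            k33=7.170e-1, k37=5.551e-2, k38=3.708e0,
            k34=6.293e-3, k35=2.794e0, k36=6.545e-2,
        ),
    ),
    "col9": dict(
        variant="full",
        axes={},
        k1_pre=0.003, k1_post=0.01,
        k=dict(
            k1=0.003, k2=3.710e-3, k3=1.048e1, k4=2.095e-1,
            k5=1.542e-3, k6=6.528e-4, k7=1.275e-2, k8=1.048e1,
            k9=2.095e-1, k10=2.436e-2, k11=2.760e0, k12=4.284e-1,
            k13=9.259e0, k14=1.852e0, k15=8.436e-5, k16=1.373e-4,
            k17=1.048e1, k18=2.095e-1, k19=1.542e-4, k20=2.760e0,
            k21=4.284e-1, k22=9.259e0, k23=7.356e0, k24=4.284e-1,
            k25=1.022e1, k26=4.284e-1, k27=2.535e-3, k28=5.194e-2,
            k29=5.275e-2, k30=3.103e-1, k31=1.626e0, k32=3.059e-1,
            k33=1.801e0, k37=3.813e-2, k38=1.456e2,
            k34=4.015e-2, k35=1.117e2, k36=9.043e-2,
        ),
    ),
}

PARAMETER_LABELS = tuple(_COLUMNS)

# Constraint-tied and free symbols of the two-stage parameter survey.
STAGE1_FREE = ("k2", "k3", "k10", "k11", "k12", "k13", "k27", "k28",
               "k29", "k30", "k31", "k32", "k33", "k37", "k38")
STAGE2_FREE = ("k2", "k3", "k6", "k7", "k15", "k16", "k23", "k25",
               "k34", "k36", "k38")


def load_parameter_set(label: str) -> ParameterSet:
    """Load one of the published parameter columns (``col4`` .. ``col9``).

    Scan-range cells are populated with their documented default and
    recorded in :attr:`ParameterSet.scan_axes`; rows not present in the
    column's network variant are 0.
    """
    if label not in _COLUMNS:
        raise KeyError(f"unknown parameter set {label!r}; available: {PARAMETER_LABELS}")
    col = _COLUMNS[label]
    vals = {s: 0.0 for s in ALL_SYMBOLS}
    vals.update(col["k"])
    axes = dict(col["axes"])
    for sym, ax in axes.items():
        if sym not in col["k"]:
            vals[sym] = ax.default
    return ParameterSet(
        values=vals,
        label=label,
        variant=col["variant"],
        k1_predamage=col.get("k1_pre"),
        k1_postdamage=col.get("k1_post"),
        scan_axes=axes,
    )


def apply_search_constraints(stage: int, base: ParameterSet) -> ParameterSet:
    """Tie constrained rate constants to the free ones for a search stage.

    Stage 1 (oscillation search): k7 = k5 = k2, k14 = 0.2*k13, k8 = k3,
    k9 = k4 = 0.02*k3.  Stage 2 (Nutlin/ratio refinement): k10 = k17 =
    k3, k4 = k9 = k18 = 0.02*k3.
    """
    v = base.values
    if stage == 1:
        return base.with_rates(
            k5=v["k2"], k7=v["k2"], k14=0.2 * v["k13"],
            k8=v["k3"], k4=0.02 * v["k3"], k9=0.02 * v["k3"],
        )
    if stage == 2:
        return base.with_rates(
            k10=v["k3"], k17=v["k3"],
            k4=0.02 * v["k3"], k9=0.02 * v["k3"], k18=0.02 * v["k3"],
        )
    raise ValueError(f"unknown search stage {stage!r}")
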