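"""Replicate-level kinetics: occupancies, dwell times, cycle times, and
concentration-scaled cycle thresholds.

A factor at stationarity alternates between a ribosome-bound and a free
state; its cycle time (one bound + free period) is

    T_cycle = tau_bound / occ_bound = tau_bound + tau_free,

since occ_bound = tau_bound / (tau_bound + tau_free). If each factor molecule
made exactly one productive binding per translation cycle, its cycle time
would equal its concentration relative to ribosomes times the ribosome
translation-cycle time; a measured factor cycle time below that threshold
implies more than one ribosome binding per translation cycle.

Per-experiment coarse models are aggregated with means and between-experiment
standard deviations, and conditions are compared with a two-sided unpaired
t-test (Student by default, Welch optional).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .coarse import CoarseModel

__all__ = [
    "KineticsSummary",
    "ThresholdInputs",
    "TTestResult",
    "cycle_time",
    "cycle_threshold",
    "aggregate",
    "compare",
    "flag_multiple_bindings",
    "significance_stars",
]


def cycle_time(occ_bound: float, dwell_bound: float) -> float:
    """Average factor cycle time tau_bound / occ_bound, in seconds.

    Equivalent to the sum of bound and free dwell times at stationarity.
    occ_bound = 0 (or NaN inputs) gives NaN with a warning.
    """
    if not np.isfinite(occ_bound) or not np.isfinite(dwell_bound) or occ_bound <= 0:
        warnings.warn("cycle_time undefined: zero/invalid bound occupancy")
        return np.nan
    if occ_bound > 1:
        raise ValueError("occ_bound must be <= 1")
    if dwell_bound <= 0:
        raise ValueError("dwell_bound must be > 0")
    return dwell_bound / occ_bound


@dataclass(frozen=True)
class ThresholdInputs:
    """Inputs to the cycle-time threshold: the factor's concentration relative
    to ribosomes (dimensionless, in (0, 1]) and the ribosome translation-cycle
    time window in seconds (lower bound used, conservative flagging)."""

    concentration_ratio: float
    ribosome_cycle_bounds: tuple[float, float] = (10.0, 17.0)

    def __post_init__(self) -> None:
        if not 0 < self.concentration_ratio <= 1:
            raise ValueError("concentration_ratio must be in (0, 1]")
        lo, hi = self.ribosome_cycle_bounds
        if not 0 < lo <= hi:
            raise ValueError("ribosome cycle bounds must be ordered and positive")


def cycle_threshold(inputs: ThresholdInputs) -> float:
    """Concentration-scaled cycle-time threshold in seconds: ratio times the
    lower bound of the ribosome translation-cycle window. A measured factor
    cycle time below this implies >1 ribosome binding per translation cycle."""
    return inputs.concentration_ratio * inputs.ribosome_cycle_bounds[0]


def flag_multiple_bindings(measured_cycle: float, inputs: ThresholdInputs) -> bool:
    """True iff the measured cycle time is below the concentration-scaled
    threshold, i.e. the factor binds ribosomes more than once per cycle."""
    return bool(measured_cycle < cycle_threshold(inputs))


@dataclass
class KineticsSummary:
    """Per-experiment and pooled occupancies/dwells for one condition.

    ``per_experiment`` maps quantity name (e.g. "occ_bound", "dwell_bound")
    to the vector of per-experiment values; ``mean``/``sd`` are across
    experiments (sample SD, ddof=1; NaN with a flag for one experiment).
    ``cycle`` is computed from the pooled mean occupancy and dwell.
    """

    condition: str
    labels: tuple[str, ...]
    per_experiment: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    cycle: float
    n_experiments: int
    n_cells: int | None = None
    n_steps: int | None = None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "labels": list(self.labels),
            "per_experiment": {k: list(v) for k, v in self.per_experiment.items()},
            "mean": self.mean,
            "sd": {k: (None if np.isnan(v) else v) for k, v in self.sd.items()},
            "cycle_s": None if np.isnan(self.cycle) else self.cycle,
            "n_experiments": self.n_experiments,
            "n_cells": self.n_cells,
            "n_steps": self.n_steps,
            "flags": list(self.flags),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)


def aggregate(
    experiments: list[CoarseModel],
    condition: str = "",
    *,
    bound_label: str = "bound",
    n_cells: int | None = None,
    n_steps: int | None = None,
) -> KineticsSummary:
    """Aggregate per-experiment coarse models into means and SDs across
    experiments; the cycle time uses the pooled mean bound occupancy and
    dwell (not per-experiment cycles averaged)."""
    if not experiments:
        raise ValueError("need at least one experiment")
    labels = experiments[0].labels
    if any(e.labels != labels for e in experiments):
        raise ValueError("experiments have inconsistent class labels")

    per: dict[str, np.ndarray] = {}
    for g, lab in enumerate(labels):
        per[f"occ_{lab}"] = np.array([e.occ[g] for e in experiments])
        per[f"dwell_{lab}"] = np.array([e.dwell[g] for e in experiments])

    flags = []
    n_exp = len(experiments)
    if n_exp < 2:
        flags.append("single experiment: SD undefined")
    mean = {k: float(np.mean(v)) for k, v in per.items()}
    sd = {
        k: (float(np.std(v, ddof=1)) if n_exp >= 2 else np.nan)
        for k, v in per.items()
    }

    occ_key, dwell_key = f"occ_{bound_label}", f"dwell_{bound_label}"
    if occ_key in mean and mean[occ_key] > 0 and np.isfinite(mean[dwell_key]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cyc = cycle_time(mean[occ_key], mean[dwell_key])
    else:
        cyc = np.nan
        flags.append(f"cycle undefined: no occupancy in class {bound_label!r}")
    return KineticsSummary(
        condition=condition,
        labels=labels,
        per_experiment=per,
        mean=mean,
        sd=sd,
        cycle=cyc,
        n_experiments=n_exp,
        n_cells=n_cells,
        n_steps=n_steps,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    stars: str
    quantity: str = ""

    def as_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "stars": self.stars, "quantity": self.quantity,
        }


def significance_stars(p: float) -> str:
    """Star coding: P<0.05 (*), P<0.01 (**), P<0.001 (***), else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare(
    a: "KineticsSummary | np.ndarray",
    b: "KineticsSummary | np.ndarray",
    quantity: str = "",
    *,
    welch: bool = False,
) -> TTestResult:
    """Two-sided unpaired t-test on per-experiment values of ``quantity``
    (e.g. "occ_bound"). Student's equal-variance test by default; Welch via
    ``welch=True``. Arrays may be passed directly in place of summaries."""
    xa = a.per_experiment[quantity] if isinstance(a, KineticsSummary) else np.asarray(a, float)
    xb = b.per_experiment[quantity] if isinstance(b, KineticsSummary) else np.asarray(b, float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 experiments per group for a t-test")
    if np.var(xa) == 0 and np.var(xb) == 0:
        # degenerate: no within-group variance
        df = float(len(xa) + len(xb) - 2)
        if np.mean(xa) == np.mean(xb):
            return TTestResult(t=0.0, df=df, p=1.0, stars="ns", quantity=quantity)
        t = np.inf if np.mean(xa) > np.mean(xb) else -np.inf
        return TTestResult(t=t, df=df, p=0.0, stars="***", quantity=quantity)
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)), quantity=quantity,
    )
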