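"""Threshold-based coarse-graining of a fitted diffusional HMM.

Fitted states are lumped into labeled classes by diffusion-coefficient
thresholds (e.g. 1 µm²/s separating ribosome-bound from free factors and
8 µm²/s separating free factors from fast cleavage products). Class
occupancy is the summed stationary occupancy of member states; inter-class
fluxes are stationary per-second transition rates; and the mean dwell time of
a class is its occupancy divided by its total outflux — i.e. the flux-based
dwell, which (unlike a segment-duration average over observed binding events)
is unbiased even when dwells exceed typical trajectory lengths.

A state whose D falls exactly on a threshold is assigned to the slower class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .hmm import DiffusionModel

__all__ = ["CoarseModel", "coarse_grain", "subcluster_split", "segment_dwell_estimate"]

#: Diffusion thresholds (µm²/s) separating bound / free / cleavage artifact.
DEFAULT_THRESHOLDS = (1.0, 8.0)
#: Finer split including the mRNA-engaged sub-state boundary at 0.25 µm²/s.
SUBCLUSTER_THRESHOLDS = (0.05, 0.25, 1.0, 8.0)


@dataclass
class CoarseModel:
    """Lumped Markov model over labeled diffusion classes.

    ``occ`` sums member-state stationary occupancies; ``flux[g, h]`` is the
    stationary g->h transition flux in events per second per molecule;
    ``dwell[g]`` = occ[g] / total outflux of g, in seconds (NaN and flagged in
    ``undefined`` for empty classes).
    """

    labels: tuple[str, ...]
    intervals: tuple[tuple[float, float], ...]  # (lo, hi] in µm²/s
    membership: np.ndarray  # state index -> class index
    occ: np.ndarray
    dwell: np.ndarray
    flux: np.ndarray
    frame_interval: float
    source_K: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "intervals_um2_per_s": [list(iv) for iv in self.intervals],
            "membership": self.membership.tolist(),
            "occupancy": self.occ.tolist(),
            "dwell_s": [None if np.isnan(d) else d for d in self.dwell],
            "flux_per_s": self.flux.tolist(),
            "frame_interval_s": self.frame_interval,
            "source_K": self.source_K,
            "undefined": list(self.undefined),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CoarseModel":
        return cls(
            labels=tuple(d["labels"]),
            intervals=tuple(tuple(iv) for iv in d["intervals_um2_per_s"]),
            membership=np.array(d["membership"], dtype=int),
            occ=np.array(d["occupancy"]),
            dwell=np.array(
                [np.nan if v is None else v for v in d["dwell_s"]], dtype=float
            ),
            flux=np.array(d["flux_per_s"]),
            frame_interval=d["frame_interval_s"],
            source_K=d["source_K"],
            undefined=tuple(d.get("undefined", ())),
        )

    @classmethod
    def load(cls, path) -> "CoarseModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __getitem__(self, label: str) -> dict:
        g = self.labels.index(label)
        return {
            "occ": float(self.occ[g]),
            "dwell": float(self.dwell[g]),
            "outflux": float(self.flux[g].sum()),
        }


def classify_states(D, thresholds) -> np.ndarray:
    """Class index per state: number of thresholds strictly below D (a state
    exactly at a threshold goes to the slower class)."""
    D = np.asarray(D, dtype=float)
    th = np.asarray(thresholds, dtype=float)
    return (D[:, None] > th[None, :]).sum(axis=1)


def default_labels(n_classes: int) -> tuple[str, ...]:
    if n_classes == 2:
        return ("bound", "free")
    if n_classes == 3:
        return ("bound", "free", "artifact")
    return tuple(f"class{i}" for i in range(n_classes))


def coarse_grain(
    model: DiffusionModel,
    thresholds=DEFAULT_THRESHOLDS,
    labels: tuple[str, ...] | None = None,
) -> CoarseModel:
    """Lump the fitted states into len(thresholds)+1 classes by D.

    Class occupancy: sum of member pi_i. Class-to-class flux (g != h):
    sum_{i in g, j in h} pi_i A_ij / Δt. Mean dwell of class g:
    occ_g / sum_{h != g} flux_{g->h}; a class with zero occupancy or zero
    outflux has dwell NaN and is listed in ``undefined``.
    """
    th = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be strictly increasing")
    n_classes = len(th) + 1
    if labels is None:
        labels = default_labels(n_classes)
    labels = tuple(labels)
    if len(labels) != n_classes:
        raise ValueError(
            f"need {n_classes} labels for {len(th)} thresholds, got {len(labels)}"
        )
    member = classify_states(model.D, th)
    occ = np.zeros(n_classes)
    np.add.at(occ, member, model.pi)

    # stationary flux matrix in events / s / molecule
    flux = np.zeros((n_classes, n_classes))
    PA = model.pi[:, None] * model.A / model.frame_interval
    for i in range(model.K):
        for j in range(model.K):
            g, h = member[i], member[j]
            if g != h:
                flux[g, h] += PA[i, j]

    dwell = np.full(n_classes, np.nan)
    undefined = []
    for g in range(n_classes):
        out = flux[g].sum()
        if occ[g] > 0 and out > 0:
            dwell[g] = occ[g] / out
        else:
            undefined.append(labels[g])

    bounds = (0.0,) + th + (np.inf,)
    intervals = tuple((bounds[i], bounds[i + 1]) for i in range(n_classes))
    return CoarseModel(
        labels=labels,
        intervals=intervals,
        membership=member,
        occ=occ,
        dwell=dwell,
        flux=flux,
        frame_interval=model.frame_interval,
        source_K=model.K,
        undefined=tuple(undefined),
    )


def subcluster_split(
    model: DiffusionModel,
    thresholds=SUBCLUSTER_THRESHOLDS,
    labels: tuple[str, ...] | None = None,
) -> CoarseModel:
    """Finer coarse-graining resolving bound sub-states, by default at
    (0.05, 0.25, 1, 8) µm²/s: very-slow / mRNA-engaged 30S-bound / 30S-bound /
    free / artifact."""
    n = len(thresholds) + 1
    if labels is None:
        if n == 5:
            labels = ("very_slow", "IF-30S-mRNA", "IF-30S", "free", "artifact")
        else:
            labels = default_labels(n)
    return coarse_grain(model, thresholds, labels)


def segment_dwell_estimate(
    state_seq_list: list[np.ndarray],
    member: np.ndarray,
    class_idx: int,
    frame_interval: float,
) -> float:
    """Naive segment-duration dwell estimator, for comparison only.

    Averages the observed durations of complete within-trajectory visits to
    the class (visits truncated by the start or end of a trajectory are
    discarded). Biased low whenever true dwells are comparable to or longer
    than trajectory durations, since long visits are preferentially truncated;
    the flux-based estimator in :func:`coarse_grain` does not share this bias.
    """
    durations = []
    for seq in state_seq_list:
        cls = member[np.asarray(seq, dtype=int)]
        inside = cls == class_idx
        if not inside.any():
            continue
        # complete visits: bounded by a frame outside the class on both sides
        changes = np.flatnonzero(np.diff(inside.astype(int)))
        starts = [c + 1 for c in changes if inside[c + 1]]
        ends = [c + 1 for c in changes if not inside[c + 1]]
        for s in starts:
            nxt = [e for e in ends if e > s]
            if nxt:
                durations.append(nxt[0] - s)
    if not durations:
        return np.nan
    return float(np.mean(durations) * frame_interval)
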