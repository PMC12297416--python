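"""Normalized-cell-coordinate mapping and spatial occupancy heatmaps.

Localizations are mapped into the frame of their cell: rotate by minus the
cell orientation about the cell center, then scale so that the long axis runs
u in [-1, 1] and the short axis v in [-1, 1]. Class-resolved occupancy maps
are 2D histograms over (u, v) in which each localization is weighted by its
posterior probability of belonging to the selected diffusion class (soft
assignment), normalized to total mass 1. Points falling farther than 1 + eps
outside the outline (localization error) are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coarse import classify_states
from .hmm import DiffusionModel, Posterior
from .trajectory_io import CellGeometry, Dataset, Localization

logger = logging.getLogger("spt.spatial")

__all__ = [
    "NormalizedPoint",
    "normalize_position",
    "normalize_dataset",
    "occupancy_heatmap",
    "heatmap_from_points",
]

#: Tolerance for localization error placing points slightly outside the cell.
EDGE_TOLERANCE = 0.05
DEFAULT_BINS = (50, 25)  # (u, v)


@dataclass(frozen=True)
class NormalizedPoint:
    """A localization in normalized cell coordinates with a class weight."""

    u: float
    v: float
    label: str = ""
    weight: float = 1.0


def normalize_position(
    p: Localization, cell: CellGeometry, eps: float = EDGE_TOLERANCE
) -> NormalizedPoint | None:
    """Map one localization into (u, v); None when outside 1 + eps."""
    u, v = _normalize_xy(
        np.array([[p.x, p.y]]), cell
    )
    if abs(u[0]) > 1 + eps or abs(v[0]) > 1 + eps:
        return None
    return NormalizedPoint(u=float(u[0]), v=float(v[0]))


def _normalize_xy(xy: np.ndarray, cell: CellGeometry) -> tuple[np.ndarray, np.ndarray]:
    th = cell.orientation
    R = np.array([[np.cos(-th), -np.sin(-th)], [np.sin(-th), np.cos(-th)]])
    rel = (xy - np.asarray(cell.center)) @ R.T
    return 2.0 * rel[:, 0] / cell.length, 2.0 * rel[:, 1] / cell.width


def normalize_dataset(
    ds: Dataset, eps: float = EDGE_TOLERANCE
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalize every localization of the dataset.

    Returns (u, v, keep_mask, traj_index) over all localizations in dataset
    order, where keep_mask marks points inside the 1 + eps outline and
    traj_index maps each localization to its trajectory's position in
    ``ds.trajectories``.
    """
    cells = ds.cell_map()
    us, vs, idx = [], [], []
    for m, tr in enumerate(ds.trajectories):
        cell = cells[tr.cell_id]
        u, v = _normalize_xy(tr.xy, cell)
        us.append(u)
        vs.append(v)
        idx.append(np.full(len(u), m))
    u = np.concatenate(us)
    v = np.concatenate(vs)
    keep = (np.abs(u) <= 1 + eps) & (np.abs(v) <= 1 + eps)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("normalize_dataset: excluded %d / %d points outside the "
                    "cell outline", n_excluded, len(u))
    return u, v, keep, np.concatenate(idx)


def heatmap_from_points(
    u: np.ndarray,
    v: np.ndarray,
    weights: np.ndarray | None = None,
    bins: tuple[int, int] = DEFAULT_BINS,
    fold: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Weighted 2D histogram over (u, v) in [-1, 1]², normalized to sum 1.

    Returned grid has shape (bins_v, bins_u): rows are v-bins, columns u-bins.
    ``fold=True`` averages the four quadrants (mirror symmetry along both
    axes) back onto the full grid. ``normalize=False`` returns raw weighted
    counts, under which maps of nested classes are bin-wise additive.
    """
    H, _, _ = np.histogram2d(
        v, u, bins=(bins[1], bins[0]), range=[[-1, 1], [-1, 1]], weights=weights
    )
    total = H.sum()
    if normalize:
        if total == 0:
            raise ValueError("empty selection: no mass in the heatmap")
        H = H / total
    if fold:
        H = (H + H[::-1, :] + H[:, ::-1] + H[::-1, ::-1]) / 4.0
    return H


def occupancy_heatmap(
    ds: Dataset,
    model: DiffusionModel,
    post: Posterior,
    class_sel: str | int,
    thresholds=(1.0, 8.0),
    labels: tuple[str, ...] | None = None,
    bins: tuple[int, int] = DEFAULT_BINS,
    fold: bool = False,
    viterbi: bool = False,
    eps: float = EDGE_TOLERANCE,
    normalize: bool = True,
) -> np.ndarray:
    """Class-resolved spatial occupancy map.

    Each localization contributes its posterior probability of belonging to
    the selected coarse class (``viterbi=True`` hardens weights to the
    argmax state's class). ``class_sel`` is a class label (with ``labels``,
    or the defaults of the coarse module) or a class index.
    """
    from .coarse import default_labels

    member = classify_states(model.D, thresholds)
    if labels is None:
        labels = default_labels(len(thresholds) + 1)
    if isinstance(class_sel, str):
        class_idx = labels.index(class_sel)
    else:
        class_idx = int(class_sel)

    u, v, keep, tidx = normalize_dataset(ds, eps=eps)
    weights = np.empty(len(u))
    pos = 0
    for tr in ds.trajectories:
        g = post.gamma[tr.traj_id]
        if viterbi:
            w = (member[np.argmax(g, axis=1)] == class_idx).astype(float)
        else:
            w = g[:, member == class_idx].sum(axis=1)
        weights[pos : pos + len(w)] = w
        pos += len(w)
    return heatmap_from_points(
        u[keep], v[keep], weights[keep], bins=bins, fold=fold, normalize=normalize
    )


def plot_heatmap(H, ax=None, **kwargs):  # pragma: no cover - decoration
    """Render an occupancy map (untested plotting helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(H, origin="lower", extent=(-1, 1, -1, 1), aspect="auto", **kwargs)
    ax.set_xlabel("u (long axis)")
    ax.set_ylabel("v (short axis)")
    return ax
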