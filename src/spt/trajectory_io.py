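"""On-disk data model for trajectories, cell geometry, and filtering rules.

Trajectories are ordered 2D localizations (µm, image frame) with integer frame
indices; detection gaps of up to ``max_gap`` missing frames are allowed within
a trajectory. Cell geometry records spherocylinder poses used for coordinate
normalization and size-based sorting.

CSV dialects
------------
Trajectory CSV header:
    ``traj_id,cell_id,experiment_id,frame,x_um,y_um[,loc_sd_um]``
Cell CSV header:
    ``cell_id,experiment_id,center_x_um,center_y_um,orientation_rad,length_um,width_um``
UTF-8, "." decimal separator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("spt.io")

#: Largest number of consecutive missing frames tolerated inside a trajectory.
DEFAULT_MAX_GAP = 3
#: Trajectories must be strictly longer than this many localizations.
DEFAULT_MIN_LENGTH = 5

TRAJ_COLUMNS = ["traj_id", "cell_id", "experiment_id", "frame", "x_um", "y_um"]
CELL_COLUMNS = [
    "cell_id",
    "experiment_id",
    "center_x_um",
    "center_y_um",
    "orientation_rad",
    "length_um",
    "width_um",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant (frames, gaps, links)."""


@dataclass(frozen=True)
class Localization:
    """One detected position: frame index and x/y in µm.

    ``loc_sd`` is the per-point localization standard deviation (µm); when
    None, the model-level localization parameter of the HMM is used.
    """

    frame: int
    x: float
    y: float
    loc_sd: float | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame must be >= 0, got {self.frame}")
        if self.loc_sd is not None and self.loc_sd < 0:
            raise ValidationError("loc_sd must be >= 0")


@dataclass
class Trajectory:
    """One tracked molecule: ordered localizations with a cell link.

    ``frame_interval`` is the camera frame time Δt in seconds;
    ``pulse_duration`` the stroboscopic laser pulse t_E (0 < t_E <= Δt,
    t_E = 0 meaning instantaneous exposure).
    """

    traj_id: str
    cell_id: str
    experiment_id: str
    points: list[Localization]
    frame_interval: float
    pulse_duration: float

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if not 0 <= self.pulse_duration <= self.frame_interval:
            raise ValidationError(
                "pulse_duration must satisfy 0 <= t_E <= frame_interval"
            )
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError(
                f"frames not strictly increasing in trajectory {self.traj_id!r}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=np.int64)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def gaps(self) -> np.ndarray:
        """Number of missing frames between consecutive localizations."""
        f = self.frames
        return np.diff(f) - 1

    def max_gap(self) -> int:
        g = self.gaps()
        return int(g.max()) if g.size else 0


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder pose: center and orientation in the image frame (µm,
    radians), pole-to-pole length and width (diameter)."""

    cell_id: str
    experiment_id: str
    center: tuple[float, float]
    orientation: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValidationError(
                f"cell {self.cell_id!r}: need length >= width > 0, "
                f"got length={self.length}, width={self.width}"
            )


@dataclass
class Dataset:
    """Trajectories plus cell geometry for one experimental condition."""

    trajectories: list[Trajectory]
    cells: list[CellGeometry]
    condition: str = ""

    def __post_init__(self) -> None:
        self.validate_links()

    def validate_links(self) -> None:
        cell_ids = {c.cell_id for c in self.cells}
        exp_ids = {c.experiment_id for c in self.cells}
        for t in self.trajectories:
            if t.cell_id not in cell_ids:
                raise ValidationError(
                    f"trajectory {t.traj_id!r} references unknown cell {t.cell_id!r}"
                )
            if t.experiment_id not in exp_ids:
                raise ValidationError(
                    f"trajectory {t.traj_id!r} references experiment "
                    f"{t.experiment_id!r} with no cell records"
                )

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_steps(self) -> int:
        return sum(max(len(t) - 1, 0) for t in self.trajectories)

    def cell_map(self) -> dict[str, CellGeometry]:
        return {c.cell_id: c for c in self.cells}


# ---------------------------------------------------------------------------
# reading / writing


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_cells(path) -> list[CellGeometry]:
    """Read a cell-geometry CSV (see module docstring for the dialect)."""
    df = pd.read_csv(path)
    _require_columns(df, CELL_COLUMNS, f"cell file {path}")
    cells = []
    for row in df.itertuples(index=False):
        cells.append(
            CellGeometry(
                cell_id=str(row.cell_id),
                experiment_id=str(row.experiment_id),
                center=(float(row.center_x_um), float(row.center_y_um)),
                orientation=float(row.orientation_rad),
                length=float(row.length_um),
                width=float(row.width_um),
            )
        )
    return cells


def read_trajectories(
    traj_path,
    cells_path,
    frame_interval: float,
    pulse_duration: float,
    *,
    max_gap: int = DEFAULT_MAX_GAP,
    gap_policy: str = "reject",
    condition: str = "",
) -> Dataset:
    """Parse trajectory and cell CSVs into a Dataset. No length filtering is
    applied here; gap violations are handled according to ``gap_policy``:

    - ``"reject"`` (default): a gap larger than ``max_gap`` raises
      ValidationError naming the trajectory;
    - ``"split"``: the trajectory is split at each oversized gap into
      sub-trajectories suffixed ``/0``, ``/1``, ...
    """
    if gap_policy not in ("reject", "split"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    df = pd.read_csv(traj_path)
    _require_columns(df, TRAJ_COLUMNS, f"trajectory file {traj_path}")
    has_sd = "loc_sd_um" in df.columns

    cells = read_cells(cells_path)
    trajectories: list[Trajectory] = []
    for traj_id, grp in df.groupby("traj_id", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValidationError(
                f"frames not strictly increasing in trajectory {traj_id!r}"
            )
        points = [
            Localization(
                frame=int(r.frame),
                x=float(r.x_um),
                y=float(r.y_um),
                loc_sd=float(r.loc_sd_um) if has_sd and pd.notna(r.loc_sd_um) else None,
            )
            for r in grp.itertuples(index=False)
        ]
        cell_id = str(grp["cell_id"].iloc[0])
        exp_id = str(grp["experiment_id"].iloc[0])

        pieces = _split_at_gaps(points, max_gap)
        if len(pieces) > 1 and gap_policy == "reject":
            worst = int((np.diff(frames) - 1).max())
            raise ValidationError(
                f"trajectory {traj_id!r}: gap of {worst} missing frames "
                f"exceeds max_gap={max_gap}"
            )
        for i, piece in enumerate(pieces):
            tid = str(traj_id) if len(pieces) == 1 else f"{traj_id}/{i}"
            trajectories.append(
                Trajectory(
                    traj_id=tid,
                    cell_id=cell_id,
                    experiment_id=exp_id,
                    points=piece,
                    frame_interval=frame_interval,
                    pulse_duration=pulse_duration,
                )
            )
    return Dataset(trajectories=trajectories, cells=cells, condition=condition)


def _split_at_gaps(points: list[Localization], max_gap: int) -> list[list[Localization]]:
    pieces: list[list[Localization]] = [[points[0]]]
    for prev, cur in zip(points, points[1:]):
        if cur.frame - prev.frame - 1 > max_gap:
            pieces.append([cur])
        else:
            pieces[-1].append(cur)
    return pieces


def write_trajectories(ds: Dataset, traj_path, cells_path) -> None:
    """Write a Dataset back to the two CSV dialects (round-trip safe)."""
    rows = []
    any_sd = any(p.loc_sd is not None for t in ds.trajectories for p in t.points)
    for t in ds.trajectories:
        for p in t.points:
            row = {
                "traj_id": t.traj_id,
                "cell_id": t.cell_id,
                "experiment_id": t.experiment_id,
                "frame": p.frame,
                "x_um": repr(p.x),
                "y_um": repr(p.y),
            }
            if any_sd:
                row["loc_sd_um"] = "" if p.loc_sd is None else repr(p.loc_sd)
            rows.append(row)
    pd.DataFrame(rows).to_csv(traj_path, index=False)

    crows = [
        {
            "cell_id": c.cell_id,
            "experiment_id": c.experiment_id,
            "center_x_um": repr(c.center[0]),
            "center_y_um": repr(c.center[1]),
            "orientation_rad": repr(c.orientation),
            "length_um": repr(c.length),
            "width_um": repr(c.width),
        }
        for c in ds.cells
    ]
    pd.DataFrame(crows).to_csv(cells_path, index=False)


# ---------------------------------------------------------------------------
# filtering


def filter_trajectories(
    ds: Dataset,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
) -> Dataset:
    """Keep trajectories strictly longer than ``min_length`` localizations
    whose internal gaps are all <= ``max_gap``. Idempotent; order preserved."""
    kept = [
        t
        for t in ds.trajectories
        if len(t) > min_length and t.max_gap() <= max_gap
    ]
    removed = len(ds.trajectories) - len(kept)
    logger.info(
        "filter_trajectories: kept %d / %d trajectories (removed %d)",
        len(kept), len(ds.trajectories), removed,
    )
    if not kept:
        warnings.warn("filter_trajectories: no trajectories retained")
    return Dataset(trajectories=kept, cells=list(ds.cells), condition=ds.condition)


def sort_cells_by_size(ds: Dataset, min_len: float, max_len: float) -> Dataset:
    """Size-based cell sorting: keep cells with min_len <= length <= max_len
    (µm) and the trajectories inside them. Approximates nucleoid-count-based
    exclusion of newly divided / overly long cells by a length window."""
    cells = [c for c in ds.cells if min_len <= c.length <= max_len]
    # Keep experiment linkage valid: a trajectory survives only if its cell does.
    kept_ids = {c.cell_id for c in cells}
    trajs = [t for t in ds.trajectories if t.cell_id in kept_ids]
    logger.info(
        "sort_cells_by_size: kept %d / %d cells, %d / %d trajectories",
        len(cells), len(ds.cells), len(trajs), len(ds.trajectories),
    )
    return Dataset(trajectories=trajs, cells=cells, condition=ds.condition)
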