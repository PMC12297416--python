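"""Synthetic trajectory generator for multi-state diffusion in bacterial cells.

Emulates stroboscopic single-molecule tracking of molecules switching between
K Brownian diffusion states inside a spherocylindrical cell:

* 3D Brownian motion propagated at ``n_sub`` sub-steps per camera frame, with
  reflecting boundaries at the cell envelope (rod of given width with
  hemispherical caps);
* Markov switching between states with exponential waiting times (the state is
  frozen within a sub-step);
* motion blur: the emitted position per frame is the mean of the sub-step
  positions falling inside the laser-pulse window at the start of the frame,
  projected to 2D (the optical axis is discarded);
* isotropic Gaussian localization error of standard deviation ``loc_sd``;
* geometric trajectory-length decay (photobleaching) and independent missed
  detections with probability ``p_gap``, constrained so that no surviving gap
  exceeds ``max_gap`` and the first/last frames are always detected;
* trajectories distributed over several independent "experiments", each with
  its own cells.

Ground truth (hidden state per localization and cell assignment) is returned
alongside, for parameter-recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import CellGeometry, Dataset, Localization, Trajectory

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "blur_factor"]


def blur_factor(pulse_duration: float, frame_interval: float) -> float:
    """Motion-blur variance-reduction coefficient R = t_E / (6 Δt).

    For uniform illumination over a pulse of length t_E within a frame of
    length Δt, averaging the Brownian path over the pulse reduces the apparent
    per-frame displacement variance by 2·R·(2·D·Δt). R = 1/6 for full-frame
    exposure; R -> 0 in the instantaneous-exposure limit (t_E = 0 accepted).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if pulse_duration < 0 or pulse_duration > frame_interval:
        raise ValueError("need 0 <= pulse_duration <= frame_interval")
    return pulse_duration / (6.0 * frame_interval)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror typical conditions of stroboscopic tracking of initiation
    factors in E. coli: 3 ms pulses in 5 ms frames, ~30-frame trajectories,
    30 nm localization error, ~0.8 µm wide, ~3 µm long cells.
    """

    K: int = 2
    D: tuple[float, ...] = (0.1, 3.0)  # µm²/s
    #: K×K switching-rate matrix, off-diagonal entries in 1/s; the diagonal
    #: is ignored (set to minus the row sum internally).
    rates: tuple[tuple[float, ...], ...] = ((0.0, 1 / 0.3), (1 / 0.7, 0.0))
    frame_interval: float = 0.005  # s
    pulse_duration: float = 0.003  # s
    loc_sd: float = 0.03  # µm
    mean_traj_len: float = 30.0  # frames
    p_gap: float = 0.1
    max_gap: int = 3
    n_traj: int = 1000
    n_experiments: int = 3
    cell_length_mean: float = 3.0  # µm, lognormal location (of the mean)
    cell_length_cv: float = 0.15
    cell_width: float = 0.8  # µm
    confine: bool = True
    n_sub: int = 50
    max_traj_len: int = 500  # truncation of the geometric length
    seed: int | None = None

    def __post_init__(self) -> None:
        self.D = tuple(float(d) for d in self.D)
        if len(self.D) != self.K:
            raise ValueError("len(D) must equal K")
        if any(d < 0 for d in self.D):
            raise ValueError("diffusion coefficients must be >= 0")
        R = np.asarray(self.rates, dtype=float)
        if R.shape != (self.K, self.K):
            raise ValueError("rates must be K x K")
        off = R[~np.eye(self.K, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not 0 <= self.pulse_duration <= self.frame_interval:
            raise ValueError("need 0 <= pulse_duration <= frame_interval")
        if not 0 <= self.p_gap < 1:
            raise ValueError("need 0 <= p_gap < 1")
        if self.mean_traj_len < 1:
            raise ValueError("mean_traj_len must be >= 1")

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q with rows summing to zero."""
        Q = np.asarray(self.rates, dtype=float).copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_occupancy(self) -> np.ndarray:
        """Stationary distribution of the switching process (pi @ Q = 0)."""
        if self.K == 1:
            return np.array([1.0])
        Q = self.rate_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(
            (Q > 0).astype(int), directed=True, connection="strong"
        )
        if n_comp > 1:
            raise ValueError(
                "reducible rate matrix: no unique stationary distribution"
            )
        # Solve pi Q = 0 with sum(pi) = 1 via the nullspace of Q^T.
        M = np.vstack([Q.T, np.ones(self.K)])
        b = np.zeros(self.K + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(M, b, rcond=None)
        if np.any(pi < -1e-9) or not np.isfinite(pi).all():
            raise ValueError("rate matrix has no valid stationary distribution")
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass
class GroundTruth:
    """Hidden truth aligned with the emitted Dataset.

    ``states[traj_id]`` holds the hidden state index at each *emitted*
    localization (the state at the start of the laser pulse); ``true_xy``
    the blur-averaged true 2D position (before localization noise).
    """

    states: dict[str, np.ndarray] = field(default_factory=dict)
    true_xy: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# geometry helpers (cell frame: long axis = x, centered at origin)


def _inside(pos: np.ndarray, half_axis: float, radius: float) -> np.ndarray:
    """Boolean mask: which (n, 3) positions lie inside the spherocylinder."""
    x = pos[:, 0]
    ax = np.clip(np.abs(x) - half_axis, 0.0, None)
    return ax**2 + pos[:, 1] ** 2 + pos[:, 2] ** 2 <= radius**2


def _sample_interior(
    rng: np.random.Generator, n: int, half_axis: float, radius: float
) -> np.ndarray:
    """Uniform points inside the spherocylinder by rejection from the
    bounding box."""
    pts = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        cand = rng.uniform(-1, 1, size=(m, 3)) * np.array(
            [half_axis + radius, radius, radius]
        )
        ok = cand[_inside(cand, half_axis, radius)]
        take = min(len(ok), n - filled)
        pts[filled : filled + take] = ok[:take]
        filled += take
    return pts


# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate a full dataset (trajectories + cells) with ground truth.

    Identical seeds give bit-identical output. See the module docstring for
    the generative model.
    """
    rng = np.random.default_rng(cfg.seed)
    pi0 = cfg.stationary_occupancy()
    D = np.asarray(cfg.D)
    Q = cfg.rate_matrix
    dt_sub = cfg.frame_interval / cfg.n_sub
    exit_rate = -np.diag(Q)
    p_switch = exit_rate * dt_sub
    if np.any(p_switch > 0.1):
        warnings.warn(
            "switching rate * sub-step exceeds 0.1; increase n_sub for "
            "accurate switching statistics"
        )
    # Conditional destination probabilities given a switch out of each state.
    dest = np.zeros((cfg.K, cfg.K))
    for k in range(cfg.K):
        if exit_rate[k] > 0:
            dest[k] = Q[k] / exit_rate[k]
            dest[k, k] = 0.0
        else:
            dest[k, k] = 1.0

    # Pulse window: sub-steps at the start of each frame. At least the first
    # sub-step position is always used (t_E = 0 -> snapshot at frame start).
    n_pulse = max(int(round(cfg.pulse_duration / cfg.frame_interval * cfg.n_sub)), 1)

    # --- cells: one per trajectory, grouped into experiments -----------------
    n = cfg.n_traj
    exp_of = rng.integers(0, cfg.n_experiments, size=n)
    sigma_log = np.sqrt(np.log(1 + cfg.cell_length_cv**2))
    mu_log = np.log(cfg.cell_length_mean) - 0.5 * sigma_log**2
    lengths = np.maximum(np.exp(rng.normal(mu_log, sigma_log, size=n)), cfg.cell_width)
    radius = cfg.cell_width / 2.0
    half_axis = np.maximum(lengths / 2.0 - radius, 0.0)
    centers = rng.uniform(5.0, 45.0, size=(n, 2))
    orientations = rng.uniform(0, np.pi, size=n)

    # --- trajectory lengths (frames, geometric with given mean) --------------
    p_bleach = 1.0 / cfg.mean_traj_len
    n_frames = np.minimum(rng.geometric(p_bleach, size=n), cfg.max_traj_len)
    t_max = int(n_frames.max())

    # --- lockstep propagation over sub-steps ---------------------------------
    if cfg.confine:
        pos = np.empty((n, 3))
        for i in range(n):  # per-cell geometry differs; sample one point each
            pos[i] = _sample_interior(rng, 1, half_axis[i], radius)[0]
    else:
        pos = np.zeros((n, 3))
    state = rng.choice(cfg.K, size=n, p=pi0) if cfg.K > 1 else np.zeros(n, dtype=int)

    blur_sum = np.zeros((n, 3))
    frame_xy = np.full((n, t_max, 2), np.nan)  # blurred true 2D, cell frame
    frame_state = np.zeros((n, t_max), dtype=np.int64)
    sqrt2dt = np.sqrt(2.0 * D * dt_sub)

    for t in range(t_max):
        active = n_frames > t
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        blur_sum[idx] = 0.0
        frame_state[idx, t] = state[idx]
        for s in range(cfg.n_sub):
            if s < n_pulse:
                blur_sum[idx] += pos[idx]
            # Brownian sub-step, then reflection at the envelope.
            step = rng.standard_normal((idx.size, 3)) * sqrt2dt[state[idx]][:, None]
            newpos = pos[idx] + step
            if cfg.confine:
                # Geometry differs per cell; group by identical half_axis is
                # overkill — reflection is cheap enough done jointly with
                # per-row parameters via a small loop over unique radii.
                newpos = _reflect_per_cell(newpos, half_axis[idx], radius)
            pos[idx] = newpos
            # Markov switching, frozen within the sub-step.
            if cfg.K > 1:
                u = rng.random(idx.size)
                switch = u < p_switch[state[idx]]
                if switch.any():
                    sw = idx[switch]
                    state[sw] = _sample_destinations(rng, dest, state[sw])
        frame_xy[idx, t, :] = blur_sum[idx, :2] / n_pulse

    # --- detection gaps ------------------------------------------------------
    trajectories: list[Trajectory] = []
    cells: list[CellGeometry] = []
    truth = GroundTruth(config=cfg)
    for i in range(n):
        L = int(n_frames[i])
        keep = np.ones(L, dtype=bool)
        if cfg.p_gap > 0 and L > 2:
            drop = rng.random(L) < cfg.p_gap
            drop[0] = drop[-1] = False
            keep = _apply_gap_limit(~drop, cfg.max_gap)
        frames = np.flatnonzero(keep)

        # Rotate/translate from the cell frame into the image frame.
        th = orientations[i]
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy_cell = frame_xy[i, frames, :]
        xy_img = xy_cell @ Rm.T + centers[i]
        noisy = xy_img + rng.normal(0.0, cfg.loc_sd, size=xy_img.shape)

        cid = f"cell{i:05d}"
        eid = f"exp{exp_of[i]}"
        tid = f"traj{i:05d}"
        cells.append(
            CellGeometry(
                cell_id=cid,
                experiment_id=eid,
                center=(float(centers[i, 0]), float(centers[i, 1])),
                orientation=float(th),
                length=float(lengths[i]),
                width=float(cfg.cell_width),
            )
        )
        pts = [
            Localization(frame=int(f), x=float(p[0]), y=float(p[1]))
            for f, p in zip(frames, noisy)
        ]
        trajectories.append(
            Trajectory(
                traj_id=tid,
                cell_id=cid,
                experiment_id=eid,
                points=pts,
                frame_interval=cfg.frame_interval,
                pulse_duration=cfg.pulse_duration,
            )
        )
        truth.states[tid] = frame_state[i, frames].copy()
        truth.true_xy[tid] = xy_img

    ds = Dataset(trajectories=trajectories, cells=cells, condition="simulated")
    return ds, truth


def _reflect_per_cell(pos: np.ndarray, half_axis: np.ndarray, radius: float) -> np.ndarray:
    """Reflection with per-row half_axis (radius shared)."""
    out = pos.copy()
    for _ in range(8):
        x = out[:, 0]
        ax = np.clip(np.abs(x) - half_axis, 0.0, None)
        bad = ax**2 + out[:, 1] ** 2 + out[:, 2] ** 2 > radius**2
        if not bad.any():
            return out
        p = out[bad]
        ha = half_axis[bad]
        cx = np.clip(p[:, 0], -ha, ha)
        anchor = np.stack([cx, 0 * cx, 0 * cx], axis=1)
        rel = p - anchor
        r = np.linalg.norm(rel, axis=1)
        r = np.where(r == 0, 1e-12, r)
        rnew = 2.0 * radius - r
        rnew = np.where(rnew < 0, 0.5 * radius, rnew)
        out[bad] = anchor + rel * (rnew / r)[:, None]
    # final clamp
    x = out[:, 0]
    ax = np.clip(np.abs(x) - half_axis, 0.0, None)
    bad = ax**2 + out[:, 1] ** 2 + out[:, 2] ** 2 > radius**2
    if bad.any():  # pragma: no cover
        p = out[bad]
        ha = half_axis[bad]
        cx = np.clip(p[:, 0], -ha, ha)
        anchor = np.stack([cx, 0 * cx, 0 * cx], axis=1)
        rel = p - anchor
        r = np.linalg.norm(rel, axis=1)
        out[bad] = anchor + rel * (0.99 * radius / np.where(r == 0, 1, r))[:, None]
    return out


def _sample_destinations(
    rng: np.random.Generator, dest: np.ndarray, states: np.ndarray
) -> np.ndarray:
    """Vectorized categorical draw of switch destinations per current state."""
    cdf = np.cumsum(dest[states], axis=1)
    u = rng.random(len(states))[:, None]
    return (u > cdf).sum(axis=1)


def _apply_gap_limit(keep: np.ndarray, max_gap: int) -> np.ndarray:
    """Re-insert dropped frames so that no gap exceeds max_gap."""
    keep = keep.copy()
    last = 0
    for j in range(1, len(keep)):
        if keep[j]:
            last = j
        elif j - last > max_gap:
            keep[j] = True
            last = j
    return keep
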