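"""Global maximum-likelihood diffusional HMM for single-particle trajectories.

All trajectories of a dataset are fitted jointly to a K-state hidden Markov
model in which each state k is a Brownian diffusion state with coefficient
D_k (µm²/s). The observed per-step 2D displacement over a span of n frames
(n = 1 + number of missing frames) is emitted as an isotropic Gaussian with
per-dimension variance

    v_k(n) = 2 D_k (n Δt) (1 - 2R/n) + 2 σ_loc²,

which corrects for motion blur (blur coefficient R = t_E / 6Δt for uniform
stroboscopic exposure) and localization error σ_loc. Hidden states switch
between consecutive displacements through the per-frame transition matrix A,
raised to the n-th power across detection gaps. Fitting is Baum–Welch EM from
multiple random initializations; the per-frame A is updated from exact
expected transition counts through the latent missing frames. Model
comparison across K uses AIC.

Consecutive-step covariance induced by blur and localization noise is
neglected (diagonal emission approximation); the resulting bias is quantified
by recovery tests against the simulator, which includes the full physics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .simulate import blur_factor
from .trajectory_io import Dataset

logger = logging.getLogger("spt.hmm")

__all__ = [
    "DiffusionModel",
    "Posterior",
    "step_variance",
    "loglik",
    "fit",
    "aic",
    "model_scan",
    "posterior",
]

_D_INIT_RANGE = (0.005, 20.0)  # µm²/s, log-uniform random initialization
_SELF_TRANS_RANGE = (0.8, 0.99)
_D_MAX = 200.0  # µm²/s, upper bracket for the M-step line search


def step_variance(
    D: float, n_frames: int, sigma_loc: float, R: float, frame_interval: float
) -> float:
    """Per-dimension displacement variance over a span of ``n_frames`` frames.

    v = 2 D (n Δt) (1 - 2R/n) + 2 σ_loc². n_frames = g+1 spans a gap of g
    missing frames; R is the blur coefficient, σ_loc the localization SD.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = float(n_frames)
    return 2.0 * D * (n * frame_interval) * (1.0 - 2.0 * R / n) + 2.0 * sigma_loc**2


@dataclass
class DiffusionModel:
    """Fitted K-state diffusional HMM.

    States are stored sorted by ascending D (ties broken by occupancy,
    descending). ``pi`` is the stationary left eigenvector of the per-frame
    transition matrix ``A``. ``sigma_loc`` is the global localization SD (µm)
    and ``R`` the blur coefficient; both enter the emission variances.
    """

    K: int
    D: np.ndarray  # (K,) µm²/s
    A: np.ndarray  # (K, K) per-frame transition probabilities
    pi: np.ndarray  # (K,) stationary occupancy
    sigma_loc: float
    R: float
    frame_interval: float
    logL: float = np.nan
    n_params: int = 0
    aic: float = np.nan

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.D.shape != (self.K,) or self.A.shape != (self.K, self.K):
            raise ValueError("inconsistent model dimensions")
        if np.any(self.D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of A must sum to 1")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "D_um2_per_s": self.D.tolist(),
            "A_per_frame": self.A.tolist(),
            "pi": self.pi.tolist(),
            "sigma_loc_um": self.sigma_loc,
            "blur_R": self.R,
            "frame_interval_s": self.frame_interval,
            "logL": self.logL,
            "n_params": self.n_params,
            "aic": self.aic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionModel":
        return cls(
            K=d["K"],
            D=np.array(d["D_um2_per_s"]),
            A=np.array(d["A_per_frame"]),
            pi=np.array(d["pi"]),
            sigma_loc=d["sigma_loc_um"],
            R=d["blur_R"],
            frame_interval=d["frame_interval_s"],
            logL=d.get("logL", np.nan),
            n_params=d.get("n_params", 0),
            aic=d.get("aic", np.nan),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DiffusionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Posterior:
    """E-step bookkeeping: per-localization state probabilities.

    ``gamma[traj_id]`` has one row per localization: for localization i < n-1
    it is the posterior over the state of the displacement starting at i; the
    last localization repeats the final displacement's posterior. ``xi_sum``
    holds the summed pairwise transition expectations by span.
    """

    gamma: dict[str, np.ndarray]
    xi_sum: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# internal packed representation


class _Packed:
    """Displacement sequences padded to a rectangle for vectorized passes.

    dx2[m, t]   squared 2D displacement of trajectory m at step t
    span[m, t]  frame span of that step (1 + gap), 0 where padded
    point_sd2[m, t]  optional fixed per-step localization variance term
                     (sd_i² + sd_{i+1}²), NaN when per-point SDs are absent
    """

    def __init__(self, ds: Dataset):
        seqs = []
        self.traj_ids = []
        self.dt = None
        self.R = None
        for tr in ds.trajectories:
            if len(tr) < 2:
                warnings.warn(
                    f"trajectory {tr.traj_id!r} has fewer than 2 localizations; skipped"
                )
                continue
            if self.dt is None:
                self.dt = tr.frame_interval
                self.R = blur_factor(tr.pulse_duration, tr.frame_interval)
            xy = tr.xy
            d = np.diff(xy, axis=0)
            dx2 = (d**2).sum(axis=1)
            span = np.diff(tr.frames)
            sds = [p.loc_sd for p in tr.points]
            if all(s is not None for s in sds):
                sd = np.asarray(sds, dtype=float)
                psd2 = sd[:-1] ** 2 + sd[1:] ** 2
            else:
                psd2 = np.full(len(dx2), np.nan)
            seqs.append((dx2, span.astype(np.int64), psd2))
            self.traj_ids.append(tr.traj_id)
        if not seqs:
            raise ValueError("dataset contains no trajectory with >= 2 localizations")
        self.n_traj = len(seqs)
        self.lengths = np.array([len(s[0]) for s in seqs])
        T = int(self.lengths.max())
        self.T = T
        self.dx2 = np.zeros((self.n_traj, T))
        self.span = np.zeros((self.n_traj, T), dtype=np.int64)
        self.psd2 = np.full((self.n_traj, T), np.nan)
        for m, (dx2, span, psd2) in enumerate(seqs):
            L = len(dx2)
            self.dx2[m, :L] = dx2
            self.span[m, :L] = span
            self.psd2[m, :L] = psd2
        self.mask = self.span > 0
        self.spans_present = np.unique(self.span[self.mask])
        self.has_point_sd = not np.isnan(self.psd2[self.mask]).any()
        self.n_steps = int(self.mask.sum())

    def emission_logprob(self, D: np.ndarray, sigma_loc: float, R: float) -> np.ndarray:
        """(n_traj, T, K) log emission densities (bivariate isotropic)."""
        n = np.where(self.mask, self.span, 1).astype(float)
        # per-dimension variance, (n_traj, T, K)
        dterm = 2.0 * (n * self.dt) * (1.0 - 2.0 * R / n)
        if self.has_point_sd:
            noise = np.where(self.mask, self.psd2, 1.0)
        else:
            noise = np.full_like(self.dx2, 2.0 * sigma_loc**2)
        v = dterm[..., None] * D[None, None, :] + noise[..., None]
        v = np.maximum(v, 1e-300)
        ll = -np.log(2.0 * np.pi * v) - self.dx2[..., None] / (2.0 * v)
        ll[~self.mask] = 0.0
        return ll


def _matrix_powers(A: np.ndarray, spans: np.ndarray) -> dict[int, np.ndarray]:
    pows = {1: A}
    for s in range(2, int(spans.max()) + 1):
        pows[s] = pows[s - 1] @ A
    return {int(s): pows[int(s)] for s in spans} | {1: A}


def _forward_backward(
    packed: _Packed,
    D: np.ndarray,
    A: np.ndarray,
    p0: np.ndarray,
    sigma_loc: float,
    R: float,
    *,
    want_posteriors: bool = True,
):
    """Scaled forward-backward over all trajectories simultaneously.

    Returns (logL, gamma, xi_sum, gamma0) where gamma is (n_traj, T, K)
    posteriors per displacement, xi_sum maps span -> summed (K, K) pairwise
    expectations over all steps with that span, and gamma0 is the posterior
    of the first displacement per trajectory.
    """
    K = len(D)
    N, T = packed.dx2.shape
    logB = packed.emission_logprob(D, sigma_loc, R)
    # Per-step scaling of emissions for numerical range.
    bmax = logB.max(axis=2)
    B = np.exp(logB - bmax[..., None])
    pows = _matrix_powers(A, packed.spans_present)

    alpha = np.zeros((N, T, K))
    c = np.ones((N, T))
    a = p0[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0:1]
    # The state of displacement i is the physical state at its first frame;
    # the chain advances span[i] frames to reach the state of displacement
    # i+1, so the transition operator between steps t-1 and t is A^span[t-1].
    for t in range(1, T):
        act = packed.mask[:, t]
        if not act.any():
            continue
        prev = alpha[:, t - 1, :]
        nxt = np.zeros((N, K))
        for s, As in pows.items():
            sel = act & (packed.span[:, t - 1] == s)
            if sel.any():
                nxt[sel] = prev[sel] @ As
        a = nxt * B[:, t, :]
        ct = a.sum(axis=1)
        ct = np.where(act, ct, 1.0)
        alpha[:, t, :] = np.where(act[:, None], a / ct[:, None], prev)
        c[:, t] = ct

    last = packed.lengths - 1
    # logL: sum over active steps of log c, plus the emission scaling.
    logL = float(np.log(c[packed.mask]).sum() + bmax[packed.mask].sum())

    if not want_posteriors:
        return logL, None, None, None

    beta = np.zeros((N, T, K))
    rows = np.arange(N)
    beta[rows, last, :] = 1.0
    xi_sum = {int(s): np.zeros((K, K)) for s in pows}
    for t in range(T - 1, 0, -1):
        act = packed.mask[:, t]
        if not act.any():
            continue
        w = B[:, t, :] * beta[:, t, :] / c[:, t:t + 1]  # (N, K)
        prev_beta = np.zeros((N, K))
        for s, As in pows.items():
            sel = act & (packed.span[:, t - 1] == s)
            if sel.any():
                prev_beta[sel] = w[sel] @ As.T
                xi_sum[s] += As * (alpha[sel, t - 1, :].T @ w[sel])
        beta[:, t - 1, :] = np.where(act[:, None], prev_beta, beta[:, t - 1, :])

    gamma = alpha * beta
    gsum = gamma.sum(axis=2, keepdims=True)
    gsum[gsum == 0] = 1.0
    gamma = gamma / gsum
    gamma[~packed.mask] = 0.0
    gamma0 = gamma[:, 0, :]
    return logL, gamma, xi_sum, gamma0


def _expected_transition_counts(
    A: np.ndarray, xi_sum: dict[int, np.ndarray]
) -> np.ndarray:
    """Exact expected per-frame i->j transition counts given endpoint pair
    expectations over spans: a span-n transition is governed by A^n; the
    expected counts through the n latent per-frame moves are

        counts_n = A * sum_{t=0}^{n-1} (A^t)^T  W  (A^{n-1-t})^T,

    with W = Xi_n / A^n elementwise (Xi_n the summed endpoint expectations).
    """
    K = A.shape[0]
    counts = np.zeros((K, K))
    nmax = max(xi_sum)
    pows = [np.eye(K)]
    for _ in range(nmax):
        pows.append(pows[-1] @ A)
    for n, Xi in xi_sum.items():
        if not Xi.any():
            continue
        An = pows[n]
        W = np.divide(Xi, An, out=np.zeros_like(Xi), where=An > 0)
        S = np.zeros((K, K))
        for t in range(n):
            S += pows[t].T @ W @ pows[n - 1 - t].T
        counts += A * S
    return counts


def _mstep_transitions(
    counts: np.ndarray, G0: np.ndarray, A_init: np.ndarray
) -> np.ndarray:
    """Stationarity-tied M-step for the transition matrix.

    Maximizes Q(A) = sum_ij C_ij log A_ij + sum_j G0_j log pi_j(A) over
    row-stochastic A, where C are expected transition counts and G0 the
    summed first-step posteriors (the initial distribution is tied to the
    stationary vector pi(A)). Rows are parametrized by logits; the gradient
    of the stationary term uses dpi^T = pi^T dA Z with the fundamental
    matrix Z = (I - A + 1 pi^T)^{-1}. Started from the current A, so the
    generalized-EM ascent property is preserved (the better of start and
    optimum is returned).
    """
    from scipy.optimize import minimize

    K = A_init.shape[0]
    eye = np.eye(K)

    def unpack(x):
        logits = x.reshape(K, K)
        logits = logits - logits.max(axis=1, keepdims=True)
        E = np.exp(logits)
        return E / E.sum(axis=1, keepdims=True)

    def negQ_grad(x):
        A = np.maximum(unpack(x), 1e-300)
        pi = _stationary(A)
        pi_s = np.maximum(pi, 1e-300)
        Q = float((counts * np.log(A)).sum() + (G0 * np.log(pi_s)).sum())
        Z = np.linalg.solve((eye - A + np.outer(np.ones(K), pi)).T, eye).T
        gA = counts / A + np.outer(pi, Z @ (G0 / pi_s))
        # chain rule through the row softmax
        gx = A * (gA - (A * gA).sum(axis=1, keepdims=True))
        return -Q, -gx.ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        x0 = np.log(np.maximum(A_init, 1e-12)).ravel()
        q0 = negQ_grad(x0)[0]
        res = minimize(negQ_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 100, "ftol": 1e-14, "gtol": 1e-12})
    if res.fun <= q0:
        return unpack(res.x)
    return A_init  # pragma: no cover - optimizer failed to improve


def _stationary(A: np.ndarray) -> np.ndarray:
    """Left stationary vector of a row-stochastic matrix."""
    K = A.shape[0]
    M = np.vstack([A.T - np.eye(K), np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _optimize_state_D(
    S_n: dict[int, float], W_n: dict[int, float], noise_n: dict[int, float],
    dt: float, R: float
) -> float:
    """M-step for one state's D: maximize the expected log-likelihood

        Q(D) = sum_n [ -W_n log v_n(D) - S_n / (2 v_n(D)) ],
        v_n(D) = c_n D + noise_n,  c_n = 2 Δt (n - 2R),

    where S_n, W_n are responsibility-weighted sums of squared displacements
    and weights over steps of span n. Closed form for a single span; 1-D
    bounded search otherwise.
    """
    spans = [n for n in S_n if W_n[n] > 0]
    if not spans:
        return 0.0
    if len(spans) == 1:
        n = spans[0]
        c = 2.0 * dt * (n - 2.0 * R)
        vhat = S_n[n] / (2.0 * W_n[n])
        return max((vhat - noise_n[n]) / c, 0.0)

    def negQ(D):
        q = 0.0
        for n in spans:
            c = 2.0 * dt * (n - 2.0 * R)
            v = max(c * D + noise_n[n], 1e-300)
            q += -W_n[n] * np.log(v) - S_n[n] / (2.0 * v)
        return -q

    res = minimize_scalar(negQ, bounds=(0.0, _D_MAX), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _em_single(
    packed: _Packed,
    K: int,
    rng: np.random.Generator,
    *,
    sigma_loc: float | None,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, list[float]]:
    """One EM run from a random initialization. Returns (D, A, pi, sigma,
    logL, history). The initial-state distribution is tied to the stationary
    vector of A throughout."""
    lo, hi = _D_INIT_RANGE
    D = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=K)))
    if K == 1:
        A = np.ones((1, 1))
    else:
        diag = rng.uniform(*_SELF_TRANS_RANGE, size=K)
        A = ((1.0 - diag) / (K - 1))[:, None] * np.ones((K, K))
        np.fill_diagonal(A, diag)
    pi = _stationary(A)
    fit_sigma = sigma_loc is None and not packed.has_point_sd
    sigma = rng.uniform(0.01, 0.05) if fit_sigma else (sigma_loc or 0.0)
    if packed.has_point_sd:
        sigma = 0.0

    history: list[float] = []
    prev_logL = -np.inf
    for it in range(max_iter):
        logL, gamma, xi_sum, gamma0 = _forward_backward(
            packed, D, A, pi, sigma, packed.R
        )
        history.append(logL)
        if np.isfinite(prev_logL):
            rel = (logL - prev_logL) / max(abs(prev_logL), 1.0)
            if rel < -1e-9:
                logger.debug("EM logL decreased by %.3g at iter %d", -rel, it)
            if abs(logL - prev_logL) <= tol * max(abs(prev_logL), 1.0):
                break
        prev_logL = logL

        # M-step: transitions (stationarity-tied), diffusion, sigma. The
        # initial distribution is pi(A), so the Q function for A carries a
        # sum_j gamma_0(j) log pi_j(A) term in addition to the expected
        # transition counts; _mstep_transitions maximizes it directly
        # (generalized EM).
        if K > 1:
            counts = _expected_transition_counts(A, xi_sum)
            A = _mstep_transitions(counts, gamma0.sum(axis=0), A)
            pi = _stationary(A)

        # responsibility-weighted sums grouped by span (and noise term)
        S_n: list[dict[int, float]] = [dict() for _ in range(K)]
        W_n: list[dict[int, float]] = [dict() for _ in range(K)]
        noise_n: dict[int, float] = {}
        for s in packed.spans_present:
            sel = packed.span == s
            g = gamma[sel]  # (n_sel, K)
            d2 = packed.dx2[sel]
            if packed.has_point_sd:
                # per-step noise varies; fold it by treating mean noise per
                # span (exact when per-point SDs are constant; the general
                # case uses the weighted mean as a fast approximation)
                noise = packed.psd2[sel]
                noise_n[int(s)] = float(np.average(noise, weights=g.sum(axis=1)))
            else:
                noise_n[int(s)] = 2.0 * sigma**2
            for k in range(K):
                W_n[k][int(s)] = float(g[:, k].sum())
                S_n[k][int(s)] = float((g[:, k] * d2).sum())
        for k in range(K):
            D[k] = _optimize_state_D(S_n[k], W_n[k], noise_n, packed.dt, packed.R)

        if fit_sigma:
            sigma = _optimize_sigma(S_n, W_n, D, packed.dt, packed.R, sigma)

    return D, A, pi, sigma, history[-1], history


def _optimize_sigma(S_n, W_n, D, dt, R, sigma0) -> float:
    """Conditional M-step for the global localization SD given D."""
    K = len(D)

    def negQ(sig):
        q = 0.0
        for k in range(K):
            for n, w in W_n[k].items():
                if w == 0:
                    continue
                c = 2.0 * dt * (n - 2.0 * R)
                v = max(c * D[k] + 2.0 * sig**2, 1e-300)
                q += -w * np.log(v) - S_n[k][n] / (2.0 * v)
        return -q

    res = minimize_scalar(negQ, bounds=(0.0, 0.5), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _sort_states(D, A, pi):
    """Sort states by ascending D; ties broken by occupancy descending."""
    order = np.lexsort((-pi, D))
    return D[order], A[np.ix_(order, order)], pi[order], order


def fit(
    ds: Dataset,
    K: int,
    *,
    n_starts: int = 10,
    seed: int = 0,
    sigma_loc: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> DiffusionModel:
    """Fit a K-state model by EM from ``n_starts`` random initializations and
    return the highest-likelihood result.

    ``sigma_loc=None`` fits a single global localization SD (unless per-point
    SDs are present, which are then used as fixed per-step noise); a float
    fixes it. States are sorted by ascending D; ``pi`` is recomputed as the
    stationary vector of the fitted per-frame A, and the reported logL/AIC
    are evaluated under that stationary initial distribution.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    packed = _Packed(ds)
    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for start in range(n_starts):
        try:
            D, A, pi, sig, logL, hist = _em_single(
                packed, K, rng, sigma_loc=sigma_loc, tol=tol, max_iter=max_iter
            )
        except np.linalg.LinAlgError as err:  # pragma: no cover
            failures.append(str(err))
            continue
        if not np.isfinite(logL):
            failures.append("non-finite likelihood")
            continue
        if best is None or logL > best[4]:
            best = (D, A, pi, sig, logL, hist)
    if best is None:
        raise RuntimeError(
            f"no EM initialization converged for K={K}: {failures}"
        )
    D, A, pi, sig, _, hist = best
    D, A, pi, _ = _sort_states(D, A, pi)
    sigma_fitted = sigma_loc is None and not packed.has_point_sd
    n_params = K + K * (K - 1) + (1 if sigma_fitted else 0)
    model = DiffusionModel(
        K=K, D=D, A=A, pi=pi, sigma_loc=sig, R=packed.R,
        frame_interval=packed.dt, n_params=n_params,
    )
    model.logL = loglik(ds, model)
    model.aic = aic(model)
    logger.info("fit K=%d: logL=%.3f AIC=%.3f D=%s", K, model.logL, model.aic,
                np.array2string(model.D, precision=3))
    return model


def loglik(ds: Dataset, model: DiffusionModel) -> float:
    """Forward-algorithm log-likelihood of the dataset under the model, with
    ``model.pi`` as the initial state distribution and A^n across gaps."""
    packed = _Packed(ds)
    logL, *_ = _forward_backward(
        packed, model.D, model.A, model.pi, model.sigma_loc, model.R,
        want_posteriors=False,
    )
    return logL


def posterior(ds: Dataset, model: DiffusionModel) -> Posterior:
    """Per-localization posterior state probabilities under the model.

    The posterior of the displacement starting at localization i is assigned
    to localization i; the trajectory's last localization repeats the final
    displacement's posterior.
    """
    packed = _Packed(ds)
    _, gamma, xi_sum, _ = _forward_backward(
        packed, model.D, model.A, model.pi, model.sigma_loc, model.R
    )
    out: dict[str, np.ndarray] = {}
    for m, tid in enumerate(packed.traj_ids):
        L = packed.lengths[m]
        g = gamma[m, :L, :]
        out[tid] = np.vstack([g, g[-1:, :]])
    return Posterior(gamma=out, xi_sum={int(k): v for k, v in xi_sum.items()})


def aic(model: DiffusionModel) -> float:
    """Akaike information criterion, 2 n_params - 2 logL; n_params counts the
    K diffusion coefficients, K(K-1) off-diagonal transition probabilities,
    and the global sigma_loc when it was fitted (the initial distribution is
    tied to stationarity and contributes none)."""
    return 2.0 * model.n_params - 2.0 * model.logL


def model_scan(
    ds: Dataset,
    K_range=range(1, 10),
    *,
    n_starts: int = 10,
    seed: int = 0,
    sigma_loc: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[DiffusionModel]:
    """Fit every model size in ``K_range`` and return the fitted models in
    order. The per-K summary (D values, occupancies, AIC) is logged; use
    :func:`scan_table` for a tabular view."""
    models = []
    for K in K_range:
        models.append(
            fit(ds, K, n_starts=n_starts, seed=seed + K, sigma_loc=sigma_loc,
                tol=tol, max_iter=max_iter)
        )
    return models


def scan_table(models: list[DiffusionModel]):
    """Long-format summary of a model scan: one row per (K, state)."""
    import pandas as pd

    rows = []
    for m in models:
        for k in range(m.K):
            rows.append(
                {"K": m.K, "state": k, "D_um2_per_s": m.D[k],
                 "occupancy": m.pi[k], "logL": m.logL, "aic": m.aic}
            )
    return pd.DataFrame(rows)


def plot_scan(models, thresholds=(1.0, 8.0), ax=None):
    """Occupancy-vs-D bubble chart across model sizes (untested decoration)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for m in models:
        ax.scatter(np.maximum(m.D, 1e-3), [m.K] * m.K, s=2000 * m.pi,
                   alpha=0.6, color="C0")
    for t in thresholds:
        ax.axvline(t, color="red", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("D (µm²/s)")
    ax.set_ylabel("model size K")
    return ax
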