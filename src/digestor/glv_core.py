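"""Generalized Lotka-Volterra simulation, inference and sign analysis.

The community model is dx_i/dt = x_i (r_i + sum_j a_ij x_j). Parameters are
estimated by gradient matching: the finite-difference derivative of
ln x_i is regressed on [1, x_1 .. x_n] with an optional ridge penalty on
the interaction slopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline, make_smoothing_spline

DEFAULT_FLOOR = 1e-8
BLOWUP_LIMIT = 1e12


class BlowupError(RuntimeError):
    """Simulation diverged; records the first divergent taxon and time."""

    def __init__(self, taxon: str, time: float):
        super().__init__(f"abundance of {taxon!r} exceeded {BLOWUP_LIMIT:g} at t = {time:.4g}")
        self.taxon = taxon
        self.time = time


class UnderdeterminedError(ValueError):
    """Fewer observations than parameters with no regularization."""


@dataclass
class GLVModel:
    """Intrinsic growth rates ``r`` and interaction matrix ``A``."""

    taxa: list[str]
    r: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.taxa)
        if n < 1:
            raise ValueError("need at least one taxon")
        if self.r.shape != (n,) or self.A.shape != (n, n):
            raise ValueError("shape mismatch between taxa, r and A")
        if not (np.isfinite(self.r).all() and np.isfinite(self.A).all()):
            raise ValueError("model parameters must be finite")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"taxa": self.taxa, "r": self.r.tolist(), "A": self.A.tolist()}, fh, indent=1
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GLVModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(taxa=list(doc["taxa"]), r=np.asarray(doc["r"]), A=np.asarray(doc["A"]))


@dataclass
class Trajectory:
    """Strictly positive abundances of ``n`` taxa at ordered timepoints."""

    times: np.ndarray
    X: np.ndarray
    taxa: list[str]
    floored: np.ndarray | None = None  # mask of entries raised to the floor

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.X.shape != (self.times.size, len(self.taxa)):
            raise ValueError("X must be timepoints x taxa")
        if np.any(self.X <= 0):
            raise ValueError("abundances must be strictly positive (apply a floor first)")

    @classmethod
    def from_observations(
        cls,
        times: Sequence[float],
        X: np.ndarray,
        taxa: Sequence[str],
        floor: float = DEFAULT_FLOOR,
    ) -> "Trajectory":
        """Build a trajectory, replacing non-positive entries by ``floor`` (flagged)."""
        X = np.asarray(X, dtype=float)
        mask = X < floor
        return cls(
            times=np.asarray(times, dtype=float),
            X=np.where(mask, floor, X),
            taxa=list(taxa),
            floored=mask,
        )


@dataclass
class SignMatrix:
    """Ternary interaction signs derived from A with neutrality threshold eps."""

    signs: np.ndarray
    taxa: list[str]
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        n = len(self.taxa)
        if self.signs.shape != (n, n):
            raise ValueError("sign matrix must be n x n")
        if not np.isin(self.signs, (-1, 0, 1)).all():
            raise ValueError("entries must be in {-1, 0, +1}")


@dataclass
class InteractionSummary:
    positive: int
    negative: int
    neutral: int
    label: str | None = None

    @property
    def total(self) -> int:
        return self.positive + self.negative + self.neutral


@dataclass
class InferenceDiagnostics:
    r_squared: np.ndarray
    condition_number: float
    degenerate: bool = False
    n_floored: int = 0


def simulate(
    model: GLVModel,
    x0: Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    floor: float = DEFAULT_FLOOR,
) -> Trajectory:
    """Integrate the gLV system with adaptive Runge-Kutta.

    Abundances below ``floor`` are clamped after integration; any state
    exceeding :data:`BLOWUP_LIMIT` aborts with :class:`BlowupError`.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial abundances must be strictly positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    r, A = model.r, model.A

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        return x * (r + A @ x)

    def blowup_event(t: float, x: np.ndarray) -> float:
        return BLOWUP_LIMIT - np.max(np.abs(x))

    blowup_event.terminal = True
    blowup_event.direction = -1

    t0 = float(times[0])
    sol = solve_ivp(
        rhs,
        (t0, float(times[-1])),
        x0,
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        events=blowup_event,
        dense_output=False,
    )
    if sol.t_events and len(sol.t_events[0]) > 0:
        t_ev = float(sol.t_events[0][0])
        x_ev = sol.y_events[0][0]
        taxon = model.taxa[int(np.argmax(np.abs(x_ev)))]
        raise BlowupError(taxon, t_ev)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    X = np.maximum(sol.y.T, floor)
    return Trajectory(times=times, X=X, taxa=list(model.taxa), floored=sol.y.T < floor)


def log_derivatives(times: np.ndarray, X: np.ndarray) -> np.ndarray:
    """d(ln x)/dt on an irregular grid.

    Interior points use three-point Lagrange (quadratic) differences;
    endpoints use one-sided two-point differences.
    """
    t = np.asarray(times, dtype=float)
    L = np.log(X)
    T = t.size
    D = np.empty_like(L)
    D[0] = (L[1] - L[0]) / (t[1] - t[0])
    D[-1] = (L[-1] - L[-2]) / (t[-1] - t[-2])
    for k in range(1, T - 1):
        t0, t1, t2 = t[k - 1], t[k], t[k + 1]
        w0 = (t1 - t2) / ((t0 - t1) * (t0 - t2))
        w1 = (2 * t1 - t0 - t2) / ((t1 - t0) * (t1 - t2))
        w2 = (t1 - t0) / ((t2 - t0) * (t2 - t1))
        D[k] = w0 * L[k - 1] + w1 * L[k] + w2 * L[k + 1]
    return D


DERIVATIVE_SCHEMES = ("fd", "spline", "smooth")


def spline_log_derivatives(
    times: np.ndarray, X: np.ndarray, smoothing: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Spline-based d(ln x)/dt and the (possibly smoothed) abundances.

    With ``smoothing`` each taxon's log series is fit with a GCV-tuned
    smoothing spline (appropriate for noisy observations); otherwise an
    interpolating cubic spline is differentiated (high-order accuracy on
    noiseless data). Needs at least 5 timepoints.
    """
    t = np.asarray(times, dtype=float)
    L = np.log(X)
    Y = np.empty_like(L)
    Xs = np.empty_like(L)
    for j in range(X.shape[1]):
        if smoothing:
            sp = make_smoothing_spline(t, L[:, j])
        else:
            sp = CubicSpline(t, L[:, j])
        Y[:, j] = sp.derivative()(t)
        Xs[:, j] = np.exp(sp(t))
    return Y, Xs


def _as_trajectories(traj: Trajectory | Sequence[Trajectory]) -> list[Trajectory]:
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if not trajs:
        raise ValueError("need at least one trajectory")
    taxa = trajs[0].taxa
    for tr in trajs[1:]:
        if tr.taxa != taxa:
            raise ValueError("all trajectories must share the same taxa, in order")
    return trajs


def _stack_design(
    trajs: Sequence[Trajectory], derivative: str
) -> tuple[np.ndarray, np.ndarray]:
    if derivative not in DERIVATIVE_SCHEMES:
        raise ValueError(f"derivative must be one of {DERIVATIVE_SCHEMES}")
    ys, zs = [], []
    for tr in trajs:
        if derivative == "fd":
            y, xs = log_derivatives(tr.times, tr.X), tr.X
        else:
            y, xs = spline_log_derivatives(tr.times, tr.X, smoothing=derivative == "smooth")
        ys.append(y)
        zs.append(np.column_stack([np.ones(tr.times.size), xs]))
    return np.vstack(ys), np.vstack(zs)


def _penalty(ridge: float, Z: np.ndarray, standardize: bool) -> np.ndarray:
    """Diagonal ridge penalty on the slopes only (intercept unpenalized).

    With ``standardize`` the penalty is scaled by each predictor's variance,
    making ``ridge`` unit-free (equivalent to ridge on standardized columns).
    """
    n = Z.shape[1] - 1
    if standardize:
        scales = Z[:, 1:].std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
        diag = np.concatenate([[0.0], scales**2])
    else:
        diag = np.concatenate([[0.0], np.ones(n)])
    return np.diag(diag) * ridge


def infer(
    traj: Trajectory | Sequence[Trajectory],
    ridge: float = 1e-3,
    derivative: str = "fd",
    standardize: bool = True,
    degenerate_tol: float = 1e-10,
) -> tuple[GLVModel, InferenceDiagnostics]:
    """Estimate ``r`` and ``A`` by gradient matching.

    For each taxon the response is the derivative of its log abundance
    (``derivative``: three-point finite differences, interpolating-spline
    or GCV smoothing-spline derivatives),
    regressed on ``[1, x_1 .. x_n]`` across all timepoints of one or more
    trajectories. The ridge penalty applies to the interaction slopes only,
    never the intercept. Under-determined problems (fewer than ``n + 2``
    timepoints per trajectory) are refused at ``ridge == 0``.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    trajs = _as_trajectories(traj)
    taxa = trajs[0].taxa
    n = len(taxa)
    rows = sum(tr.times.size for tr in trajs)
    for tr in trajs:
        if tr.times.size < 3:
            raise ValueError("each trajectory needs at least 3 timepoints")
    if rows - len(trajs) < n + 1 and ridge == 0:
        raise UnderdeterminedError(
            f"{rows} timepoints cannot identify {n * (n + 1)} parameters without "
            f"regularization; pass ridge > 0 (e.g. 1e-3)"
        )
    n_floored = sum(
        int(tr.floored.sum()) for tr in trajs if tr.floored is not None
    )
    Y, Z = _stack_design(trajs, derivative)
    if np.max(np.abs(Y)) < degenerate_tol:
        diag = InferenceDiagnostics(
            r_squared=np.zeros(n),
            condition_number=float("inf"),
            degenerate=True,
            n_floored=n_floored,
        )
        return GLVModel(taxa=list(taxa), r=np.zeros(n), A=np.zeros((n, n))), diag

    gram = Z.T @ Z + _penalty(ridge, Z, standardize)
    beta = np.linalg.solve(gram, Z.T @ Y)  # (n+1) x n, one column per taxon
    r = beta[0]
    A = beta[1:].T
    fitted = Z @ beta
    ss_res = ((Y - fitted) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1 - ss_res / ss_tot, 1.0)
    diag = InferenceDiagnostics(
        r_squared=r2,
        condition_number=float(np.linalg.cond(Z)),
        degenerate=False,
        n_floored=n_floored,
    )
    return GLVModel(taxa=list(taxa), r=r, A=A), diag


def select_ridge_loo(
    traj: Trajectory | Sequence[Trajectory],
    candidates: Sequence[float] | None = None,
    derivative: str = "fd",
    standardize: bool = True,
) -> float:
    """Ridge penalty minimizing leave-one-timepoint-out squared error.

    Uses the closed-form ridge leave-one-out residuals (hat-matrix
    shortcut) over the stacked regression rows.
    """
    if candidates is None:
        candidates = np.logspace(-6, 1, 8)
    trajs = _as_trajectories(traj)
    Y, Z = _stack_design(trajs, derivative)
    best_lam, best_err = float(candidates[0]), np.inf
    for lam in candidates:
        gram = Z.T @ Z + _penalty(float(lam), Z, standardize)
        try:
            ginv = np.linalg.inv(gram)
        except np.linalg.LinAlgError:
            continue
        beta = ginv @ (Z.T @ Y)
        resid = Y - Z @ beta
        leverage = np.einsum("ij,jk,ik->i", Z, ginv, Z)
        leverage = np.clip(leverage, None, 1 - 1e-12)
        err = float(((resid / (1 - leverage[:, None])) ** 2).sum())
        if err < best_err:
            best_err, best_lam = err, float(lam)
    return best_lam


def classify_signs(model: GLVModel, epsilon: float = 0.0) -> SignMatrix:
    """Ternarize A: +1 above ``eps * s``, -1 below ``-eps * s``, else 0.

    The scale ``s`` is the median |a_ij| over nonzero entries, so ``eps`` is
    unit-free; ``eps = 0`` reduces to the exact algebraic sign.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    A = model.A
    nonzero = np.abs(A[A != 0])
    scale = float(np.median(nonzero)) if nonzero.size else 0.0
    thr = epsilon * scale
    signs = np.zeros_like(A, dtype=int)
    signs[A > thr] = 1
    signs[A < -thr] = -1
    return SignMatrix(signs=signs, taxa=list(model.taxa), epsilon=epsilon)


def count_interactions(s: SignMatrix, label: str | None = None) -> InteractionSummary:
    """Tally signs over all n^2 ordered entries, diagonal included."""
    return InteractionSummary(
        positive=int((s.signs == 1).sum()),
        negative=int((s.signs == -1).sum()),
        neutral=int((s.signs == 0).sum()),
        label=label,
    )


def _check_compatible(a: SignMatrix, b: SignMatrix) -> None:
    if a.signs.shape != b.signs.shape or a.taxa != b.taxa:
        raise ValueError("sign matrices must share shape and taxon ordering")


def shared_interactions(a: SignMatrix, b: SignMatrix) -> int:
    """Number of ordered entries with identical sign in both matrices."""
    _check_compatible(a, b)
    return int((a.signs == b.signs).sum())


def unique_interactions(target: SignMatrix, others: Sequence[SignMatrix]) -> int:
    """Entries whose sign in ``target`` differs from EVERY other matrix."""
    if not others:
        raise ValueError("need at least one comparison matrix")
    for o in others:
        _check_compatible(target, o)
    differs = np.ones_like(target.signs, dtype=bool)
    for o in others:
        differs &= target.signs != o.signs
    return int(differs.sum())
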