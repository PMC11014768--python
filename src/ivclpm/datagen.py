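"""Stationary bivariate time-series generator with instrumental variables.

The generating process is a first-order, time-homogeneous vector
autoregression for Z_t = (X_t, Y_t) with two standardized, possibly
correlated instruments V = (IVx, IVy) that act on their trait at every
occasion:

    Z_t = B Z_{t-1} + C V + e_t,      t = 2, ..., T
    Z_1 = C V + e_1

with lag matrix B = [[bX2X1, bXY], [bYX, bY2Y1]], instrument loading
C = diag(bX, bY), Cov(V) = [[1, rIV], [rIV, 1]] and occasion residuals
e_t with variances (resid_var_x, resid_var_y) and cross-sectional
correlation rexy.  Only lagged paths connect X and Y, consistent with
the cause preceding the outcome in the true process.

The module offers closed-form stationary moments (linear solves of the
fixed-point equations), the occasion-wise covariance recursion with a
consecutive-difference stationarity criterion, the full (2 + 2T)-variable
RAM representation, two-wave moment extraction at an arbitrary lag, and
exact-moment ("empirical") multivariate-normal sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_discrete_lyapunov

from .ram import MomentSet, RAMSpec

__all__ = [
    "DataGenParams",
    "NonStationaryError",
    "StationaryState",
    "stationary_moments",
    "detect_stationarity",
    "build_full_ram",
    "two_wave_moments",
    "exact_sample",
    "iv_r_squared",
]

TWO_WAVE_LABELS = ["IVx", "IVy", "X1", "Y1", "X2", "Y2"]


class NonStationaryError(ValueError):
    """The lag matrix has spectral radius >= 1: no stationary limit exists."""


@dataclass(frozen=True)
class DataGenParams:
    """Coefficients, residual structure, IV structure and length of the
    generating process.

    Defaults follow the simulation design this generator emulates:
    unit residual variances per occasion, T = 150 occasions, N = 1000.
    """

    bYX: float = 0.2          # lag-1 causal effect X -> Y
    bXY: float = 0.2          # lag-1 causal effect Y -> X
    bX2X1: float = 0.7        # AR(1) of X
    bY2Y1: float = 0.7        # AR(1) of Y
    rexy: float = 0.3         # cross-sectional residual correlation
    bX: float = 0.08          # per-occasion effect IVx -> X
    bY: float = 0.08          # per-occasion effect IVy -> Y
    rIV: float = 0.25         # correlation of the two instruments
    resid_var_x: float = 1.0
    resid_var_y: float = 1.0
    T: int = 150              # number of occasions
    N: int = 1000             # nominal sample size

    def __post_init__(self) -> None:
        if abs(self.rexy) >= 1 or abs(self.rIV) >= 1:
            raise ValueError("|rexy| and |rIV| must be < 1")
        if self.resid_var_x <= 0 or self.resid_var_y <= 0:
            raise ValueError("residual variances must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if np.max(np.abs(np.linalg.eigvals(self.lag_matrix))) >= 1:
            raise NonStationaryError(
                "spectral radius of the lag matrix is >= 1; the process has no "
                "stationary limit"
            )

    # -- structural pieces ----------------------------------------------

    @property
    def lag_matrix(self) -> np.ndarray:
        """B: rows receive, columns send — [[bX2X1, bXY], [bYX, bY2Y1]]."""
        return np.array([[self.bX2X1, self.bXY], [self.bYX, self.bY2Y1]])

    @property
    def iv_loading(self) -> np.ndarray:
        return np.diag([self.bX, self.bY])

    @property
    def iv_cov(self) -> np.ndarray:
        return np.array([[1.0, self.rIV], [self.rIV, 1.0]])

    @property
    def resid_cov(self) -> np.ndarray:
        c = self.rexy * np.sqrt(self.resid_var_x * self.resid_var_y)
        return np.array([[self.resid_var_x, c], [c, self.resid_var_y]])

    # -- config IO -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "DataGenParams":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "DataGenParams":
        """Read parameters from a YAML or JSON config file."""
        text = Path(path).read_text()
        d = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StationaryState:
    """Stationary moments of (X, Y) and their covariances with the IVs."""

    q: np.ndarray            # 2x2 Cov((X, Y), (IVx, IVy))
    P: np.ndarray            # 2x2 Cov((X, Y))
    stat_index: int          # first occasion meeting the stationarity criterion
    _params: DataGenParams = field(repr=False)

    def lag_cov(self, k: int) -> np.ndarray:
        """Cov(Z_{t+k}, Z_t) at stationarity; k = 0 returns P."""
        if k < 0:
            raise ValueError("lag k must be non-negative")
        B, C = self._params.lag_matrix, self._params.iv_loading
        L = self.P.copy()
        cq = C @ self.q.T
        for _ in range(k):
            L = B @ L + cq
        return L


def _recursion_step(
    params: DataGenParams, q: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One occasion of the covariance recursion: (q_i, P_i) -> (q_{i+1}, P_{i+1})."""
    B, C = params.lag_matrix, params.iv_loading
    Svv, Psi = params.iv_cov, params.resid_cov
    q_next = B @ q + C @ Svv
    P_next = B @ P @ B.T + B @ q @ C.T + C @ q.T @ B.T + C @ Svv @ C.T + Psi
    return q_next, 0.5 * (P_next + P_next.T)


def _first_occasion(params: DataGenParams) -> tuple[np.ndarray, np.ndarray]:
    """Moments of Z_1 = C V + e_1 (no autoregressive input at occasion 1)."""
    C, Svv, Psi = params.iv_loading, params.iv_cov, params.resid_cov
    return C @ Svv, C @ Svv @ C.T + Psi


def detect_stationarity(params: DataGenParams, tol: float = 1e-4, max_iter: int = 100_000) -> int:
    """First occasion index i >= 2 at which every monitored element of the
    cross-sectional covariance of (IVx, IVy, X_i, Y_i) changes by < tol
    in absolute value from occasion i - 1.

    The monitored set is all ten unique elements of that 4x4 matrix: the
    IV block is constant, so the criterion effectively tracks q_i and P_i.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    q, P = _first_occasion(params)
    for i in range(2, max_iter):
        q_next, P_next = _recursion_step(params, q, P)
        delta = max(np.abs(q_next - q).max(), np.abs(P_next - P).max())
        q, P = q_next, P_next
        if delta < tol:
            return i
    raise RuntimeError("stationarity criterion not met within max_iter occasions")


def stationary_moments(params: DataGenParams, tol: float = 1e-4) -> StationaryState:
    """Stationary moments by direct linear solves (no iteration).

    q solves q = B q + C Svv, i.e. q = (I - B)^-1 C Svv; P solves the
    discrete-Lyapunov fixed point P = B P B' + Q with
    Q = B q C' + C q' B' + C Svv C' + Psi.
    """
    B, C = params.lag_matrix, params.iv_loading
    Svv, Psi = params.iv_cov, params.resid_cov
    q = np.linalg.solve(np.eye(2) - B, C @ Svv)
    Q = B @ q @ C.T + C @ q.T @ B.T + C @ Svv @ C.T + Psi
    P = solve_discrete_lyapunov(B, Q)
    P = 0.5 * (P + P.T)
    return StationaryState(q=q, P=P, stat_index=detect_stationarity(params, tol), _params=params)


def iv_r_squared(params: DataGenParams) -> float:
    """R^2 of the regression of X on IVx in the stationary model.

    IVx is standardized (unit variance), so R^2 = Cov(X, IVx)^2 / Var(X).
    """
    st = stationary_moments(params)
    return float(st.q[0, 0] ** 2 / (st.P[0, 0] * params.iv_cov[0, 0]))


def build_full_ram(params: DataGenParams) -> RAMSpec:
    """The full generating model as a RAM spec over (IVx, IVy, X_1..X_T,
    Y_1..Y_T); dimension m = 2 (1 + T).  All entries are fixed at the
    generating values (no free parameters)."""
    T = params.T
    labels = ["IVx", "IVy"] + [f"X{t}" for t in range(1, T + 1)] + [f"Y{t}" for t in range(1, T + 1)]
    m = 2 * (1 + T)
    A = np.zeros((m, m))
    S = np.zeros((m, m))
    ix = lambda t: 2 + (t - 1)          # X_t row
    iy = lambda t: 2 + T + (t - 1)      # Y_t row
    S[:2, :2] = params.iv_cov
    rc = params.rexy * np.sqrt(params.resid_var_x * params.resid_var_y)
    for t in range(1, T + 1):
        A[ix(t), 0] = params.bX
        A[iy(t), 1] = params.bY
        S[ix(t), ix(t)] = params.resid_var_x
        S[iy(t), iy(t)] = params.resid_var_y
        S[ix(t), iy(t)] = S[iy(t), ix(t)] = rc
        if t > 1:
            A[ix(t), ix(t - 1)] = params.bX2X1
            A[ix(t), iy(t - 1)] = params.bXY
            A[iy(t), ix(t - 1)] = params.bYX
            A[iy(t), iy(t - 1)] = params.bY2Y1
    return RAMSpec(labels=labels, A=A.astype(object), S=S.astype(object),
                   M=np.zeros(m, dtype=object), free_params=[])


def two_wave_moments(params: DataGenParams, dT: int, t1: int = 100) -> MomentSet:
    """Exact moments of (IVx, IVy, X1, Y1, X2, Y2) with wave 1 at occasion
    t1 and wave 2 at occasion t1 + dT, from the occasion-wise recursion.

    Requires t1 at or beyond the stationarity index (so the two-wave
    moments depend on the interval dT, not on t1 itself) and
    t1 + dT <= T.
    """
    if dT < 1:
        raise ValueError("dT must be a positive integer")
    if t1 + dT > params.T:
        raise ValueError(
            f"wave 2 at occasion {t1 + dT} exceeds the series length T={params.T}"
        )
    if t1 < detect_stationarity(params):
        raise ValueError(
            f"wave 1 at occasion {t1} precedes the stationarity index "
            f"{detect_stationarity(params)}"
        )
    # exact occasion moments by recursion from occasion 1
    q, P = _first_occasion(params)
    for _ in range(2, t1 + 1):
        q, P = _recursion_step(params, q, P)
    q1, P1 = q, P
    # cross-lag block Cov(Z_{t1+k}, Z_{t1}) and wave-2 own moments
    B, C = params.lag_matrix, params.iv_loading
    L = P1.copy()
    for _ in range(dT):
        L = B @ L + C @ q1.T
    q2, P2 = q1, P1
    for _ in range(dT):
        q2, P2 = _recursion_step(params, q2, P2)
    cov = np.zeros((6, 6))
    cov[:2, :2] = params.iv_cov
    cov[2:4, :2] = q1
    cov[4:6, :2] = q2
    cov[2:4, 2:4] = P1
    cov[4:6, 4:6] = P2
    cov[4:6, 2:4] = L
    cov[:2, 2:4] = q1.T
    cov[:2, 4:6] = q2.T
    cov[2:4, 4:6] = L.T
    return MomentSet(labels=list(TWO_WAVE_LABELS), cov=cov, means=np.zeros(6), n=params.N)


def exact_sample(moments: MomentSet, seed: int) -> pd.DataFrame:
    """A dataset of ``moments.n`` rows whose unbiased (n-1 divisor) sample
    covariance equals ``moments.cov`` and whose sample means equal
    ``moments.means``, to machine precision.

    Construction: draw standard-normal deviates, center, whiten by the
    empirical covariance factor, then recolor by the Cholesky factor of
    the target covariance.
    """
    p, n = moments.p, moments.n
    if n <= p:
        raise ValueError("n must exceed the number of variables for exact sampling")
    eigvals = np.linalg.eigvalsh(moments.cov)
    if eigvals[0] <= 0:
        raise ValueError(
            f"target covariance is not positive-definite (smallest eigenvalue "
            f"{eigvals[0]:.3e})"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    s_emp = (z.T @ z) / (n - 1)
    l_emp = np.linalg.cholesky(s_emp)
    l_tgt = np.linalg.cholesky(moments.cov)
    # whiten (solve against the empirical factor), then recolor
    white = np.linalg.solve(l_emp, z.T).T
    data = white @ l_tgt.T + moments.means
    return pd.DataFrame(data, columns=moments.labels)
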