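"""Shared fixtures and the independent path-tracing oracle.

The oracle computes model-implied moments by summing products of path
coefficients over tracing routes — the total-effect matrix is accumulated
as the series I + A + A^2 + ... (finite for acyclic path diagrams,
convergent when reciprocal loops have product < 1) — never by inverting
(I - A), so it is independent of the RAM engine it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ivclpm import DataGenParams


def path_tracing_moments(A: np.ndarray, S: np.ndarray, m: np.ndarray,
                         max_terms: int = 10_000, tol: float = 1e-14):
    """Covariance and means by route enumeration (powers of A)."""
    p = A.shape[0]
    total = np.eye(p)
    term = np.eye(p)
    for _ in range(max_terms):
        term = term @ A
        if np.abs(term).max() < tol:
            break
        total += term
    else:
        raise RuntimeError("path series did not converge; loop product >= 1?")
    return total @ S @ total.T, total @ m


@pytest.fixture(scope="session")
def low_ar_params() -> DataGenParams:
    """Low-AR bidirectional generating set (instrument R^2 of 2.09%)."""
    return DataGenParams(bYX=0.1, bXY=0.1, bX2X1=0.5, bY2Y1=0.5,
                         rexy=0.3, bX=0.08, bY=0.08, rIV=0.25)


@pytest.fixture(scope="session")
def high_ar_params() -> DataGenParams:
    """High-AR bidirectional generating set (instrument R^2 of 8.03%)."""
    return DataGenParams(bYX=0.2, bXY=0.2, bX2X1=0.7, bY2Y1=0.7,
                         rexy=0.1, bX=0.08, bY=0.08, rIV=0.25)


@pytest.fixture(scope="session")
def unidirectional_params() -> DataGenParams:
    """Unidirectional X -> Y generating set (instrument R^2 of 8.26%)."""
    return DataGenParams(bYX=0.4, bXY=0.0, bX2X1=0.8, bY2Y1=0.8,
                         rexy=0.3, bX=0.1, bY=0.1, rIV=0.0)


@pytest.fixture(scope="session")
def figure_set_params() -> DataGenParams:
    """The reference parameter set for the interval-sweep figures
    (bYX = bXY = 0.2, AR 0.7/0.7, rexy = 0.3)."""
    return DataGenParams(bYX=0.2, bXY=0.2, bX2X1=0.7, bY2Y1=0.7,
                         rexy=0.3, bX=0.08, bY=0.08, rIV=0.25)


IVCLPM_THETA = {
    "bx1": 0.2, "bx2": 0.1, "by1": 0.25, "by2": 0.05,
    "bY1X1": 0.3, "bX1Y1": 0.15, "bY2X1": 0.2, "bX2Y1": 0.1,
    "bY2X2": 0.12, "bX2Y2": 0.08, "bX2X1": 0.5, "bY2Y1": 0.45,
    "Vpx": 1.0, "Vpy": 1.0, "Cixiy": 0.25,
    "Vx1": 1.0, "Vy1": 1.2, "Cx1y1": 0.3,
    "Vx2": 0.9, "Vy2": 1.1, "Cx2y2": 0.2,
}


@pytest.fixture(scope="session")
def ivclpm_theta() -> dict[str, float]:
    """An admissible IV-CLPM parameter point used as a generating truth."""
    theta = dict(IVCLPM_THETA)
    theta.update({f"b0_{v}": 0.0 for v in ("IVx", "IVy", "X1", "Y1", "X2", "Y2")})
    return theta
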