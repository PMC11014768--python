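"""RAM (Reticular Action Model) representation of recursive path models.

A path model over ``p`` observed variables is held as three templates:

* ``A`` — directed regression paths, column-to-row convention
  (``A[i, j]`` is the path from variable ``j`` to variable ``i``);
* ``S`` — symmetric (co)variances of the exogenous parts and residuals;
* ``M`` — intercepts.

Template entries are either fixed reals or parameter-name strings.  Given
a value for every named parameter the model-implied moments are

    Sigma = (I - A)^-1 S (I - A)^-T
    mu    = (I - A)^-1 m

All modeled variables here are observed (residual variances live on the
diagonal of ``S``), so no filter/selection matrix is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Parameter",
    "RAMSpec",
    "MomentSet",
    "SingularStructuralMatrix",
    "MissingParameterError",
    "expected_covariance",
    "expected_means",
]

Entry = float | str  # template entry: fixed value or parameter name


class SingularStructuralMatrix(ValueError):
    """Raised when (I - A) is numerically singular at the given theta."""


class MissingParameterError(KeyError):
    """Raised when theta does not assign a value to a free parameter."""


@dataclass(frozen=True)
class Parameter:
    """A free parameter: name, optimizer start value, optional lower bound."""

    name: str
    start: float = 0.1
    lower: float | None = None


def _as_template(rows: Sequence[Sequence[Entry]]) -> np.ndarray:
    arr = np.empty((len(rows), len(rows[0])), dtype=object)
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            arr[i, j] = v if isinstance(v, str) else float(v)
    return arr


def _template_names(arr: np.ndarray) -> set[str]:
    return {v for v in arr.ravel() if isinstance(v, str)}


@dataclass
class RAMSpec:
    """A parameterized path model in RAM form."""

    labels: list[str]
    A: np.ndarray  # object array: float or parameter-name string
    S: np.ndarray
    M: np.ndarray  # 1-d object array
    free_params: list[Parameter] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        p = len(self.labels)
        self.A = _as_template(self.A) if self.A.dtype != object else self.A
        self.S = _as_template(self.S) if self.S.dtype != object else self.S
        m = np.empty(p, dtype=object)
        for i, v in enumerate(np.asarray(self.M, dtype=object).ravel()):
            m[i] = v if isinstance(v, str) else float(v)
        self.M = m
        if self.A.shape != (p, p) or self.S.shape != (p, p) or self.M.shape != (p,):
            raise ValueError("template shapes must match the number of labels")
        # S symmetric as a template; fixed diagonal entries non-negative
        for i in range(p):
            for j in range(p):
                if self.S[i, j] != self.S[j, i]:
                    raise ValueError(
                        f"S template not symmetric at ({self.labels[i]}, {self.labels[j]})"
                    )
            d = self.S[i, i]
            if not isinstance(d, str) and d < 0:
                raise ValueError(f"fixed variance of {self.labels[i]} is negative")
        names = [par.name for par in self.free_params]
        if len(names) != len(set(names)):
            raise ValueError("duplicate free parameter names")
        used = _template_names(self.A) | _template_names(self.S) | _template_names(self.M)
        missing = used - set(names)
        if missing:
            raise ValueError(f"template parameters not in free_params: {sorted(missing)}")
        unused = set(names) - used
        if unused:
            raise ValueError(f"free parameters unused in templates: {sorted(unused)}")

    # -- materialization -------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def param_names(self) -> list[str]:
        return [par.name for par in self.free_params]

    def start_values(self) -> dict[str, float]:
        return {par.name: par.start for par in self.free_params}

    def _fill(self, template: np.ndarray, theta: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(template.shape, dtype=float)
        it = np.nditer(np.empty(template.shape), flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            v = template[idx]
            if isinstance(v, str):
                try:
                    out[idx] = theta[v]
                except KeyError as exc:
                    raise MissingParameterError(
                        f"no value supplied for free parameter {v!r}"
                    ) from exc
            else:
                out[idx] = v
        return out

    def matrices(
        self, theta: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Numeric (A, S, m) at the given parameter values."""
        return self._fill(self.A, theta), self._fill(self.S, theta), self._fill(self.M, theta)

    def expected_covariance(self, theta: Mapping[str, float]) -> np.ndarray:
        A, S = self._fill(self.A, theta), self._fill(self.S, theta)
        iva = _inv_i_minus_a(A)
        sigma = iva @ S @ iva.T
        return 0.5 * (sigma + sigma.T)  # symmetrize roundoff

    def expected_means(self, theta: Mapping[str, float]) -> np.ndarray:
        A, m = self._fill(self.A, theta), self._fill(self.M, theta)
        return _inv_i_minus_a(A) @ m

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "A": self.A.tolist(),
                "S": self.S.tolist(),
                "M": self.M.tolist(),
                "free_params": [
                    {"name": q.name, "start": q.start, "lower": q.lower}
                    for q in self.free_params
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RAMSpec":
        d = json.loads(text)
        return cls(
            labels=d["labels"],
            A=_as_template(d["A"]),
            S=_as_template(d["S"]),
            M=np.asarray(d["M"], dtype=object),
            free_params=[Parameter(q["name"], q["start"], q.get("lower")) for q in d["free_params"]],
        )


def _inv_i_minus_a(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    ima = np.eye(p) - A
    # reciprocal condition check: singular structural matrix is a user error
    if np.linalg.cond(ima) > 1e12:
        raise SingularStructuralMatrix(
            "structural matrix (I - A) is singular or near-singular at theta"
        )
    return np.linalg.inv(ima)


def expected_covariance(spec: RAMSpec, theta: Mapping[str, float]) -> np.ndarray:
    """Model-implied covariance Sigma = (I-A)^-1 S (I-A)^-T."""
    return spec.expected_covariance(theta)


def expected_means(spec: RAMSpec, theta: Mapping[str, float]) -> np.ndarray:
    """Model-implied means mu = (I-A)^-1 m."""
    return spec.expected_means(theta)


@dataclass
class MomentSet:
    """Sample (or population) moments: covariance, means, labels, and N.

    The universal fitting input — models are fitted to a ``MomentSet``
    whether it came from raw data, the data generator, or a file.
    """

    labels: list[str]
    cov: np.ndarray
    means: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.cov = np.asarray(self.cov, dtype=float)
        self.means = np.asarray(self.means, dtype=float).ravel()
        p = len(self.labels)
        if self.cov.shape != (p, p):
            raise ValueError("cov dimensions must match labels")
        if self.means.shape != (p,):
            raise ValueError("means length must match labels")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12, rtol=0.0):
            raise ValueError("cov must be symmetric to within 1e-12")
        if int(self.n) < 1:
            raise ValueError("n must be a positive integer")
        self.n = int(self.n)

    @property
    def p(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "MomentSet":
        """Moments restricted (and reordered) to the given labels."""
        idx = [self.labels.index(v) for v in labels]
        return MomentSet(
            labels=list(labels),
            cov=self.cov[np.ix_(idx, idx)],
            means=self.means[idx],
            n=self.n,
        )

    @classmethod
    def from_dataframe(cls, df, n: int | None = None, ddof: int = 1) -> "MomentSet":
        """Moments of a complete-case data table (default unbiased, n-1).

        The n-1 divisor pairs with :func:`ivclpm.datagen.exact_sample`, whose
        output matches the unbiased sample covariance exactly, so that
        sample -> moments -> fit round-trips reproduce generating values.
        """
        x = np.asarray(df, dtype=float)
        if np.isnan(x).any():
            raise ValueError("data table contains missing values; complete cases required")
        labels = list(df.columns)
        return cls(
            labels=labels,
            cov=np.cov(x, rowvar=False, ddof=ddof),
            means=x.mean(axis=0),
            n=n if n is not None else x.shape[0],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "cov": self.cov.tolist(),
                "means": self.means.tolist(),
                "n": self.n,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MomentSet":
        d = json.loads(text)
        return cls(labels=d["labels"], cov=np.asarray(d["cov"]), means=np.asarray(d["means"]), n=d["n"])
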