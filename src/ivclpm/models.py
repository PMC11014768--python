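"""Builders for the three analysis models.

* :func:`build_clpm` — the two-wave cross-lagged panel model over
  (X1, Y1, X2, Y2): two autoregressive and two lagged ("distal") paths.
* :func:`build_ivr` — cross-sectional instrumental-variables regression
  over (IVx, X, Y): the instrument identifies the causal path X -> Y
  alongside a free residual covariance.
* :func:`build_iv_clpm` — the CLPM augmented with one instrument per
  trait, applying the IVR cross-sectionally at each wave.  In the
  bidirectional form this adds reciprocal "proximal" paths at each wave
  (X1 <-> Y1 and X2 <-> Y2, each direction a separate parameter) on top
  of the distal paths; the reciprocal pairs make A non-triangular, and
  the instruments provide the identification.  The unidirectional form
  drops IVy and every Y -> X causal path.

Causal parameters are classified by timing: ``proximal_w1`` (cumulative
causation up to wave 1), ``distal`` (lagged, across the between-wave
interval) and ``proximal_w2`` (between-wave causation not captured by
the distal path), each with ``x_to_y`` / ``y_to_x`` roles.  Restricted
variants for likelihood-ratio testing are derived by fixing named causal
parameters to zero with :func:`apply_restrictions`.

Intercepts are always freely estimated (saturated means), so mean
modeling never affects covariance-structure comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ram import Parameter, RAMSpec

__all__ = ["ModelSpec", "build_clpm", "build_ivr", "build_iv_clpm", "apply_restrictions"]

CausalMap = dict[str, dict[str, str]]


@dataclass
class ModelSpec:
    """A RAM path model plus the roster of its causal parameters."""

    ram: RAMSpec
    causal_params: CausalMap
    family: str          # "clpm" | "ivr" | "ivclpm"
    direction: str       # "bidirectional" | "unidirectional"
    restricted: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = set(self.ram.param_names)
        for timing, roles in self.causal_params.items():
            for role, name in roles.items():
                if name not in names and name not in self.restricted:
                    raise ValueError(
                        f"causal parameter {name!r} ({timing}/{role}) is not a "
                        "free parameter of the model"
                    )

    @property
    def causal_names(self) -> list[str]:
        out = []
        for roles in self.causal_params.values():
            out.extend(roles.values())
        return [n for n in out if n not in self.restricted]

    def causal(self, timing: str, role: str) -> str:
        """Name of a causal parameter, e.g. ``causal('distal', 'x_to_y')``."""
        return self.causal_params[timing][role]

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "direction": self.direction,
                "restricted": list(self.restricted),
                "causal_params": self.causal_params,
                "ram": json.loads(self.ram.to_json()),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            ram=RAMSpec.from_json(json.dumps(d["ram"])),
            causal_params=d["causal_params"],
            family=d["family"],
            direction=d["direction"],
            restricted=tuple(d["restricted"]),
        )


def _spec(labels, paths, covs, free_regressions, free_covs, intercept_prefix="b0"):
    """Assemble a RAMSpec from path and covariance dictionaries.

    ``paths``: {(to, from): name-or-value}; ``covs``: {(a, b): name-or-value}.
    """
    p = len(labels)
    idx = {v: i for i, v in enumerate(labels)}
    A = np.zeros((p, p), dtype=object)
    A[:] = 0.0
    S = np.zeros((p, p), dtype=object)
    S[:] = 0.0
    for (to, frm), entry in paths.items():
        A[idx[to], idx[frm]] = entry
    for (a, b), entry in covs.items():
        S[idx[a], idx[b]] = entry
        S[idx[b], idx[a]] = entry
    M = np.empty(p, dtype=object)
    intercepts = []
    for i, v in enumerate(labels):
        name = f"{intercept_prefix}_{v}"
        M[i] = name
        intercepts.append(Parameter(name, 0.0))
    free = (
        [Parameter(n, 0.1) for n in free_regressions]
        + [Parameter(n, 1.0 if n.startswith("V") else 0.0) for n in free_covs]
        + intercepts
    )
    return RAMSpec(labels=list(labels), A=A, S=S, M=M, free_params=free)


def build_clpm() -> ModelSpec:
    """The traditional two-wave CLPM: bidirectional lagged effects
    (bY2X1, bX2Y1), AR(1) paths, free wave-specific (co)variances.

    Covariance-structure free-parameter count is 10, equal to the number
    of unique moments of 4 variables: the model is just-identified.
    """
    labels = ["X1", "Y1", "X2", "Y2"]
    paths = {
        ("X2", "X1"): "bX2X1",
        ("Y2", "Y1"): "bY2Y1",
        ("Y2", "X1"): "bY2X1",   # distal X -> Y
        ("X2", "Y1"): "bX2Y1",   # distal Y -> X
    }
    covs = {
        ("X1", "X1"): "Vx1", ("Y1", "Y1"): "Vy1", ("X1", "Y1"): "Cx1y1",
        ("X2", "X2"): "Vx2", ("Y2", "Y2"): "Vy2", ("X2", "Y2"): "Cx2y2",
    }
    ram = _spec(labels, paths, covs,
                ["bX2X1", "bY2Y1", "bY2X1", "bX2Y1"],
                ["Vx1", "Vy1", "Cx1y1", "Vx2", "Vy2", "Cx2y2"])
    return ModelSpec(
        ram=ram,
        causal_params={"distal": {"x_to_y": "bY2X1", "y_to_x": "bX2Y1"}},
        family="clpm",
        direction="bidirectional",
    )


def build_ivr() -> ModelSpec:
    """Cross-sectional IV regression over (IVx, X, Y): the causal path
    bYX is identified by the instrument, with a free residual covariance
    CovExy absorbing confounding.  Just-identified (6 parameters, 6
    moments); the ML estimate of bYX equals the IV-ratio
    Cov(IVx, Y) / Cov(IVx, X).
    """
    labels = ["IVx", "X", "Y"]
    paths = {("X", "IVx"): "bX", ("Y", "X"): "bYX"}
    covs = {
        ("IVx", "IVx"): "Vivx",
        ("X", "X"): "Vex", ("Y", "Y"): "Vey", ("X", "Y"): "CovExy",
    }
    ram = _spec(labels, paths, covs, ["bX", "bYX"], ["Vivx", "Vex", "Vey", "CovExy"])
    return ModelSpec(
        ram=ram,
        causal_params={"proximal_w1": {"x_to_y": "bYX"}},
        family="ivr",
        direction="unidirectional",
    )


def build_iv_clpm(bidirectional: bool = True) -> ModelSpec:
    """The IV-augmented CLPM.

    Bidirectional: 6 observed variables (IVx, IVy, X1, Y1, X2, Y2); free
    are 4 IV paths (bx1, bx2, by1, by2), the reciprocal proximal pairs at
    each wave, the two distal paths, the two AR(1) paths, and 9
    (co)variances — 21 covariance-structure parameters for 21 unique
    moments (just-identified).

    Unidirectional: drops IVy and every Y -> X causal path, keeping the
    proximal X -> Y effect at both waves and the distal X -> Y effect
    (14 parameters vs 15 moments; 1 df over-identified).
    """
    if bidirectional:
        labels = ["IVx", "IVy", "X1", "Y1", "X2", "Y2"]
        paths = {
            ("X1", "IVx"): "bx1", ("X2", "IVx"): "bx2",
            ("Y1", "IVy"): "by1", ("Y2", "IVy"): "by2",
            ("Y1", "X1"): "bY1X1", ("X1", "Y1"): "bX1Y1",   # proximal wave 1
            ("Y2", "X1"): "bY2X1", ("X2", "Y1"): "bX2Y1",   # distal
            ("Y2", "X2"): "bY2X2", ("X2", "Y2"): "bX2Y2",   # proximal wave 2
            ("X2", "X1"): "bX2X1", ("Y2", "Y1"): "bY2Y1",   # AR(1)
        }
        covs = {
            ("IVx", "IVx"): "Vpx", ("IVy", "IVy"): "Vpy", ("IVx", "IVy"): "Cixiy",
            ("X1", "X1"): "Vx1", ("Y1", "Y1"): "Vy1", ("X1", "Y1"): "Cx1y1",
            ("X2", "X2"): "Vx2", ("Y2", "Y2"): "Vy2", ("X2", "Y2"): "Cx2y2",
        }
        ram = _spec(
            labels, paths, covs,
            ["bx1", "bx2", "by1", "by2", "bY1X1", "bX1Y1", "bY2X1", "bX2Y1",
             "bY2X2", "bX2Y2", "bX2X1", "bY2Y1"],
            ["Vpx", "Vpy", "Cixiy", "Vx1", "Vy1", "Cx1y1", "Vx2", "Vy2", "Cx2y2"],
        )
        causal = {
            "proximal_w1": {"x_to_y": "bY1X1", "y_to_x": "bX1Y1"},
            "distal": {"x_to_y": "bY2X1", "y_to_x": "bX2Y1"},
            "proximal_w2": {"x_to_y": "bY2X2", "y_to_x": "bX2Y2"},
        }
        return ModelSpec(ram=ram, causal_params=causal, family="ivclpm",
                         direction="bidirectional")
    labels = ["IVx", "X1", "Y1", "X2", "Y2"]
    paths = {
        ("X1", "IVx"): "bx1", ("X2", "IVx"): "bx2",
        ("Y1", "X1"): "bY1X1",
        ("Y2", "X1"): "bY2X1",
        ("Y2", "X2"): "bY2X2",
        ("X2", "X1"): "bX2X1", ("Y2", "Y1"): "bY2Y1",
    }
    covs = {
        ("IVx", "IVx"): "Vpx",
        ("X1", "X1"): "Vx1", ("Y1", "Y1"): "Vy1", ("X1", "Y1"): "Cx1y1",
        ("X2", "X2"): "Vx2", ("Y2", "Y2"): "Vy2", ("X2", "Y2"): "Cx2y2",
    }
    ram = _spec(
        labels, paths, covs,
        ["bx1", "bx2", "bY1X1", "bY2X1", "bY2X2", "bX2X1", "bY2Y1"],
        ["Vpx", "Vx1", "Vy1", "Cx1y1", "Vx2", "Vy2", "Cx2y2"],
    )
    causal = {
        "proximal_w1": {"x_to_y": "bY1X1"},
        "distal": {"x_to_y": "bY2X1"},
        "proximal_w2": {"x_to_y": "bY2X2"},
    }
    return ModelSpec(ram=ram, causal_params=causal, family="ivclpm",
                     direction="unidirectional")


def fix_parameters(ram: RAMSpec, values: dict[str, float]) -> RAMSpec:
    """A copy of ``ram`` with the named free parameters replaced by fixed
    values in the templates (and dropped from the free list)."""
    unknown = set(values) - set(ram.param_names)
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")

    def sub(template):
        out = template.copy()
        flat = out.ravel()
        for i, v in enumerate(flat):
            if isinstance(v, str) and v in values:
                flat[i] = float(values[v])
        return out

    return RAMSpec(
        labels=list(ram.labels),
        A=sub(ram.A),
        S=sub(ram.S),
        M=sub(ram.M),
        free_params=[q for q in ram.free_params if q.name not in values],
    )


def apply_restrictions(model: ModelSpec, names: list[str]) -> ModelSpec:
    """A copy of ``model`` with the named causal parameters fixed at zero.

    Used to form the nested comparison models of the likelihood-ratio
    hierarchy (6 df omnibus, 3 df per direction, joint 2 df, single 1 df).
    """
    if not names:
        return model
    valid = set(model.causal_names)
    unknown = [n for n in names if n not in valid]
    if unknown:
        raise ValueError(
            f"unknown or non-causal parameter(s) {unknown}; valid causal "
            f"parameters are {sorted(valid)}"
        )
    new_ram = fix_parameters(model.ram, {n: 0.0 for n in names})
    return ModelSpec(
        ram=new_ram,
        causal_params=model.causal_params,
        family=model.family,
        direction=model.direction,
        restricted=model.restricted + tuple(names),
    )
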