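"""Deterministic canonical fixtures for examples, tests and docs.

Everything is computed at run time from the default generating
parameters; the same seed always produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .datagen import (
    DataGenParams,
    detect_stationarity,
    exact_sample,
    iv_r_squared,
    stationary_moments,
    two_wave_moments,
)
from .ram import MomentSet

__all__ = ["generate_fixtures"]

SAMPLE_N = 200
FIXTURE_DT = 5


def generate_fixtures(seed: int, out_dir) -> list[Path]:
    """Write the canonical fixture set and return the file paths.

    * ``params.yaml`` — the default generating parameter set;
    * ``moments.json`` — exact 6-variable two-wave moments at dT = 5;
    * ``sample.csv`` — an exact-moment sample (n = 200) of those moments;
    * ``expected.json`` — stationary moments, stationarity indices and
      instrument R-squared values for the canonical parameter sets,
      recomputed (not stored constants).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = DataGenParams()
    written: list[Path] = []

    p_path = out / "params.yaml"
    p_path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
    written.append(p_path)

    moments = two_wave_moments(params, FIXTURE_DT)
    m_path = out / "moments.json"
    m_path.write_text(moments.to_json() + "\n")
    written.append(m_path)

    small = MomentSet(labels=moments.labels, cov=moments.cov, means=moments.means, n=SAMPLE_N)
    frame = exact_sample(small, seed=seed)
    s_path = out / "sample.csv"
    frame.to_csv(s_path, index=False, float_format="%.12g")
    written.append(s_path)

    canonical = {
        "low_ar_bidirectional": dict(bYX=0.1, bXY=0.1, bX2X1=0.5, bY2Y1=0.5,
                                     rexy=0.3, bX=0.08, bY=0.08, rIV=0.25),
        "high_ar_bidirectional": dict(bYX=0.2, bXY=0.2, bX2X1=0.7, bY2Y1=0.7,
                                      rexy=0.1, bX=0.08, bY=0.08, rIV=0.25),
        "unidirectional": dict(bYX=0.4, bXY=0.0, bX2X1=0.8, bY2Y1=0.8,
                               rexy=0.3, bX=0.1, bY=0.1, rIV=0.0),
    }
    expected: dict = {}
    for name, kw in canonical.items():
        ps = DataGenParams(**kw)
        st = stationary_moments(ps)
        expected[name] = {
            "params": kw,
            "stationary_cov_xy_iv": st.q.tolist(),
            "stationary_cov_xy": st.P.tolist(),
            "stationarity_index": detect_stationarity(ps),
            "iv_r_squared_pct": round(100 * iv_r_squared(ps), 6),
        }
    e_path = out / "expected.json"
    e_path.write_text(json.dumps(expected, indent=1, sort_keys=True) + "\n")
    written.append(e_path)
    return written
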