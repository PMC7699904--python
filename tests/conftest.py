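"""Shared fixtures: packaged case-study tables, default configs, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hypoxalert import (
    default_expert_config,
    default_technical_config,
    load_results,
    packaged_results_path,
)


@pytest.fixture(scope="session")
def technical_config():
    return default_technical_config()


@pytest.fixture(scope="session")
def expert_config():
    return default_expert_config()


@pytest.fixture(scope="session")
def case_study_rows():
    """The 30 printed (RT, RE, RG, states) rows of the case study."""
    return load_results(packaged_results_path())


@pytest.fixture(scope="session")
def case_study_rg(case_study_rows):
    return [r.global_risk for r in case_study_rows]


@pytest.fixture(scope="session")
def case_study_actual(case_study_rows):
    return [r.actual_emergency for r in case_study_rows]


def brute_force_defuzzify(shapes, lo, hi, n=1_000_001):
    """Independent dense-sampling centroid of a max-envelope of clipped trapezoids.

    ``shapes`` is a list of ``(activation, (a, b, c, d))``. Implemented with
    np.interp, sharing no code with the package's engine.
    """
    y = np.linspace(lo, hi, n)
    g = np.zeros_like(y)
    for act, (a, b, c, d) in shapes:
        xp, fp = [a, b, c, d], [0.0, 1.0, 1.0, 0.0]
        # np.interp needs strictly usable breakpoints; nudge degenerate edges
        eps = 1e-9 * max(1.0, abs(hi - lo))
        if a == b:
            xp[0] = a - eps
        if c == d:
            xp[3] = d + eps
        mu = np.interp(y, xp, fp, left=0.0, right=0.0)
        g = np.maximum(g, np.minimum(act, mu))
    assert g.sum() > 0
    return float(np.dot(y, g) / g.sum())
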