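"""Shared fixtures.

Pulse designs are expensive (minutes), so they are session-scoped and
shared between the unit tests and the acceptance tests:

* ``design_pulse_h`` / ``design_pulse_c`` — the locking pair used by the
  trajectory and sequence tests, designed on the default robustness grids
  augmented with on-resonance drift members (the conditions under which
  the locking demonstrations are evaluated).
* ``t4_pulse`` — the 1H pulse designed on exactly the prescribed
  5 drifts x 5 offsets x 3 B1 product grid, best of 3 restarts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from cohlock.cloc_design import OptimizationSpec, optimize_cloc


@pytest.fixture(scope="session")
def design_pair():
    spec_h = OptimizationSpec.proton_default(n_restarts=2)
    spec_h = replace(spec_h, ensemble=spec_h.ensemble.with_voxel_emphasis(12))
    pulse_h, report_h = optimize_cloc(spec_h)
    spec_c = OptimizationSpec.carbon_default(n_restarts=2)
    spec_c = replace(spec_c, ensemble=spec_c.ensemble.with_voxel_emphasis(12))
    pulse_c, report_c = optimize_cloc(spec_c)
    return {
        "pulse_h": pulse_h,
        "report_h": report_h,
        "spec_h": spec_h,
        "pulse_c": pulse_c,
        "report_c": report_c,
        "spec_c": spec_c,
    }


@pytest.fixture(scope="session")
def design_pulse_h(design_pair):
    return design_pair["pulse_h"]


@pytest.fixture(scope="session")
def design_pulse_c(design_pair):
    return design_pair["pulse_c"]


@pytest.fixture(scope="session")
def t4_design():
    """The acceptance-grid design: 5 x 5 x 3 ensemble, best of 3 restarts."""
    spec = OptimizationSpec.proton_default(n_restarts=3)
    pulse, report = optimize_cloc(spec)
    return {"pulse": pulse, "report": report, "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
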