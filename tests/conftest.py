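"""Shared fixtures.

The expensive session-scoped fixtures run small simulations once and are
reused by several physics tests (slab equilibria at three temperatures, an
equilibrated homogeneous fluid). Problem sizes are deliberately small: the
properties under test (monotonicity, isotropy, agreement within errors) are
robust at these sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from spidec import Box, MDParams, ModelSpec, run_md
from spidec.fixtures import preformed_slab_configuration

LJ_SLAB_TEMPERATURES = (0.65, 0.80, 0.95)


@pytest.fixture(scope="session")
def lj_model():
    return ModelSpec.lj_particle()


@pytest.fixture(scope="session")
def lj_slab_runs(lj_model):
    """LJ-particle slab equilibria at three temperatures (Lx=7, Lz/Lx=2.5).

    Started from a preformed central slab so no spinodal-decomposition wait
    is needed; the second half of each run samples two-phase equilibrium.
    """
    box = Box.rectangular(7.0, 2.5)
    out = {}
    for i, T in enumerate(LJ_SLAB_TEMPERATURES):
        cfg = preformed_slab_configuration(lj_model, box, 0.3, seed=40 + i)
        params = MDParams(
            n_steps=50_000,
            temperature=T,
            save_interval=2_000,
            seed=140 + i,
            limit_steps=2_000,
        )
        out[T] = run_md(cfg, lj_model, params)
    return out


@pytest.fixture(scope="session")
def lj_fluid_run(lj_model):
    """Equilibrated homogeneous (supercritical) LJ fluid, T=1.5, rho=0.5.

    Friction 1.0 decorrelates the kinetic energy quickly, giving tight
    statistics on temperature and pressure isotropy from a short run.
    """
    from spidec.configuration import random_insert

    box = Box.rectangular(8.0, 1.0)
    cfg = random_insert(lj_model, box, 0.5, seed=21)
    warm = run_md(
        cfg,
        lj_model,
        MDParams(n_steps=10_000, temperature=1.5, friction=1.0,
                 save_interval=10_000, seed=22),
    )
    return run_md(
        warm.final,
        lj_model,
        MDParams(
            n_steps=30_000,
            temperature=1.5,
            friction=1.0,
            save_interval=500,
            seed=23,
            limit_steps=0,
        ),
    )
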