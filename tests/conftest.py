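import numpy as np
import pytest

from cardiolattice import fixtures
from cardiolattice.params import (CM, ELASTIC_AREA_SCALE,
                                  ENERGY_LENGTH_SCALE, FB,
                                  CellTypeParams, ModelParams)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simple_params(*, G=0.0, p_detach=0.0, p_unleash=0.0, lam=2.0,
                  target_area_um2=100.0, l_max_um=1e6, n_protr=4,
                  j_cell_md=1.0, j_cell_cell=3.0, j_cm_fb=5.0,
                  temperature=1.0) -> ModelParams:
    """Small hand-checkable parameter set (energies already in lattice
    units once the G/P x400 scale is divided out)."""
    tp = CellTypeParams(lam=lam / ELASTIC_AREA_SCALE,
                        target_area_um2=target_area_um2,
                        G=G / ENERGY_LENGTH_SCALE,
                        p_detach=p_detach / ENERGY_LENGTH_SCALE,
                        p_unleash=p_unleash / ENERGY_LENGTH_SCALE,
                        l_max_um=l_max_um, n_protr=n_protr)
    return ModelParams(cm=tp, fb=tp, j_cell_medium=(j_cell_md, j_cell_md),
                       j_cell_cell=(j_cell_cell, j_cell_cell),
                       j_cm_fb=j_cm_fb, temperature=temperature)


@pytest.fixture
def plus_mask():
    return fixtures.plus_pentomino_mask()
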