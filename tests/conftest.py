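import numpy as np
import pytest

from il12sig import (
    DoseResponseParams,
    PhosphoDesign,
    ReceptorContext,
    ViabilityDesign,
    gen_phospho,
    gen_viability,
)


@pytest.fixture
def default_params() -> DoseResponseParams:
    return DoseResponseParams(ec50=10.0, alpha=1.0, kd=40.0)


@pytest.fixture
def b16_ctx() -> ReceptorContext:
    return ReceptorContext(cell_line="B16F0", stoichiometry="homodimer", area_um2=344.0)


@pytest.fixture
def t_cell_ctx() -> ReceptorContext:
    return ReceptorContext(cell_line="2D6", stoichiometry="heterodimer", area_um2=104.0)


@pytest.fixture
def viability_obs():
    """Default 16-well synthetic viability plate (seeded)."""
    return gen_viability(ViabilityDesign(seed=11))


@pytest.fixture
def hybrid_phospho_obs(b16_ctx):
    """Stratified phospho data generated by the hybrid mechanism (seeded)."""
    return gen_phospho(PhosphoDesign(seed=11), b16_ctx)
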