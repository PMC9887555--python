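import numpy as np
import pytest

from surgprio.synthetic_data import (LifeTable, PanelConfig, ProcedureParams,
                                     generate_life_table,
                                     generate_procedure_truth)


@pytest.fixture(scope="session")
def zero_life_table() -> LifeTable:
    """No background mortality (isolates disease/surgery effects)."""
    ages = np.arange(0, 101, dtype=float)
    return LifeTable(ages, np.zeros_like(ages))


@pytest.fixture(scope="session")
def default_life_table() -> LifeTable:
    return generate_life_table()


@pytest.fixture(scope="session")
def toy_params() -> ProcedureParams:
    """3-cycle toy case with hand-computable trace."""
    return ProcedureParams(procedure_id="toy", age0=60.0, q_pre=0.6,
                           q_post=0.9, p_wait_death=0.1,
                           p_periop_death=0.05, s_long=1.0,
                           horizon_years=5.0)


@pytest.fixture(scope="session")
def small_truths():
    return generate_procedure_truth(n_proc=6, n_gbd=2, seed=7)


@pytest.fixture(scope="session")
def quiet_panel() -> PanelConfig:
    return PanelConfig(name="original", n_experts=8, expert_sd=0.05,
                       round2_shrinkage=0.5, seed=11)
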