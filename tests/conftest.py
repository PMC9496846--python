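import numpy as np
import pandas as pd
import pytest

from ufgpanel.core_io import ExpressionMatrix, PanelStudy, PotencyTable
from ufgpanel.synthetic_data import SynthConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One reference synthetic panel with planted signatures (seed 11)."""
    expr, pot, truth = simulate_panel(SynthConfig(seed=11))
    return PanelStudy(expr, pot), truth


@pytest.fixture()
def tiny_potency():
    """Three drugs x 8 lines with hand-set IC50s (molar)."""
    lines = [f"L{i}" for i in range(1, 9)]
    rng = np.random.default_rng(42)
    ic50 = pd.DataFrame(
        rng.uniform(1e-9, 100e-9, size=(3, 8)),
        index=["d1", "d2", "d3"],
        columns=lines,
    )
    censored = pd.DataFrame(False, index=ic50.index, columns=ic50.columns)
    top = pd.Series({"d1": 300e-9, "d2": 1000e-9, "d3": 1000e-9})
    return PotencyTable(ic50, censored, top)


@pytest.fixture()
def small_expression():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    lines = [f"L{i:02d}" for i in range(16)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(5, 1, size=(20, 16)), index=genes, columns=lines)
    )
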