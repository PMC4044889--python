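import numpy as np
import pytest

from panelforge.io_model import IntensityMatrix, StudyDesign
from panelforge.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture
def tiny_matrix() -> IntensityMatrix:
    values = np.array(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 6.0, 7.0, 8.0],
         [9.0, 10.0, 11.0, 12.0]]
    )
    return IntensityMatrix(["p1", "p2", "p3"], ["i1", "i2", "i3", "i4"], values)


@pytest.fixture
def eight_injection_design() -> StudyDesign:
    # 4 samples x 2 replicates, 2 groups, one study
    return StudyDesign(
        injection_ids=[f"i{k}" for k in range(1, 9)],
        sample_ids=["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
        groups=["cancer", "cancer", "cancer", "cancer",
                "control", "control", "control", "control"],
        studies=["A"] * 8,
        replicates=[1, 2, 1, 2, 1, 2, 1, 2],
    )


@pytest.fixture
def small_simulated_study():
    cfg = SimulationConfig(
        n_proteins=30, n_informative=3, effect_size=2.5,
        n_cancer=10, n_control=10, n_replicates=2, seed=11,
    )
    return simulate_study(cfg, "A") + (cfg,)
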