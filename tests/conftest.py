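import numpy as np
import pandas as pd
import pytest

from targetmet.msio import CompoundEntry, PeakTable, SampleMeta
from targetmet.simulate import ScenarioConfig, simulate_study


@pytest.fixture
def small_library():
    return [
        CompoundEntry("T3", formula="C15H12I3NO4", adduct="[M+H]+",
                      rt=9.0, rt_tol=0.4, is_pair="T3_IS"),
        CompoundEntry("T3_IS", target_mz=657.8174, rt=9.0, rt_tol=0.4,
                      is_internal_standard=True),
        CompoundEntry("ala", target_mz=90.0549, rt=5.0, rt_tol=0.4),
        CompoundEntry("is_1", target_mz=95.0, rt=5.0, rt_tol=0.4,
                      is_internal_standard=True),
    ]


@pytest.fixture
def qc_table():
    """Hand-built table: 2 study, 3 pools, 2x2 dilutions, 1 blank."""
    samples = [
        SampleMeta("s1", "a", "study", 1.0, 1, 5.0),
        SampleMeta("s2", "b", "study", 1.0, 2, 5.0),
        SampleMeta("p1", "pool", "pool", 1.0, 3, 5.0),
        SampleMeta("p2", "pool", "pool", 1.0, 4, 5.0),
        SampleMeta("p3", "pool", "pool", 1.0, 5, 5.0),
        SampleMeta("d3a", "pool", "pool_dilution", 1 / 3, 6, 5.0),
        SampleMeta("d10a", "pool", "pool_dilution", 1 / 10, 7, 5.0),
        SampleMeta("bl", "blank", "blank", 1.0, 8, 5.0),
    ]
    compounds = [
        CompoundEntry("good", target_mz=100.0, rt=1.0),
        CompoundEntry("is_1", target_mz=200.0, rt=2.0,
                      is_internal_standard=True),
    ]
    good = [500.0, 900.0, 700.0, 710.0, 690.0, 700 / 3, 70.0, np.nan]
    is1 = [1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0]
    areas = pd.DataFrame(
        {"good": good, "is_1": is1},
        index=[s.sample_id for s in samples],
    )
    return PeakTable(areas, samples=samples, compounds=compounds)


@pytest.fixture(scope="session")
def default_study():
    config = ScenarioConfig(n_metabolites=30, n_is=6, noise_cv=0.05,
                            matrix_sd=0.2)
    return simulate_study(config, seed=11)
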