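import numpy as np
import pandas as pd
import pytest

from urbanfounder.genotypes import SampleInfo, make_toy_genotypes
from urbanfounder.inference import SimulationConfig, build_reference_table
from urbanfounder.synthetic import StudyDesign, generate_study_matrix
from urbanfounder.variant_io import FilterConfig, apply_site_filters

#: Scaled-down simulation settings used by every ABC-related test.
TEST_SIM_CFG = dict(n_ind=10, seq_len=5e5, n_seg=2)
REF_TABLE_SIMS = 320
REF_TABLE_SEED = 11


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(**TEST_SIM_CFG)


@pytest.fixture(scope="session")
def ref_table(sim_cfg):
    """Shared scaled ABC reference table (expensive; built once)."""
    return build_reference_table(REF_TABLE_SIMS, sim_cfg, seed=REF_TABLE_SEED)


@pytest.fixture(scope="session")
def study():
    """Scaled synthetic study: (filtered matrix, metadata, raw matrix)."""
    design = StudyDesign(seed=3)
    cfg = SimulationConfig(n_ind=20, seq_len=5e5, n_seg=4)
    gm, info = generate_study_matrix(design, cfg)
    gmf, _ = apply_site_filters(gm, FilterConfig(max_missing=12))
    return gmf, info, gm


@pytest.fixture()
def toy_info():
    return SampleInfo(
        pd.DataFrame(
            {
                "sample_id": [f"ind{i}" for i in range(6)],
                "population": ["A"] * 3 + ["B"] * 3,
                "habitat": ["rural"] * 3 + ["urban"] * 3,
                "longitude": np.linspace(-62.0, -61.5, 6),
                "latitude": np.linspace(-38.5, -38.0, 6),
            }
        )
    )


def pop_info(populations, habitats=None, lon=None, lat=None):
    """Helper to build SampleInfo for arbitrary label vectors."""
    n = len(populations)
    return SampleInfo(
        pd.DataFrame(
            {
                "sample_id": [f"ind{i}" for i in range(n)],
                "population": populations,
                "habitat": habitats or ["rural"] * n,
                "longitude": lon if lon is not None else np.zeros(n),
                "latitude": lat if lat is not None else np.zeros(n),
            }
        )
    )
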