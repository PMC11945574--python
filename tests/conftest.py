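import numpy as np
import pytest
from hypothesis import settings

from pyrethro import chem_map, pbk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return chem_map.default_registry()


@pytest.fixture(scope="session")
def human_params():
    return pbk.load_pbk_parameters()


@pytest.fixture(scope="session")
def adult():
    return pbk.Physiology(body_weight=70.0, daily_urine_volume=1.5, daily_creatinine=1.5)


@pytest.fixture(scope="session")
def physiology_by_age():
    return {a: pbk.Physiology.reference(a) for a in pbk.AGE_GROUPS}


@pytest.fixture(scope="session")
def single_pathway_registry():
    """Minimal registry: one compound feeding one specific metabolite."""
    compounds = [chem_map.CompoundSpec("deltamethrin", 505.2, "deltamethrin", 1.0)]
    metabolites = [
        chem_map.MetaboliteSpec(m, 214.2 if m == "3PBA" else 298.0)
        for m in chem_map.MEASURED_METABOLITES
    ]
    matrix = chem_map.TransformationMatrix({("deltamethrin", "DBCA"): 0.43})
    return chem_map.validate_registry(compounds, metabolites, matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
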