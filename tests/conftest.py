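import numpy as np
import pytest

import tcdcm
from tcdcm import (
    DesignSpec,
    HemoParams,
    default_template,
    enumerate_models,
    full_model,
    make_design,
    masks,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def model_specs(template):
    return enumerate_models(template)


@pytest.fixture(scope="session")
def full_mask(template):
    return masks(full_model(template), template)


@pytest.fixture(scope="session")
def short_design():
    """One task cycle at a coarse microtime grid: the small test workhorse."""
    return make_design(DesignSpec(n_cycles=1, microtime_bins=8))


@pytest.fixture(scope="session")
def default_design():
    return make_design(DesignSpec())


@pytest.fixture(scope="session")
def hemo():
    return HemoParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_vector(params, param_map):
    """Flatten a DcmParameters object in a ParamMap's canonical order."""
    from tcdcm.model_space import REGION_INDEX

    out = []
    for name in param_map.names:
        kind, lbl = name.split(":", 1)
        if kind == "C":
            cond, dst = lbl.split("->")
            out.append(params.c[REGION_INDEX[dst], 0 if cond == "low" else 1])
        else:
            src, dst = lbl.split("->")
            m = {"A": params.a, "Blow": params.b_low, "Bhigh": params.b_high}[kind]
            out.append(m[REGION_INDEX[dst], REGION_INDEX[src]])
    return np.array(out)
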