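import numpy as np
import pytest

import kcscreen as kc


@pytest.fixture(scope="session")
def config():
    return kc.default_config()


@pytest.fixture(scope="session")
def cohort121(config):
    """Study-sized cohort: 50 normal / 33 subKC / 38 KC."""
    return kc.generate_cohort(config, 50, 33, 38, seed=11)


@pytest.fixture(scope="session")
def pattern(cohort121):
    return kc.build_normative_pattern(cohort121)


@pytest.fixture(scope="session")
def table(cohort121, pattern):
    return kc.assemble_table(cohort121, pattern, provenance="seed=11")


def make_profile(zones, layer="epithelium", eye_id="eye"):
    return kc.ZonalProfile(eye_id=eye_id, layer=layer, zones=np.asarray(zones, dtype=float))


def make_pattern(value=52.0):
    return kc.NormativePattern(
        zones={l: np.full(30, float(value)) for l in kc.LAYERS}, n_eyes=1
    )
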