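import numpy as np
import pytest

from fractalseg.fractaldb import DBConfig, build_db, read_manifest
from fractalseg.ifs import RenderConfig
from fractalseg.phantom import PhantomConfig, generate_cohort
from fractalseg.roi import prepare_case


@pytest.fixture(scope="session")
def tiny_db(tmp_path_factory):
    """3 categories x 5 instances, quick renders; shared across tests."""
    out = tmp_path_factory.mktemp("db")
    cfg = DBConfig(n_categories=3, n_instances=5,
                   render=RenderConfig(n_points=5000), seed=11)
    manifest = build_db(cfg, out)
    return cfg, out, manifest


@pytest.fixture(scope="session")
def toy_db(tmp_path_factory):
    """2 well-separated categories x 40 instances for pretext-learning tests."""
    out = tmp_path_factory.mktemp("toydb")
    cfg = DBConfig(n_categories=2, n_instances=40, seed=11)
    manifest = build_db(cfg, out)
    return cfg, out, manifest


@pytest.fixture(scope="session")
def small_cohort():
    """Eight phantom cases spanning the complexity range."""
    return generate_cohort(PhantomConfig(n_cases=8, seed=3))


@pytest.fixture(scope="session")
def small_rois(small_cohort):
    return {c.case_id: prepare_case(c) for c in small_cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
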