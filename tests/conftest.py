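import pytest

from lander import obsdata, resemblance


@pytest.fixture(scope="session")
def study_deployments():
    return obsdata.load_study_deployments()


@pytest.fixture(scope="session")
def study_observations():
    return obsdata.load_study_observations()


@pytest.fixture(scope="session")
def study_matrix():
    """Bundled 8 x 14 raw n_max matrix, depth-ordered."""
    return obsdata.study_community_matrix()


@pytest.fixture(scope="session")
def sqrt_matrix(study_matrix):
    return resemblance.transform_abundance(study_matrix, "sqrt")


@pytest.fixture(scope="session")
def study_resemblance(sqrt_matrix):
    return resemblance.bray_curtis(sqrt_matrix)


@pytest.fixture(scope="session")
def depth_grouping(study_matrix):
    """Shallow (deployments 1-3, < 1000 m) vs deep (4-8) labels."""
    return {s: ("shallow" if s in {"1", "2", "3"} else "deep") for s in study_matrix.sample_ids}
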