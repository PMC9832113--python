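"""Shared fixtures: compact model specs and seeded synthetic datasets."""

import numpy as np
import pytest

import mimicgsem as mg
from mimicgsem.model_spec import Covariate, Indicator, LatentVariable, ModelSpec


def two_latent_spec(direct=(), covariates=(), paths=(), full_covariance=False):
    """Two latents x three indicators each, anchors first, logit links."""
    inds = []
    for name, lat, anchor in [
        ("stunting", "malnutrition", True), ("wasting", "malnutrition", False),
        ("underweight", "malnutrition", False), ("diarrhea", "morbidity", True),
        ("cough", "morbidity", False), ("fever", "morbidity", False),
    ]:
        inds.append(Indicator(name, lat, "logit", 1.0 if anchor else None, tuple(direct)))
    return ModelSpec(
        latents=(LatentVariable("malnutrition"), LatentVariable("morbidity")),
        indicators=tuple(inds),
        covariates=tuple(covariates),
        latent_paths=(("malnutrition", "morbidity"),),
        covariate_to_latent_paths=tuple(paths),
        full_covariance=full_covariance,
    )


@pytest.fixture(scope="session")
def paper_spec():
    return mg.default_paper_spec()


@pytest.fixture(scope="session")
def paper_theta(paper_spec):
    return mg.paper_like_params(paper_spec)


@pytest.fixture(scope="session")
def moderate_spec():
    """A plain two-latent measurement model with two covariates."""
    return mg.two_latent_toy_preset()[0]


@pytest.fixture(scope="session")
def moderate_theta():
    return mg.two_latent_toy_preset()[1]


MODERATE_MARGINALS = mg.two_latent_toy_preset()[2]


@pytest.fixture(scope="session")
def moderate_data(moderate_spec, moderate_theta):
    cfg = mg.SimulationConfig(
        n=200, seed=11, true_params=moderate_theta,
        covariate_marginals=MODERATE_MARGINALS,
    )
    return mg.simulate_children(cfg, moderate_spec)


@pytest.fixture(scope="session")
def one_latent_spec():
    return ModelSpec(
        latents=(LatentVariable("trait"),),
        indicators=(
            Indicator("y1", "trait", "logit", 1.0),
            Indicator("y2", "trait", "logit", None),
            Indicator("y3", "trait", "logit", None),
        ),
        covariates=(), latent_paths=(), covariate_to_latent_paths=(),
    )


@pytest.fixture(scope="session")
def one_latent_theta(one_latent_spec):
    from mimicgsem.likelihood import ParameterVector

    layout = mg.param_layout(one_latent_spec)
    return ParameterVector.from_dict(layout, {
        "intercept:y1": -0.5, "intercept:y2": -0.3, "intercept:y3": -0.8,
        "loading:y2": 0.9, "loading:y3": 1.1, "lnsd:trait": np.log(0.8),
    })
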