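import io

import numpy as np
import pytest

from twinpath import (
    MeansParameters,
    PathParameters,
    SimulationConfig,
    TwinDataset,
    read_twin_csv,
)


def make_dataset(rows: str) -> TwinDataset:
    """Build a TwinDataset from inline CSV text (tests' shorthand)."""
    return read_twin_csv(io.StringIO(rows.strip() + "\n"))


def univariate_params(a=0.0, c=0.0, d=0.0, e=1.0, intercept=0.0, beta_age=0.0,
                      beta_sex=0.0, sources=("A", "C", "E")) -> PathParameters:
    paths = {"A": a, "C": c, "D": d, "E": e}
    return PathParameters(
        loadings={S: np.zeros(1) for S in sources},
        specifics={S: np.array([float(paths[S])]) for S in sources},
        means=MeansParameters([intercept], [beta_age], [beta_sex]),
    )


def random_ip_params(rng: np.random.Generator, p: int, sources=("A", "C", "E"),
                     with_means: bool = False) -> PathParameters:
    """Random admissible independent-pathway paths with trait variances ~1."""
    loadings = {S: rng.uniform(0.2, 0.6, p) * rng.choice([-1.0, 1.0]) for S in sources}
    specifics = {S: rng.uniform(0.2, 0.6, p) for S in sources}
    if with_means:
        means = MeansParameters(
            rng.normal(0, 1, p), rng.normal(0, 0.05, p), rng.normal(0, 0.3, p)
        )
    else:
        means = MeansParameters(np.zeros(p), np.zeros(p), np.zeros(p))
    return PathParameters(loadings=loadings, specifics=specifics, means=means)


def univariate_config(a2, c2, e2, n_mz, n_dz, seed, beta_age=0.0, beta_sex=0.0,
                      intercept=0.0) -> SimulationConfig:
    params = univariate_params(
        a=np.sqrt(a2), c=np.sqrt(c2), e=np.sqrt(e2),
        intercept=intercept, beta_age=beta_age, beta_sex=beta_sex,
    )
    return SimulationConfig(
        n_mz=n_mz, n_dz=n_dz, trait_names=("y",), params=params, seed=seed
    )


TINY_CSV = """
pair_id,zygosity,age_1,age_2,sex_1,sex_2,GLS_1,GLS_2,DCT_1,DCT_2
p1,MZ,50,50,1,1,-21.5,-20.9,180,175
p2,MZ,61,61,0,0,-23.1,-22.8,200,195
p3,DZ,47,47,1,1,-19.8,-21.2,160,170
"""


@pytest.fixture
def tiny_complete() -> TwinDataset:
    return make_dataset(TINY_CSV)
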