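import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cemodule as cm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_instance():
    """A small planted instance shared by read-only tests."""
    spec = cm.SyntheticSpec(
        S=40, N1=30, N2=15, N3=30, K_true=3,
        members_lnc=5, members_mir=3, members_mrna=5, seed=11,
    )
    dataset, nets, truth = cm.generate(spec)
    return spec, dataset, nets, truth


@pytest.fixture(scope="session")
def fitted_small(small_instance):
    spec, dataset, nets, truth = small_instance
    hp = cm.Hyperparameters(K=3, seed=11, max_iter=2000)
    result = cm.fit(dataset, nets, hp)
    return dataset, nets, truth, hp, result


def random_state(rng, S, n1, n2, n3, K, scale=1.0):
    """Strictly positive random factor state for objective/update tests."""
    return cm.FactorizationResult(
        W=scale * (1.0 - rng.random((S, K))),
        H1=scale * (1.0 - rng.random((n1, K))),
        H2=scale * (1.0 - rng.random((n2, K))),
        H3=scale * (1.0 - rng.random((n3, K))),
    )


def make_layer(values, kind="mRNA", prefix="g"):
    values = np.asarray(values, dtype=float)
    S, N = values.shape
    return cm.OmicsLayer(
        layer_kind=kind,
        molecule_ids=[f"{prefix}{j}" for j in range(N)],
        sample_ids=[f"s{i}" for i in range(S)],
        values=values,
    )
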