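import numpy as np
import pytest
from hypothesis import settings

import langgame as lg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_corpus() -> lg.Corpus:
    return lg.packaged_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240313)


def attach_linear_rates(
    corpus: lg.Corpus,
    alpha: float = 0.3,
    beta: float = 0.08,
    sigma: float = 0.02,
    seed: int = 0,
) -> lg.Corpus:
    """Join synthetic prosocial rates onto a corpus via the linear model."""
    rng = np.random.default_rng(seed)
    records = []
    for rec in corpus:
        d = lg.delta_s(rec.sentiments).value
        rate = float(np.clip(alpha + beta * d + rng.normal(0.0, sigma), 0.0, 1.0))
        records.append(rec.model_copy(update={"prosocial_rate": rate}))
    return lg.Corpus(records=tuple(records), provenance="synthetic rates")
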