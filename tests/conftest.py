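import numpy as np
import pytest

import myelorank as mr
from myelorank.nma_model import PosteriorSamples


@pytest.fixture(scope="session")
def table1_trials():
    return mr.table1_fixture()


@pytest.fixture(scope="session")
def canon_trials(table1_trials):
    return mr.canonicalize_treatments(table1_trials)


@pytest.fixture(scope="session")
def fixture_network(canon_trials):
    return mr.build_network(canon_trials)


def make_samples(d_full, treatments, reference, endpoint="PFS", tau=0.1):
    """PosteriorSamples from an explicit (N, a) matrix of d draws.

    The reference column of ``d_full`` must be zero; draws are split into
    two pseudo-chains so the container shape matches the sampler output.
    """
    d_full = np.asarray(d_full, dtype=float)
    n, a = d_full.shape
    assert n % 2 == 0
    free_cols = [j for j, t in enumerate(treatments) if t != reference]
    flat = np.concatenate(
        [d_full[:, free_cols], np.full((n, 1), tau)], axis=1
    )
    draws = flat.reshape(2, n // 2, a)
    names = tuple(f"d[{t}]" for t in treatments if t != reference) + ("tau",)
    return PosteriorSamples(
        endpoint=endpoint,
        reference=reference,
        treatments=tuple(treatments),
        draws=draws,
        param_names=names,
    )


@pytest.fixture
def samples_factory():
    return make_samples
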