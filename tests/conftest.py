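import numpy as np
import pytest

from anchornet import anchor_tests as at


@pytest.fixture
def rng():
    return np.random.default_rng(20180919)


@pytest.fixture
def random_trio(rng):
    """A correlated rank-normalized (E, A, B) trio of length 30."""
    n = 30
    e = rng.standard_normal(n)
    a = 0.6 * e + rng.standard_normal(n)
    b = 0.5 * a + rng.standard_normal(n)
    return tuple(at.rank_normal_transform(v) for v in (e, a, b))


def random_correlated_trios(seed: int, n_trios: int, sizes=(8, 20, 50)):
    """Rank-normalized trios spanning independent, chained and confounded cases."""
    rng = np.random.default_rng(seed)
    trios = []
    while len(trios) < n_trios:
        n = int(rng.choice(sizes))
        kind = len(trios) % 4
        e = rng.standard_normal(n)
        if kind == 0:  # independent
            a, b = rng.standard_normal((2, n))
        elif kind == 1:  # chain E -> A -> B
            a = 0.8 * e + 0.5 * rng.standard_normal(n)
            b = 0.7 * a + 0.5 * rng.standard_normal(n)
        elif kind == 2:  # pleiotropy B <- E -> A
            a = 0.8 * e + 0.5 * rng.standard_normal(n)
            b = 0.6 * e + 0.5 * rng.standard_normal(n)
        else:  # confounded chain
            c = rng.standard_normal(n)
            a = 0.6 * e + 0.6 * c + 0.5 * rng.standard_normal(n)
            b = 0.5 * a + 0.6 * c + 0.5 * rng.standard_normal(n)
        trio = tuple(at.rank_normal_transform(v) for v in (e, a, b))
        # at small n, identical rank patterns make the sample covariance
        # singular; ML comparisons are undefined there, so resample
        rhos = [abs(at.pair_correlation(x, y)) for x, y in
                ((trio[0], trio[1]), (trio[0], trio[2]), (trio[1], trio[2]))]
        if max(rhos) > 1 - 1e-9:
            continue
        trios.append(trio)
    return trios
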