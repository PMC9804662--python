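import numpy as np
import pytest

from copulameta import StudyCounts


@pytest.fixture(scope="session")
def cml():
    from copulameta import load_cml
    return load_cml()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_counts(rng, n_studies=5, n=80, p1=0.5, p2=0.55, d1=0.4, d2=0.2):
    """Small synthetic count dataset drawn from independent binomials."""
    from scipy.special import expit, logit
    out = []
    for i in range(n_studies):
        e1, e2 = logit(p1), logit(p2)
        out.append(StudyCounts(
            study_id=f"s{i}", n_A=n, n_B=n,
            r1_A=int(rng.binomial(n, expit(e1))),
            r2_A=int(rng.binomial(n, expit(e2))),
            r1_B=int(rng.binomial(n, expit(e1 + d1))),
            r2_B=int(rng.binomial(n, expit(e2 + d2)))))
    return out


@pytest.fixture()
def small_counts(rng):
    return make_counts(rng)
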