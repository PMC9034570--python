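import math

import pytest

from ssre import ObservableRatios, RateTriplet, forward_observe


@pytest.fixture
def example_rates() -> RateTriplet:
    """A well-conditioned rate triplet with k = beta/gamma = 0.5, gamma*T = 1 at T=1."""
    return RateTriplet(alpha=2.0, beta=0.5, gamma=1.0)


@pytest.fixture
def example_obs(example_rates) -> ObservableRatios:
    """Observable pair for the example rates at T=1, derived from the closed forms.

    Evaluating the pool solutions directly: a = p_u/(p_u+m_u) ~= 0.589367,
    b = p_l/(p_l+m_l) ~= 0.835607; lies in the uniquely invertible region.
    """
    rec = forward_observe(example_rates, 1.0)
    return ObservableRatios(a=rec.iota_u / rec.chi_u, b=rec.iota_l / rec.chi_l)


@pytest.fixture
def example_record(example_rates):
    return forward_observe(example_rates, 1.0, transcript_id="tx1", gene_id="g1")


def exact_unlabeled(alpha, beta, gamma, t):
    """Independent evaluation of the pre-existing pool closed form."""
    p = alpha / beta * math.exp(-beta * t)
    m = alpha / (gamma - beta) * math.exp(-beta * t) - beta * alpha / (
        gamma * (gamma - beta)
    ) * math.exp(-gamma * t)
    return p, m


def exact_labeled(alpha, beta, gamma, t):
    """Independent evaluation of the newly synthesized pool closed form."""
    p = alpha / beta * (1.0 - math.exp(-beta * t))
    m = alpha / gamma * (
        1.0 + beta / (gamma - beta) * math.exp(-gamma * t)
    ) - alpha / (gamma - beta) * math.exp(-beta * t)
    return p, m
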