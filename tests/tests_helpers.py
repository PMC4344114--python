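"""Shared independent oracles for the test suite."""

import numpy as np
from scipy.special import gammaln

from popinfo import TruncationConfig
from popinfo.ssi import enumerate_responses


def brute_force_mi_bits(pop, ensemble, trunc=None):
    """Mutual information from the truncated joint distribution, in bits.

    Deliberately computed from first principles (joint / marginals / log
    ratio) rather than through the SSI machinery, so it can serve as an
    independent oracle for E_S[SSI] = I(S; R).
    """
    trunc = trunc or TruncationConfig()
    R = enumerate_responses(pop, ensemble, trunc)
    lam = pop.expected_counts(ensemble.values)
    logp = R.astype(float) @ np.log(lam).T - lam.sum(axis=1) - gammaln(
        R + 1.0
    ).sum(axis=1, keepdims=True)
    joint = np.exp(logp) * ensemble.probabilities  # (n_states, n_s)
    pr = joint.sum(axis=1, keepdims=True)
    ps = ensemble.probabilities[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pr * ps))
    return float(np.nansum(terms))
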