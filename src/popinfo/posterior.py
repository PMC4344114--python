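"""Bayesian-observer analysis of the population code.

A hypothetical observer with full knowledge of the stimulus distribution and
the encoding model infers the stimulus from a single population response.
Writing Z for the observer's belief, the single-response posterior is the
Bayes posterior P(s|r), and the average posterior conditioned on the true
stimulus,

    P(z|s) = sum_r P(z|r) P(r|s)    with P(z|r) = P(s|r),

visualizes the "confusion" the code introduces between stimuli (for example
the symmetric cross of a unimodal tuning curve, whose two flanks are
ambiguous, or the chequerboard of a noisy monotonic curve, whose plateau and
baseline regions are internally indistinguishable).  Sorting each column by
decreasing probability makes the per-stimulus uncertainty, the conditional
entropy H(Z|S=s), easy to see.

The entropy-based stimulus-specific measure

    I2(s) = H(S) - H(Z|S=s)

resembles the SSI but is not the same quantity: the SSI averages the entropy
of posteriors, I2 takes the entropy of the averaged posterior; the order of
averaging and entropy differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .curves import InfoCurve
from .ensembles import StimulusEnsemble
from .population import Population, substream
from .ssi import (
    MCConfig,
    TruncationConfig,
    EnumerationSizeError,
    _support_means,
    enumerate_responses,
    response_log_likelihoods,
)

__all__ = [
    "PosteriorMatrix",
    "posterior_given_response",
    "average_posterior",
    "sorted_column_summary",
    "entropy_ssi",
]


@dataclass(frozen=True)
class PosteriorMatrix:
    """Average posterior P(Z|S): rows are observer stimuli z, columns true s.

    Columns are (approximately) stochastic: exact mode sums truncated
    response lattices (mass >= 1 - N * epsilon), Monte-Carlo mode averages
    exactly normalized posteriors.
    """

    matrix: np.ndarray
    grid: np.ndarray
    prior: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        g = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.prior, dtype=float)
        if m.shape != (g.size, g.size):
            raise ValueError("matrix must be square on the stimulus grid")
        if np.any(m < 0):
            raise ValueError("posterior entries must be non-negative")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "prior", p)

    def column_entropies(self) -> np.ndarray:
        """H(Z|S=s) per column, in bits (0 log 0 := 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0)
        return -contrib.sum(axis=0)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.matrix, index=self.grid, columns=self.grid)
        df.index.name = "z"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, prior=None) -> "PosteriorMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        grid = df.index.to_numpy(dtype=float)
        if prior is None:
            prior = np.full(grid.size, 1.0 / grid.size)
        return cls(df.to_numpy(dtype=float), grid, np.asarray(prior, dtype=float))


def posterior_given_response(
    pop: Population,
    r,
    ensemble: StimulusEnsemble,
    prior=None,
) -> np.ndarray:
    """Bayes posterior P(s|r) over the full ensemble grid.

    By default the observer's prior equals the stimulus distribution; an
    alternative prior over the same grid may be supplied (it is normalized,
    so rescaling by a constant changes nothing).
    """
    r = np.asarray(r)
    if r.shape != (pop.N,):
        raise ValueError("response vector length must equal the population size")
    if prior is None:
        prior = ensemble.probabilities
    prior = np.asarray(prior, dtype=float)
    if prior.shape != ensemble.values.shape or np.any(prior < 0):
        raise ValueError("prior must be a non-negative vector on the ensemble grid")
    sup = prior > 0
    lam = np.atleast_2d(pop.expected_counts(ensemble.values[sup]))
    ll = response_log_likelihoods(r[None, :].astype(float), lam)[0]
    log_joint = ll + np.log(prior[sup])
    norm = logsumexp(log_joint)
    if not np.isfinite(norm):
        raise ValueError("response has zero probability under every stimulus")
    out = np.zeros(ensemble.values.size)
    out[sup] = np.exp(log_joint - norm)
    return out


def average_posterior(
    pop: Population,
    ensemble: StimulusEnsemble,
    mc: MCConfig | None = None,
    mode: str = "auto",
    trunc: TruncationConfig | None = None,
    prior=None,
) -> PosteriorMatrix:
    """Average posterior matrix P(Z|S) over the ensemble grid.

    ``mode="exact"`` enumerates the truncated response lattice;
    ``mode="mc"`` averages posteriors of sampled responses (requires
    ``mc``); ``mode="auto"`` tries exact and falls back to Monte Carlo.
    """
    if np.any(ensemble.probabilities <= 0):
        raise ValueError("average posterior requires a fully supported ensemble")
    trunc = trunc or TruncationConfig()
    if mode not in ("auto", "exact", "mc"):
        raise ValueError("mode must be 'auto', 'exact' or 'mc'")
    prior_vec = (
        ensemble.probabilities if prior is None else np.asarray(prior, dtype=float)
    )
    if mode in ("auto", "exact"):
        try:
            return _average_posterior_exact(pop, ensemble, trunc, prior_vec)
        except EnumerationSizeError:
            if mode == "exact":
                raise
    if mc is None:
        raise ValueError("Monte-Carlo mode requires an MCConfig")
    return _average_posterior_mc(pop, ensemble, mc, prior_vec)


def _average_posterior_exact(pop, ensemble, trunc, prior) -> PosteriorMatrix:
    _, _, lam = _support_means(pop, ensemble)
    R = enumerate_responses(pop, ensemble, trunc)
    lp = response_log_likelihoods(R, lam, include_factorial=True)
    cond = np.exp(lp)  # (n_states, n_s): P(r|s)
    log_joint = lp + np.log(prior)
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    post = np.exp(log_post)  # (n_states, n_s): P(z=col | r=row)
    matrix = post.T @ cond  # [z, s] = sum_r P(z|r) P(r|s)
    return PosteriorMatrix(matrix, ensemble.values, ensemble.probabilities)


def _average_posterior_mc(pop, ensemble, mc, prior) -> PosteriorMatrix:
    n = len(ensemble)
    lam = np.atleast_2d(pop.expected_counts(ensemble.values))
    matrix = np.empty((n, n))
    for j in range(n):
        rng = substream(mc.seed, j)
        R = pop.sample(float(ensemble.values[j]), mc.n_samples, rng)
        ll = response_log_likelihoods(R, lam)
        log_joint = ll + np.log(prior)
        log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
        matrix[:, j] = np.exp(log_post).mean(axis=0)
    return PosteriorMatrix(matrix, ensemble.values, ensemble.probabilities)


def sorted_column_summary(pm: PosteriorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Each column sorted descending (stable), plus the column entropies.

    Sorting permutes within columns only, so column sums and entropies are
    unchanged; it exposes the per-stimulus uncertainty profile directly.
    """
    order = np.argsort(-pm.matrix, axis=0, kind="stable")
    sorted_matrix = np.take_along_axis(pm.matrix, order, axis=0)
    return sorted_matrix, pm.column_entropies()


def entropy_ssi(pm: PosteriorMatrix, ensemble: StimulusEnsemble) -> InfoCurve:
    """I2(s) = H(S) - H(Z|S=s) in bits on the ensemble grid."""
    if pm.grid.shape != ensemble.values.shape or not np.allclose(
        pm.grid, ensemble.values
    ):
        raise ValueError("posterior grid does not match the ensemble")
    values = ensemble.entropy() - pm.column_entropies()
    return InfoCurve(ensemble.values, values, None, "entropy-ssi")
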