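"""Stimulus-specific information (SSI) and related Shannon measures.

The response-specific information (RSI) of a response vector ``r`` is the
reduction in stimulus entropy it produces,

    I(r) = H(S) - H(S | R = r)   (bits),

and the SSI of a stimulus is the expectation of the RSI over the responses
that stimulus elicits,

    I(s) = sum_r P(r|s) I(r).

The expectation of the SSI over the stimulus ensemble is the mutual
information I(S; R), which is non-negative even though the SSI itself can be
negative at individual (unexpected, low-probability) stimuli.

Two evaluation strategies are provided:

* exact enumeration over a truncated response lattice, feasible for small
  populations with small mean counts, and
* a Monte-Carlo estimator that samples responses from P(r|s), evaluates the
  exact Bayes posterior over the (discretized) ensemble for each sample, and
  averages the RSI; per-stimulus standard errors come from the sample
  standard deviation.  This sidesteps the exhaustive integral over the
  high-dimensional response space and scales to populations of hundreds of
  neurons.

The marginal SSI (mSSI) of neuron ``i`` is the population SSI minus the SSI
of the population with neuron ``i`` removed; it is estimated with common
random numbers (the reduced-population RSI is evaluated on the same sampled
response vectors with coordinate ``i`` dropped, a valid marginal of the
joint) so the paired difference has low variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .curves import InfoCurve
from .ensembles import StimulusEnsemble
from .population import Population, substream

__all__ = [
    "MCConfig",
    "TruncationConfig",
    "EnumerationSizeError",
    "rsi",
    "rsi_batch",
    "ssi_exact",
    "ssi_mc",
    "marginal_ssi",
    "mutual_information",
    "ssi_point",
    "marginal_ssi_point",
    "enumerate_responses",
    "response_log_likelihoods",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo settings: sample count per stimulus, seed, SE reporting."""

    n_samples: int = 1000
    seed: int = 0
    report_se: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one Monte-Carlo sample")


@dataclass(frozen=True)
class TruncationConfig:
    """Truncation of exact response-space sums.

    Each neuron's count range is cut at the smallest c with
    CDF(c; lambda_max) >= 1 - epsilon, where lambda_max is the neuron's
    largest mean over the ensemble, so the enumerated mass under every
    stimulus is at least (1 - epsilon)^N >= 1 - N epsilon.
    """

    epsilon: float = 1e-10
    max_states: int = 10_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1e-4:
            raise ValueError("epsilon must lie in (0, 1e-4)")
        if self.max_states < 1:
            raise ValueError("max_states must be positive")


class EnumerationSizeError(ValueError):
    """Raised when the truncated response lattice exceeds the state cap."""


# -- shared posterior machinery --------------------------------------------

def _support_means(pop: Population, ensemble: StimulusEnsemble):
    """(values, priors, lambda matrix) restricted to non-zero-probability stimuli."""
    sup = ensemble.support
    values = ensemble.values[sup]
    priors = ensemble.probabilities[sup]
    lam = np.atleast_2d(pop.expected_counts(values))  # (n_sup, N)
    return values, priors, lam


def response_log_likelihoods(
    R: np.ndarray, lam: np.ndarray, include_factorial: bool = False
) -> np.ndarray:
    """log P(r|s) for each response row and each stimulus column.

    Parameters
    ----------
    R : (M, N) integer array of spike counts.
    lam : (n_s, N) array of Poisson means.
    include_factorial : bool
        If False the -log r! terms (constant across stimuli, cancelling in
        posterior normalization) are omitted.
    """
    R = np.asarray(R, dtype=float)
    # Zero means are mapped to an astronomically negative log so that
    # impossible counts get zero posterior weight without producing NaNs.
    loglam = np.log(np.maximum(lam, 1e-300))
    ll = R @ loglam.T - lam.sum(axis=1)
    if include_factorial:
        ll = ll - gammaln(R + 1.0).sum(axis=1, keepdims=True)
    return ll


def _posterior_entropy_bits(log_post: np.ndarray) -> np.ndarray:
    """Row-wise entropy (bits) of normalized log-posteriors."""
    post = np.exp(log_post)
    contrib = np.where(post > 0, post * log_post, 0.0)
    return -contrib.sum(axis=1) / _LOG2


def rsi_batch(R: np.ndarray, pop: Population, ensemble: StimulusEnsemble) -> np.ndarray:
    """RSI (bits) of each response row, with exact Bayes posteriors."""
    _, priors, lam = _support_means(pop, ensemble)
    ll = response_log_likelihoods(np.atleast_2d(R), lam)
    log_joint = ll + np.log(priors)
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    h_prior = -(priors * np.log2(priors)).sum()
    return h_prior - _posterior_entropy_bits(log_post)


def rsi(r, pop: Population, ensemble: StimulusEnsemble) -> float:
    """Response-specific information of a single response vector, in bits.

    May be negative for particular responses (evidence for an unexpected
    stimulus transiently increases posterior entropy).
    """
    r = np.asarray(r)
    if r.shape != (pop.N,):
        raise ValueError("response vector length must equal the population size")
    return float(rsi_batch(r[None, :], pop, ensemble)[0])


# -- exact enumeration ------------------------------------------------------

def enumerate_responses(
    pop: Population, ensemble: StimulusEnsemble, trunc: TruncationConfig
) -> np.ndarray:
    """All response vectors on the truncated lattice; shape (n_states, N)."""
    _, _, lam = _support_means(pop, ensemble)
    caps = poisson.ppf(1.0 - trunc.epsilon, lam.max(axis=0)).astype(int)
    n_states = float(np.prod(caps + 1.0))
    if n_states > trunc.max_states:
        raise EnumerationSizeError(
            f"truncated response space has {n_states:.3g} states "
            f"(cap {trunc.max_states}); use the Monte-Carlo estimator ssi_mc"
        )
    grids = np.meshgrid(*[np.arange(c + 1) for c in caps], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def ssi_exact(
    pop: Population,
    ensemble: StimulusEnsemble,
    trunc: TruncationConfig | None = None,
) -> InfoCurve:
    """Exact SSI over the ensemble (deterministic, truncated enumeration).

    Values at zero-probability stimuli are NaN (undefined).
    """
    trunc = trunc or TruncationConfig()
    _, priors, lam = _support_means(pop, ensemble)
    R = enumerate_responses(pop, ensemble, trunc)
    lp = response_log_likelihoods(R, lam, include_factorial=True)  # (n_states, n_sup)
    cond = np.exp(lp)  # P(r|s)
    rsi_vals = rsi_batch(R, pop, ensemble)
    values_sup = cond.T @ rsi_vals  # I(s) = sum_r P(r|s) I(r)
    values = np.full(len(ensemble), np.nan)
    values[ensemble.support] = values_sup
    curve = InfoCurve(ensemble.values, values, None, "ssi[exact]")
    _warn_if_near_saturation(curve, ensemble)
    return curve


# -- Monte-Carlo estimator ---------------------------------------------------

def ssi_mc(pop: Population, ensemble: StimulusEnsemble, mc: MCConfig) -> InfoCurve:
    """Monte-Carlo SSI with per-stimulus standard errors.

    For each stimulus s, averages the RSI of ``mc.n_samples`` responses drawn
    from P(r|s); posteriors inside the RSI are computed exactly on the
    ensemble grid.  Each stimulus uses a deterministic substream derived from
    (seed, grid index), so results are independent of evaluation order.
    """
    values = np.full(len(ensemble), np.nan)
    ses = np.full(len(ensemble), np.nan)
    for j in np.flatnonzero(ensemble.support):
        rng = substream(mc.seed, int(j))
        R = pop.sample(float(ensemble.values[j]), mc.n_samples, rng)
        vals = rsi_batch(R, pop, ensemble)
        values[j] = vals.mean()
        if mc.report_se:
            ses[j] = vals.std(ddof=1) / np.sqrt(mc.n_samples) if mc.n_samples > 1 else np.inf
    se = ses if mc.report_se else None
    curve = InfoCurve(ensemble.values, values, se, "ssi[mc]")
    _warn_if_near_saturation(curve, ensemble)
    return curve


def marginal_ssi(
    pop: Population, i: int, ensemble: StimulusEnsemble, mc: MCConfig
) -> InfoCurve:
    """Marginal SSI of neuron ``i``: population SSI minus reduced-population SSI.

    Estimated with common random numbers: both RSI terms are evaluated on the
    same sampled response vectors (the reduced term drops coordinate ``i``),
    and the standard error is that of the paired difference.
    """
    if pop.N < 2:
        raise ValueError("marginal SSI needs N >= 2; use the single-neuron SSI")
    reduced = pop.drop(i)
    keep = [j for j in range(pop.N) if j != i]
    values = np.full(len(ensemble), np.nan)
    ses = np.full(len(ensemble), np.nan)
    for j in np.flatnonzero(ensemble.support):
        rng = substream(mc.seed, int(j))
        R = pop.sample(float(ensemble.values[j]), mc.n_samples, rng)
        diff = rsi_batch(R, pop, ensemble) - rsi_batch(R[:, keep], reduced, ensemble)
        values[j] = diff.mean()
        if mc.report_se:
            ses[j] = diff.std(ddof=1) / np.sqrt(mc.n_samples) if mc.n_samples > 1 else np.inf
    se = ses if mc.report_se else None
    return InfoCurve(ensemble.values, values, se, f"mssi[{i}]")


def mutual_information(curve: InfoCurve, ensemble: StimulusEnsemble) -> float:
    """I(S; R) = E_S[SSI] in bits; zero-probability stimuli contribute 0."""
    if curve.stimuli.shape != ensemble.values.shape or not np.allclose(
        curve.stimuli, ensemble.values
    ):
        raise ValueError("curve grid does not match the ensemble")
    p = ensemble.probabilities
    vals = np.where(p > 0, curve.values, 0.0)
    if np.any(np.isnan(vals[p > 0])):
        raise ValueError("SSI is undefined at a stimulus with non-zero probability")
    return float((p * vals).sum())


# -- single-point helpers (task modeling) -----------------------------------

def ssi_point(
    pop: Population,
    ensemble: StimulusEnsemble,
    member_index: int,
    mc: MCConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """MC estimate (value, SE) of the SSI at one ensemble member."""
    rng = rng if rng is not None else substream(mc.seed, member_index)
    R = pop.sample(float(ensemble.values[member_index]), mc.n_samples, rng)
    vals = rsi_batch(R, pop, ensemble)
    se = vals.std(ddof=1) / np.sqrt(mc.n_samples) if mc.n_samples > 1 else np.inf
    return float(vals.mean()), float(se)


def marginal_ssi_point(
    pop: Population,
    i: int,
    ensemble: StimulusEnsemble,
    member_index: int,
    mc: MCConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """MC estimate (value, SE) of the marginal SSI at one ensemble member."""
    if pop.N < 2:
        raise ValueError("marginal SSI needs N >= 2")
    rng = rng if rng is not None else substream(mc.seed, member_index)
    reduced = pop.drop(i)
    keep = [j for j in range(pop.N) if j != i]
    R = pop.sample(float(ensemble.values[member_index]), mc.n_samples, rng)
    diff = rsi_batch(R, pop, ensemble) - rsi_batch(R[:, keep], reduced, ensemble)
    se = diff.std(ddof=1) / np.sqrt(mc.n_samples) if mc.n_samples > 1 else np.inf
    return float(diff.mean()), float(se)


def _warn_if_near_saturation(curve: InfoCurve, ensemble: StimulusEnsemble) -> None:
    """Warn when the mutual information nearly saturates the stimulus entropy.

    A saturated code distorts the shape of the SSI, so the precision of a
    modeled code (f_bg, f_mod, tau) should be chosen to stay below this.
    """
    h = ensemble.entropy()
    if h <= 0:
        return
    try:
        mi = mutual_information(curve, ensemble)
    except ValueError:
        return
    if mi > 0.99 * h:
        warnings.warn(
            f"mutual information ({mi:.3f} bits) nearly saturates the stimulus "
            f"entropy ({h:.3f} bits); SSI shape may be distorted",
            RuntimeWarning,
            stacklevel=3,
        )
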