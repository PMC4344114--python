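"""Tuning curves and the conditionally independent Poisson encoder.

Two stereotypical rate tuning functions are modeled:

* ``unimodal`` -- a Gaussian bump,
  ``f(s) = f_bg + f_mod * exp(-(s - sigma)^2 / (2 omega^2))``,
  peaking at the characteristic stimulus ``sigma``;
* ``monotonic`` -- a logistic sigmoid,
  ``f(s) = f_bg + f_mod / (1 + exp(-(s - sigma) / omega))``,
  whose characteristic stimulus is the flank midpoint, where
  ``f(sigma) = f_bg + f_mod / 2``.

A :class:`Population` is a list of such neurons sharing an integration time
``tau``; each neuron's spike count is Poisson with mean ``tau * f_i(s)``,
conditionally independent across neurons given the stimulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "TuningCurve",
    "Population",
    "eval_rate",
    "eval_rate_derivative",
    "make_population",
    "expected_counts",
    "log_likelihood",
    "sample_responses",
    "substream",
]

_KINDS = ("unimodal", "monotonic")


@dataclass(frozen=True)
class TuningCurve:
    """Parametric rate tuning curve.

    Parameters
    ----------
    kind : {"unimodal", "monotonic"}
    f_bg : float
        Background firing rate, spikes/s.  Must be non-negative; a strictly
        positive value is recommended since Chernoff natural parameters
        require positive Poisson means.
    f_mod : float
        Modulation depth (f_max - f_bg), spikes/s; positive.
    omega : float
        Width parameter, stimulus units; positive.
    sigma : float
        Characteristic stimulus: the peak (unimodal) or flank midpoint
        (monotonic).
    """

    kind: str
    f_bg: float
    f_mod: float
    omega: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.f_bg < 0:
            raise ValueError("background rate must be non-negative")
        if self.f_mod <= 0:
            raise ValueError("modulation depth must be positive")
        if self.omega <= 0:
            raise ValueError("width parameter must be positive")

    def rate(self, s):
        """Mean firing rate f(s), spikes/s; defined on all reals."""
        s = np.asarray(s, dtype=float)
        if self.kind == "unimodal":
            out = self.f_bg + self.f_mod * np.exp(
                -((s - self.sigma) ** 2) / (2.0 * self.omega**2)
            )
        else:
            out = self.f_bg + self.f_mod / (1.0 + np.exp(-(s - self.sigma) / self.omega))
        return out if out.ndim else float(out)

    def rate_derivative(self, s):
        """Analytic tuning-curve gradient f'(s), spikes/s per stimulus unit."""
        s = np.asarray(s, dtype=float)
        if self.kind == "unimodal":
            out = (
                self.f_mod
                * (self.sigma - s)
                / self.omega**2
                * np.exp(-((s - self.sigma) ** 2) / (2.0 * self.omega**2))
            )
        else:
            # logistic derivative written via cosh for symmetry about sigma
            out = self.f_mod / (
                2.0 * self.omega * (np.cosh((self.sigma - s) / self.omega) + 1.0)
            )
        return out if out.ndim else float(out)

    def max_gradient(self) -> float:
        """max_s |f'(s)|, attained at sigma +/- omega (unimodal) or sigma."""
        if self.kind == "unimodal":
            return self.f_mod * np.exp(-0.5) / self.omega
        return self.f_mod / (4.0 * self.omega)

    def flank_width(self) -> float:
        """Rate range over maximum slope: f_mod / max|f'(s)|."""
        return self.f_mod / self.max_gradient()

    def replace(self, **kw) -> "TuningCurve":
        params = dict(
            kind=self.kind, f_bg=self.f_bg, f_mod=self.f_mod,
            omega=self.omega, sigma=self.sigma,
        )
        params.update(kw)
        return TuningCurve(**params)


@dataclass(frozen=True)
class Population:
    """Ordered collection of Poisson neurons with shared integration time."""

    neurons: tuple[TuningCurve, ...]
    tau: float

    def __post_init__(self) -> None:
        neurons = tuple(self.neurons)
        if len(neurons) < 1:
            raise ValueError("population must contain at least one neuron")
        if self.tau <= 0:
            raise ValueError("integration time must be positive")
        object.__setattr__(self, "neurons", neurons)

    @property
    def N(self) -> int:
        return len(self.neurons)

    def rates(self, s) -> np.ndarray:
        """Rate matrix f_i(s): shape (n_stimuli, N) for array s, (N,) for scalar."""
        scalar = np.ndim(s) == 0
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.stack([tc.rate(s_arr) for tc in self.neurons], axis=-1)
        return out[0] if scalar else out

    def expected_counts(self, s) -> np.ndarray:
        """Poisson means lambda_i = tau * f_i(s); shape (..., N)."""
        return self.tau * self.rates(s)

    def drop(self, i: int) -> "Population":
        """Population with neuron ``i`` removed."""
        if self.N < 2:
            raise ValueError("cannot drop a neuron from a single-neuron population")
        if not 0 <= i < self.N:
            raise IndexError("neuron index out of range")
        return Population(self.neurons[:i] + self.neurons[i + 1 :], self.tau)

    def log_likelihood(self, r, s) -> float:
        """log P(R = r | S = s) in nats (independent-Poisson product)."""
        return log_likelihood(self, r, s)

    def sample(self, s: float, M: int, rng: np.random.Generator) -> np.ndarray:
        """M i.i.d. response vectors to stimulus ``s``; shape (M, N)."""
        lam = self.expected_counts(float(s))
        return rng.poisson(lam, size=(M, self.N))

    # -- serialization: per-neuron CSV with a JSON comment header for tau ---

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [
                dict(kind=tc.kind, f_bg=tc.f_bg, f_mod=tc.f_mod,
                     omega=tc.omega, sigma=tc.sigma)
                for tc in self.neurons
            ]
        )
        header = "# " + json.dumps({"tau": self.tau}) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Population":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("population CSV must start with a '# {...}' header")
            meta = json.loads(first[1:].strip())
            df = pd.read_csv(fh, float_precision="round_trip")
        neurons = tuple(
            TuningCurve(row.kind, row.f_bg, row.f_mod, row.omega, row.sigma)
            for row in df.itertuples()
        )
        return cls(neurons, float(meta["tau"]))


# -- functional wrappers ----------------------------------------------------

def eval_rate(tc: TuningCurve, s):
    return tc.rate(s)


def eval_rate_derivative(tc: TuningCurve, s):
    return tc.rate_derivative(s)


def make_population(
    N: int,
    template: TuningCurve,
    s_min: float,
    s_max: float,
    tau: float,
    placement: str = "include-endpoints",
) -> Population:
    """Population of N copies of ``template`` with characteristic stimuli
    uniformly distributed across [s_min, s_max].

    ``placement="include-endpoints"`` (default) puts sigma_i at N regularly
    spaced points including both endpoints, so odd N yields a neuron exactly
    at the interval center -- convenient for "neuron of interest" analyses.
    ``placement="cell-centered"`` uses the midpoints of N equal sub-intervals.
    For N=1 the template's own sigma is kept.
    """
    if N < 1:
        raise ValueError("population size must be at least 1")
    if N == 1:
        return Population((template,), tau)
    if placement == "include-endpoints":
        sigmas = np.linspace(s_min, s_max, N)
    elif placement == "cell-centered":
        edges = np.linspace(s_min, s_max, N + 1)
        sigmas = 0.5 * (edges[:-1] + edges[1:])
    else:
        raise ValueError("placement must be 'include-endpoints' or 'cell-centered'")
    neurons = tuple(template.replace(sigma=float(sg)) for sg in sigmas)
    return Population(neurons, tau)


def expected_counts(pop: Population, s) -> np.ndarray:
    return pop.expected_counts(s)


def log_likelihood(pop: Population, r, s) -> float:
    """log P(r | s) in nats.

    Returns -inf when some lambda_i = 0 but r_i > 0 (an impossible count),
    rather than raising.  Log-factorials use gammaln for stability.
    """
    r = np.asarray(r)
    if r.shape != (pop.N,):
        raise ValueError("response vector length must equal the population size")
    if np.any(r < 0) or not np.issubdtype(r.dtype, np.integer):
        r = np.asarray(r, dtype=float)
        if np.any(r < 0) or np.any(r != np.round(r)):
            raise ValueError("spike counts must be non-negative integers")
    lam = pop.expected_counts(float(s))
    r = r.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = r * np.log(lam)
    term = np.where((r == 0) & (lam == 0), 0.0, term)  # 0 * log 0 := 0
    if np.any((lam == 0) & (r > 0)):
        return float("-inf")
    return float(np.sum(term - lam - gammaln(r + 1.0)))


def sample_responses(pop: Population, s: float, M: int, seed) -> np.ndarray:
    """M i.i.d. response vectors r ~ P(r|s); reproducible given ``seed``."""
    if M < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    return pop.sample(s, M, rng)


def substream(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-stimulus random substream.

    Derived from (seed, index) so Monte-Carlo results do not depend on the
    order in which stimuli are evaluated.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))
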