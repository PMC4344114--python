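"""Stimulus ensembles for population-coding analyses.

A stimulus ensemble is a discrete probability distribution over real-valued
stimuli (arbitrary units ``A``).  Ensembles come in three flavors:

* uniform discrete ensembles of ``k`` equiprobable values on an interval,
* uniform grids standing in for a *continuous* uniform stimulus variable
  (all "continuous" analyses in this package are computed on such grids), and
* arbitrary weighted ensembles, e.g. a broadly peaked stimulus distribution.

Forced-choice (K-alternative) tasks are modeled by small ensembles of K
equiprobable stimuli regularly spaced ``delta_s`` apart; a given stimulus
``s`` can sit at any of the K positions within the set, yielding K distinct
ensembles per stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEnsemble",
    "TaskSpec",
    "make_uniform_discrete",
    "discretize_continuous",
    "make_custom_ensemble",
    "make_task_ensembles",
    "normalize_spacing",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class StimulusEnsemble:
    """A discrete distribution over stimulus values.

    Attributes
    ----------
    values : ndarray
        Strictly increasing stimulus values (units A).
    probabilities : ndarray
        Per-value probability mass; non-negative, sums to 1.
    interval : tuple of float, optional
        The (s_min, s_max) interval the ensemble was built from, if any.
    """

    values: np.ndarray
    probabilities: np.ndarray
    interval: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if values.ndim != 1 or probs.ndim != 1 or values.size != probs.size:
            raise ValueError("values and probabilities must be 1-d and equal length")
        if values.size < 1:
            raise ValueError("ensemble must contain at least one stimulus")
        if np.any(np.diff(values) <= 0):
            raise ValueError("stimulus values must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probabilities", probs)

    def __len__(self) -> int:
        return self.values.size

    @property
    def k(self) -> int:
        """Number of stimuli in the ensemble."""
        return self.values.size

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of stimuli with non-zero probability."""
        return self.probabilities > 0.0

    def entropy(self) -> float:
        """Stimulus entropy H(S) in bits, with 0 log 0 := 0."""
        p = self.probabilities[self.probabilities > 0]
        return float(-(p * np.log2(p)).sum())

    def index_of(self, s: float, atol: float = 1e-9) -> int:
        """Index of the grid value equal to ``s`` (within ``atol``)."""
        idx = int(np.argmin(np.abs(self.values - s)))
        if abs(self.values[idx] - s) > atol:
            raise ValueError(f"stimulus {s} is not on the ensemble grid")
        return idx

    # -- serialization: two-column CSV (value, probability) -----------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"value": self.values, "probability": self.probabilities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusEnsemble":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["value"].to_numpy(), df["probability"].to_numpy())


@dataclass(frozen=True)
class TaskSpec:
    """A K-alternative forced-choice task.

    ``delta_s`` is the raw spacing between adjacent alternatives (units A);
    ``delta_s_norm`` is the spacing normalized by the tuning-curve flank
    width, computed by :func:`normalize_spacing` when a tuning curve is
    available.
    """

    K: int
    delta_s: float
    delta_s_norm: float | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("a forced-choice task needs K >= 2 alternatives")
        if self.delta_s <= 0:
            raise ValueError("stimulus spacing delta_s must be positive")
        if self.delta_s_norm is not None and self.delta_s_norm <= 0:
            raise ValueError("normalized spacing must be positive")


def make_uniform_discrete(k: int, s_min: float, s_max: float) -> StimulusEnsemble:
    """Ensemble of ``k`` equiprobable stimuli regularly spaced on [s_min, s_max].

    Both endpoints are included; every probability is 1/k.
    """
    if k < 2:
        raise ValueError("need at least k=2 stimuli")
    if not s_min < s_max:
        raise ValueError("need s_min < s_max")
    values = np.linspace(s_min, s_max, k)
    probs = np.full(k, 1.0 / k)
    return StimulusEnsemble(values, probs, interval=(float(s_min), float(s_max)))


def discretize_continuous(s_min: float, s_max: float, n_grid: int) -> StimulusEnsemble:
    """Uniform grid standing in for a continuous uniform stimulus variable.

    Analyses described as using a "continuous" stimulus are computed on this
    grid; the grid size trades resolution against cost and defaults to 401 in
    the bundled fixtures.
    """
    if n_grid < 2:
        raise ValueError("need at least 2 grid points")
    return make_uniform_discrete(n_grid, s_min, s_max)


def make_custom_ensemble(values, weights) -> StimulusEnsemble:
    """Ensemble from arbitrary values and non-negative weights.

    Weights are normalized to probabilities.  Zero weights are allowed;
    information curves are undefined (NaN) at zero-probability stimuli.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have matching length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return StimulusEnsemble(values, weights / total)


def make_task_ensembles(s: float, K: int, delta_s: float) -> list[StimulusEnsemble]:
    """The K ensembles of a K-alternative task that contain stimulus ``s``.

    The m-th returned ensemble (m = 1..K) places ``s`` as its m-th member;
    members are regularly spaced ``delta_s`` apart and equiprobable.  The
    sets may extend beyond any nominal stimulus interval: tuning functions
    are defined on all reals, so no clipping is applied.
    """
    spec = TaskSpec(K=K, delta_s=delta_s)  # validates K, delta_s
    out = []
    for m in range(spec.K):
        values = s + (np.arange(spec.K) - m) * spec.delta_s
        out.append(StimulusEnsemble(values, np.full(spec.K, 1.0 / spec.K)))
    return out


def normalize_spacing(delta_s: float, tc) -> float:
    """Spacing expressed relative to the tuning-curve flank width.

    The flank width is the rate range divided by the maximum gradient,
    ``f_mod / max|f'(s)|``, so the normalized spacing is::

        delta_s_norm = delta_s * max|f'(s)| / f_mod

    and equals 1 when the raw spacing matches one flank width.
    """
    if tc.f_mod <= 0:
        raise ValueError("tuning curve must have positive modulation depth")
    return float(delta_s) * tc.max_gradient() / tc.f_mod
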