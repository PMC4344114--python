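"""Fisher information for Poisson rate-coding neurons.

For a tuning curve f(s), integration time tau and Poisson variability the
Fisher information is ``J(s) = tau * f'(s)^2 / f(s)`` (units A^-2, where A
are the stimulus units).  It is zero wherever the tuning-curve gradient is
zero -- notably at the peak of a unimodal curve -- and is additive over
conditionally independent neurons.

Although several analyses use discrete stimulus ensembles, the Fisher
information is computed by treating the stimulus as continuous (a derivative
is required); curves are simply evaluated on the ensemble grid.
"""

from __future__ import annotations

import numpy as np

from .curves import InfoCurve
from .ensembles import StimulusEnsemble
from .population import Population, TuningCurve

__all__ = ["fisher_single", "fisher_population", "fisher_curve"]


def fisher_single(tc: TuningCurve, s, tau: float):
    """Single-neuron Fisher information J(s) = tau f'(s)^2 / f(s)."""
    if tau <= 0:
        raise ValueError("integration time must be positive")
    f = np.asarray(tc.rate(s), dtype=float)
    if np.any(f <= 0):
        raise ValueError("Fisher information requires f(s) > 0 (use f_bg > 0)")
    out = tau * np.asarray(tc.rate_derivative(s), dtype=float) ** 2 / f
    return out if out.ndim else float(out)


def fisher_population(pop: Population, s):
    """Population Fisher information: sum of single-neuron terms."""
    vals = [fisher_single(tc, s, pop.tau) for tc in pop.neurons]
    out = np.sum(np.asarray(vals, dtype=float), axis=0)
    return out if np.ndim(out) else float(out)


def fisher_curve(obj, ensemble: StimulusEnsemble, tau: float | None = None) -> InfoCurve:
    """Fisher information evaluated on an ensemble grid.

    ``obj`` may be a :class:`TuningCurve` (then ``tau`` is required) or a
    :class:`Population` (its own tau is used).
    """
    s = ensemble.values
    if isinstance(obj, Population):
        values = fisher_population(obj, s)
        label = "fisher[population]"
    else:
        if tau is None:
            raise ValueError("tau is required for a single tuning curve")
        values = fisher_single(obj, s, tau)
        label = "fisher"
    return InfoCurve(s, np.asarray(values, dtype=float), None, label)
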