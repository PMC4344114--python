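"""Shape comparison of stimulus-indexed information measures.

Information measures with different units (e.g. SSI in bits, Fisher
information in A^-2) are compared by treating their values on a shared
stimulus grid as vectors, normalizing to unit Euclidean length, and taking
the dot product.  A value of 1 means the two curves are directly
proportional (identical shape); the Cauchy-Schwarz inequality bounds the
result in [-1, 1].  Negative values can occur because SSI curves may dip
below zero at unexpected stimuli; no clipping is applied.
"""

from __future__ import annotations

import numpy as np

from .curves import InfoCurve

__all__ = ["normalize_curve", "shape_similarity"]


def _unit_values(curve: InfoCurve) -> np.ndarray:
    vals = np.asarray(curve.values, dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("curve contains undefined (NaN) values")
    norm = float(np.linalg.norm(vals))
    if norm == 0.0:
        raise ValueError("cannot normalize an identically zero curve")
    return vals / norm


def normalize_curve(curve: InfoCurve) -> InfoCurve:
    """Curve scaled to unit Euclidean norm over the grid (idempotent)."""
    unit = _unit_values(curve)
    se = None
    if curve.std_errors is not None:
        se = curve.std_errors / float(np.linalg.norm(curve.values))
    return InfoCurve(curve.stimuli, unit, se, curve.label)


def shape_similarity(a: InfoCurve, b: InfoCurve) -> float:
    """Normalized dot product of two curves on the same grid, in [-1, 1]."""
    a.require_grid(b)
    return float(np.dot(_unit_values(a), _unit_values(b)))
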