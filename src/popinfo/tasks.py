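"""Forced-choice task modeling and regime-transition detection.

A K-alternative forced-choice (K-AFC) task restricts the stimulus ensemble
to K equiprobable stimuli regularly spaced ``delta_s`` apart.  A stimulus s
can occupy any of the K positions in the set, so its task SSI has K
components I_k(s) -- the SSI of s under the ensemble in which s is the k-th
member -- and the task SSI is their simple average,

    I(s) = (1/K) sum_k I_k(s).

(An alternative averaging, over the members of a single centered ensemble,
equals the mutual information of that ensemble; both are provided.)

As the normalized spacing ``delta_s_norm`` (spacing over tuning-curve flank
width) grows past roughly 1, the best-encoded stimulus indicated by the
marginal task SSI (or marginal Chernoff distance) switches from the
maximal-gradient flank (fine-discrimination regime, Fisher-like) to the
peak or flank ends (coarse-discrimination regime).
:func:`find_regime_transition` scans delta_s_norm, classifies each curve by
the location of its maximum relative to the Fisher-information maxima, and
reports the spacing at which the classification switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chernoff import marginal_chernoff
from .curves import InfoCurve
from .ensembles import make_task_ensembles, normalize_spacing
from .population import Population, TuningCurve, substream
from .ssi import MCConfig, marginal_ssi_point, ssi_point

__all__ = [
    "task_ssi_components",
    "task_ssi",
    "marginal_task_ssi_curve",
    "butts_goldman_task_ssi",
    "classify_regime",
    "find_regime_transition",
    "TransitionResult",
]


def _child_seed(seed: int, index: int) -> int:
    """Deterministic 31-bit child seed for scan step ``index``."""
    state = np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def task_ssi_components(
    pop: Population,
    grid,
    K: int,
    delta_s: float,
    mc: MCConfig,
) -> list[InfoCurve]:
    """The K task-SSI component curves I_k(s) on ``grid`` (Monte-Carlo)."""
    grid = np.asarray(getattr(grid, "values", grid), dtype=float)
    n = grid.size
    components = []
    for k in range(K):
        values = np.empty(n)
        ses = np.empty(n)
        for j, s in enumerate(grid):
            ens = make_task_ensembles(float(s), K, delta_s)[k]
            rng = substream(mc.seed, k * n + j)
            values[j], ses[j] = ssi_point(pop, ens, k, mc, rng=rng)
        se = ses if mc.report_se else None
        components.append(InfoCurve(grid, values, se, f"task-ssi[k={k + 1}/{K}]"))
    return components


def task_ssi(components: list[InfoCurve]) -> InfoCurve:
    """Pointwise mean of the K task-SSI components."""
    if not components:
        raise ValueError("need at least one component")
    first = components[0]
    for c in components[1:]:
        first.require_grid(c)
    K = len(components)
    values = np.mean([c.values for c in components], axis=0)
    se = None
    if all(c.std_errors is not None for c in components):
        se = np.sqrt(np.sum([c.std_errors**2 for c in components], axis=0)) / K
    return InfoCurve(first.stimuli, values, se, f"task-ssi[K={K}]")


def marginal_task_ssi_curve(
    pop: Population,
    i: int,
    grid,
    K: int,
    delta_s: float,
    mc: MCConfig,
) -> InfoCurve:
    """K-AFC marginal SSI of neuron ``i``, averaged over the K components.

    Each component uses common random numbers for the full/reduced paired
    difference; components use independent substreams.
    """
    grid = np.asarray(getattr(grid, "values", grid), dtype=float)
    n = grid.size
    values = np.zeros(n)
    variances = np.zeros(n)
    for k in range(K):
        for j, s in enumerate(grid):
            ens = make_task_ensembles(float(s), K, delta_s)[k]
            rng = substream(mc.seed, k * n + j)
            v, se = marginal_ssi_point(pop, i, ens, k, mc, rng=rng)
            values[j] += v / K
            variances[j] += (se / K) ** 2
    se = np.sqrt(variances) if mc.report_se else None
    return InfoCurve(grid, values, se, f"task-mssi[{i},K={K},ds={delta_s:g}]")


def butts_goldman_task_ssi(
    pop: Population,
    grid,
    delta_s: float,
    mc: MCConfig,
) -> InfoCurve:
    """Alternative 2AFC average: SSI averaged over the centered ensemble.

    At each s the ensemble is {s - delta_s/2, s + delta_s/2} and the value
    is the mean SSI of its two members -- i.e. the mutual information of
    that ensemble.  Very similar to :func:`task_ssi` for small spacings;
    the component average is the more local measure at large spacings.
    """
    if delta_s <= 0:
        raise ValueError("stimulus spacing must be positive")
    grid = np.asarray(getattr(grid, "values", grid), dtype=float)
    n = grid.size
    values = np.empty(n)
    ses = np.empty(n)
    for j, s in enumerate(grid):
        ens = make_task_ensembles(float(s) - delta_s / 2.0, 2, delta_s)[0]
        rng0 = substream(mc.seed, j)
        rng1 = substream(mc.seed, n + j)
        v0, se0 = ssi_point(pop, ens, 0, mc, rng=rng0)
        v1, se1 = ssi_point(pop, ens, 1, mc, rng=rng1)
        values[j] = 0.5 * (v0 + v1)
        ses[j] = 0.5 * np.hypot(se0, se1)
    se = ses if mc.report_se else None
    return InfoCurve(grid, values, se, f"task-ssi-mi[ds={delta_s:g}]")


# -- regime classification ---------------------------------------------------

def classify_regime(
    curve: InfoCurve,
    tc: TuningCurve,
    tau: float | None = None,
    threshold: float = 0.25,
    noise_factor: float = 2.0,
    atol: float = 1e-12,
) -> str:
    """Classify an information curve as ``"fine"``, ``"coarse"`` or ``"undefined"``.

    The coarse-discrimination regime is recognized by the location of the
    best-encoded stimulus (the curve's global argmax) reaching its
    coarse-regime attractor: the tuning-curve peak for a unimodal neuron
    (argmax within ``threshold`` flank widths of sigma), or either end of
    the flank for a monotonic neuron (argmax at least half a flank width
    from sigma).  Everything else -- best-encoded stimulus on the sloping
    flank, where the Fisher information also peaks -- is the fine regime.
    The argmax of a fine-regime curve drifts gradually outward along the
    flank as the task spacing grows, so the regime switch is marked by the
    argmax *jumping* to the coarse attractor, not by its drift.

    Curves indistinguishable from zero -- non-positive maximum, or maximum
    below ``noise_factor`` times the median standard error -- are
    ``"undefined"``.  ``threshold`` is in flank widths; ``tau`` is accepted
    for interface symmetry but unused.
    """
    vmax = np.nanmax(curve.values)
    if not np.isfinite(vmax) or vmax <= atol:
        return "undefined"
    if curve.std_errors is not None:
        med_se = np.nanmedian(curve.std_errors)
        if np.isfinite(med_se) and vmax <= noise_factor * med_se:
            return "undefined"
    offset = abs(curve.argmax_stimulus() - tc.sigma)
    width = tc.flank_width()
    if tc.kind == "unimodal":
        return "coarse" if offset <= threshold * width else "fine"
    return "coarse" if offset >= 0.5 * width else "fine"


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of a fine/coarse regime scan over normalized spacings."""

    found: bool
    delta_s_norm: float
    bracket: tuple[float, float] | None
    scan: np.ndarray
    classifications: tuple[str, ...]
    measure: str
    curves: tuple[InfoCurve, ...] = field(default=(), repr=False)


def find_regime_transition(
    pop: Population,
    i: int,
    delta_s_norm_grid,
    mc: MCConfig,
    K: int = 2,
    measure: str = "mssi",
    grid=None,
    threshold: float = 0.25,
    keep_curves: bool = False,
) -> TransitionResult:
    """Locate the fine-to-coarse regime transition of neuron ``i``.

    For each normalized spacing in ``delta_s_norm_grid`` the neuron's
    marginal task information curve (``measure="mssi"`` or ``"mdc"``) is
    computed and classified with :func:`classify_regime`; the transition is
    reported as the arithmetic midpoint of the first bracketing pair of
    spacings whose classifications switch from fine to coarse.  Sub-grid
    interpolation is deliberately avoided: Monte-Carlo noise makes it
    spurious.

    The default stimulus grid spans 2.5 flank widths either side of the
    neuron's characteristic stimulus with 101 points.
    """
    tc = pop.neurons[i]
    width = tc.flank_width()
    ds_norms = np.asarray(delta_s_norm_grid, dtype=float)
    if grid is None:
        grid = np.linspace(tc.sigma - 2.5 * width, tc.sigma + 2.5 * width, 101)
    grid = np.asarray(grid, dtype=float)

    labels: list[str] = []
    curves: list[InfoCurve] = []
    for d, ds_norm in enumerate(ds_norms):
        delta_s = ds_norm * width  # invert delta_s_norm = normalize_spacing(delta_s)
        assert abs(normalize_spacing(delta_s, tc) - ds_norm) < 1e-9
        if measure == "mssi":
            step_mc = MCConfig(mc.n_samples, _child_seed(mc.seed, d), mc.report_se)
            curve = marginal_task_ssi_curve(pop, i, grid, K, delta_s, step_mc)
        elif measure == "mdc":
            if K != 2:
                raise ValueError("the Chernoff distance is defined for K = 2 only")
            curve = marginal_chernoff(pop, i, grid, delta_s)
        else:
            raise ValueError("measure must be 'mssi' or 'mdc'")
        labels.append(classify_regime(curve, tc, threshold=threshold))
        if keep_curves:
            curves.append(curve)

    b = _changepoint(labels)
    if b is None:
        return TransitionResult(
            False, float("nan"), None, ds_norms, tuple(labels), measure, tuple(curves)
        )
    lo, hi = float(ds_norms[b - 1]), float(ds_norms[b])
    return TransitionResult(
        True, 0.5 * (lo + hi), (lo, hi), ds_norms, tuple(labels),
        measure, tuple(curves),
    )


def _changepoint(labels: list[str]) -> int | None:
    """Fine-to-coarse boundary index minimizing label misclassifications.

    More robust than the first fine/coarse switch when Monte-Carlo noise
    flips an isolated label; coincides with the unique switch for clean
    sequences.  ``undefined`` labels carry no cost.  Returns None unless at
    least one fine precedes at least one coarse.
    """
    n = len(labels)
    best_b, best_cost = None, None
    for b in range(1, n):
        if "fine" not in labels[:b] or "coarse" not in labels[b:]:
            continue
        cost = labels[:b].count("coarse") + labels[b:].count("fine")
        if best_cost is None or cost < best_cost:
            best_b, best_cost = b, cost
    return best_b
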