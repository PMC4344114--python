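"""Named model configurations for the bundled analyses.

Each fixture bundles a tuning-curve template, population size, integration
time(s), stimulus ensemble and (where relevant) task settings for one of the
stereotypical study conditions analysed with this package, so experiments
and tests can reference them symbolically.  Parameters that the modeled
condition pins down are set exactly; the rest (marked in ``unspecified``)
carry documented defaults and can be overridden.

The peaked stimulus distribution used by the ``nonuniform-prior-*`` fixtures
is a synthetic stand-in: a truncated-Gaussian-shaped weight profile chosen
to be broadly peaked relative to the tuning-curve widths.  Analyses based on
it are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensembles import (
    StimulusEnsemble,
    discretize_continuous,
    make_custom_ensemble,
)
from .population import Population, TuningCurve, make_population
from .ssi import MCConfig

__all__ = ["FixtureConfig", "get_fixture", "list_fixtures"]

# Default stand-in for per-panel integration times that the modeled
# conditions leave open: five log-spaced values, seconds.
TAU_SCAN = (0.005, 0.02, 0.08, 0.3, 1.0)


@dataclass(frozen=True)
class FixtureConfig:
    """A fully specified experiment configuration."""

    name: str
    description: str
    template: TuningCurve
    N: int
    tau: float
    interval: tuple[float, float]
    n_grid: int
    tau_list: tuple[float, ...] | None = None
    prior: str = "uniform"  # "uniform" | "peaked"
    prior_width: float = 0.3
    task_K: int | None = None
    delta_s: float | None = None
    delta_s_norm_range: tuple[float, float] | None = None
    mc: MCConfig = field(default_factory=MCConfig)
    unspecified: tuple[str, ...] = ()

    def population(self, tau: float | None = None, N: int | None = None) -> Population:
        tau = self.tau if tau is None else tau
        N = self.N if N is None else N
        return make_population(N, self.template, *self.interval, tau)

    def ensemble(self, n_grid: int | None = None) -> StimulusEnsemble:
        n = self.n_grid if n_grid is None else n_grid
        if self.prior == "uniform":
            return discretize_continuous(*self.interval, n)
        grid = np.linspace(*self.interval, n)
        weights = np.exp(-(grid**2) / (2.0 * self.prior_width**2))
        return make_custom_ensemble(grid, weights)

    def with_overrides(self, **kw) -> "FixtureConfig":
        return replace(self, **kw)

    def summary(self) -> dict:
        tc = self.template
        return {
            "name": self.name,
            "description": self.description,
            "tuning": {
                "kind": tc.kind, "f_bg": tc.f_bg, "f_mod": tc.f_mod,
                "omega": tc.omega, "sigma": tc.sigma,
            },
            "N": self.N,
            "tau": self.tau,
            "tau_list": list(self.tau_list) if self.tau_list else None,
            "interval": list(self.interval),
            "n_grid": self.n_grid,
            "prior": self.prior,
            "task_K": self.task_K,
            "delta_s": self.delta_s,
            "delta_s_norm_range": (
                list(self.delta_s_norm_range) if self.delta_s_norm_range else None
            ),
            "mc": {"n_samples": self.mc.n_samples, "seed": self.mc.seed},
            "unspecified_defaults": list(self.unspecified),
        }


def _uni(f_bg, omega=0.1):
    return TuningCurve("unimodal", f_bg=f_bg, f_mod=40.0, omega=omega, sigma=0.0)


def _mono(f_bg, omega=0.044):
    return TuningCurve("monotonic", f_bg=f_bg, f_mod=40.0, omega=omega, sigma=0.0)


_REGISTRY: dict[str, FixtureConfig] = {}


def _register(cfg: FixtureConfig) -> None:
    _REGISTRY[cfg.name] = cfg


_register(FixtureConfig(
    name="single-unimodal-rich",
    description=("Single unimodal neuron with a rich discrete ensemble: "
                 "SSI, RSI and Fisher information on one axis."),
    template=_uni(f_bg=1.0), N=1, tau=1.0, interval=(-1.0, 1.0), n_grid=401,
))

_register(FixtureConfig(
    name="single-unimodal-2afc",
    description=("Single unimodal neuron, pairwise Chernoff-distance map and "
                 "2AFC information tuning curve at spacing 0.1."),
    template=_uni(f_bg=1.0), N=1, tau=0.05, interval=(-0.5, 0.5), n_grid=101,
    task_K=2, delta_s=0.1,
))

_register(FixtureConfig(
    name="single-unimodal-bayes",
    description=("Single unimodal neuron, Bayesian-observer posterior P(Z|S) "
                 "at several noise levels (integration times)."),
    template=_uni(f_bg=5.0), N=1, tau=0.08, interval=(-0.5, 0.5), n_grid=401,
    tau_list=TAU_SCAN,
    unspecified=("per-panel tau values: log-spaced defaults {5,20,80,300,1000} ms",),
))

_register(FixtureConfig(
    name="single-monotonic-rich",
    description=("Single monotonic neuron, SSI/RSI across integration times "
                 "from 5 ms to 1 s on a rich discrete ensemble."),
    template=_mono(f_bg=5.0), N=1, tau=0.08, interval=(-0.5, 0.5), n_grid=401,
    tau_list=TAU_SCAN,
    unspecified=("per-panel tau values: log-spaced defaults {5,20,80,300,1000} ms",),
))

_register(FixtureConfig(
    name="monotonic-population-scan",
    description=("Populations of monotonic neurons: convergence of the mSSI "
                 "shape to the singleton Fisher information with N and tau."),
    template=_mono(f_bg=10.0, omega=0.1), N=16, tau=0.08,
    interval=(-1.0, 1.0), n_grid=401, tau_list=TAU_SCAN,
    unspecified=("per-point N values: defaults {4, 16, 64, 256}",
                 "per-panel tau values: log-spaced defaults"),
))

_register(FixtureConfig(
    name="nonuniform-prior-unimodal",
    description=("17 unimodal neurons under a broadly peaked stimulus "
                 "distribution; mSSI of center and flank neurons."),
    template=_uni(f_bg=10.0), N=17, tau=0.5, interval=(-1.0, 1.0), n_grid=401,
    prior="peaked",
    unspecified=("peaked p(s): synthetic truncated-Gaussian stand-in, width 0.3",),
))

_register(FixtureConfig(
    name="nonuniform-prior-monotonic",
    description=("17 monotonic neurons under a broadly peaked stimulus "
                 "distribution; mSSI of center and flank neurons."),
    template=_mono(f_bg=10.0), N=17, tau=0.5, interval=(-1.0, 1.0), n_grid=401,
    prior="peaked",
    unspecified=("peaked p(s): synthetic truncated-Gaussian stand-in, width 0.3",),
))

_register(FixtureConfig(
    name="2afc-unimodal-small",
    description=("Small unimodal population, 2AFC mSSI across normalized "
                 "spacings 0.1-3.5."),
    template=_uni(f_bg=10.0), N=4, tau=0.005, interval=(-1.0, 1.0), n_grid=201,
    task_K=2, delta_s_norm_range=(0.1, 3.5),
    unspecified=("N and tau: defaults N=4, tau=5 ms (small population, high noise)",),
))

_register(FixtureConfig(
    name="2afc-monotonic-small",
    description=("Small monotonic population, 2AFC mSSI across normalized "
                 "spacings 0.01-1."),
    template=_mono(f_bg=10.0, omega=0.1), N=4, tau=0.005,
    interval=(-1.0, 1.0), n_grid=201,
    task_K=2, delta_s_norm_range=(0.01, 1.0),
    unspecified=("N and tau: defaults N=4, tau=5 ms (small population, high noise)",),
))

_register(FixtureConfig(
    name="kafc-scan-unimodal",
    description=("81 unimodal neurons, tau=20 ms: K-AFC regime scan over "
                 "normalized spacings 0.16-1.6 (mSSI and marginal Chernoff)."),
    template=_uni(f_bg=10.0), N=81, tau=0.02, interval=(-1.0, 1.0), n_grid=401,
    task_K=2, delta_s_norm_range=(0.16, 1.6),
))

_register(FixtureConfig(
    name="kafc-scan-monotonic",
    description=("81 monotonic neurons, tau=20 ms: K-AFC regime scan over "
                 "normalized spacings 0.16-1.6 (mSSI and marginal Chernoff)."),
    template=_mono(f_bg=10.0), N=81, tau=0.02, interval=(-1.0, 1.0), n_grid=401,
    task_K=2, delta_s_norm_range=(0.16, 1.6),
))


def get_fixture(name: str) -> FixtureConfig:
    """Look up a fixture by name; raises KeyError with the known names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known fixtures: {sorted(_REGISTRY)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)
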