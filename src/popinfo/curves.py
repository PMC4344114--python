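"""Stimulus-indexed information curves.

Every measure in this package (Fisher information, SSI, marginal SSI,
Chernoff task curves, posterior-entropy measures) evaluates to a value per
stimulus on a grid; :class:`InfoCurve` is the shared container, with optional
per-point Monte-Carlo standard errors and CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["InfoCurve"]


@dataclass(frozen=True)
class InfoCurve:
    """An information measure evaluated on a stimulus grid.

    Units depend on the measure: bits for the SSI family, nats for Chernoff
    distances (unless converted), A^-2 for Fisher information.  NaN values
    mark stimuli where the measure is undefined (e.g. zero prior
    probability).
    """

    stimuli: np.ndarray
    values: np.ndarray
    std_errors: np.ndarray | None = field(default=None)
    label: str = ""

    def __post_init__(self) -> None:
        stim = np.asarray(self.stimuli, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if stim.shape != vals.shape or stim.ndim != 1:
            raise ValueError("stimuli and values must be 1-d and equal length")
        object.__setattr__(self, "stimuli", stim)
        object.__setattr__(self, "values", vals)
        if self.std_errors is not None:
            se = np.asarray(self.std_errors, dtype=float)
            if se.shape != stim.shape:
                raise ValueError("std_errors must match the stimulus grid")
            if np.any(se[np.isfinite(se)] < 0):
                raise ValueError("standard errors must be non-negative")
            object.__setattr__(self, "std_errors", se)

    def __len__(self) -> int:
        return self.stimuli.size

    def same_grid(self, other: "InfoCurve", atol: float = 1e-9) -> bool:
        return self.stimuli.shape == other.stimuli.shape and bool(
            np.allclose(self.stimuli, other.stimuli, atol=atol)
        )

    def require_grid(self, other: "InfoCurve") -> None:
        if not self.same_grid(other):
            raise ValueError("curves are defined on different stimulus grids")

    def argmax_stimulus(self) -> float:
        """Stimulus at which the curve is maximal (NaNs ignored)."""
        return float(self.stimuli[np.nanargmax(self.values)])

    def with_label(self, label: str) -> "InfoCurve":
        return InfoCurve(self.stimuli, self.values, self.std_errors, label)

    def __add__(self, other: "InfoCurve") -> "InfoCurve":
        self.require_grid(other)
        se = _combine_se(self.std_errors, other.std_errors)
        return InfoCurve(self.stimuli, self.values + other.values, se, self.label)

    def __sub__(self, other: "InfoCurve") -> "InfoCurve":
        self.require_grid(other)
        se = _combine_se(self.std_errors, other.std_errors)
        return InfoCurve(self.stimuli, self.values - other.values, se, self.label)

    def scaled(self, c: float) -> "InfoCurve":
        se = None if self.std_errors is None else abs(c) * self.std_errors
        return InfoCurve(self.stimuli, c * self.values, se, self.label)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stimulus": self.stimuli, "value": self.values})
        df["std_error"] = self.std_errors if self.std_errors is not None else np.nan
        df["label"] = self.label
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InfoCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        se = df["std_error"].to_numpy() if "std_error" in df else None
        if se is not None and np.all(np.isnan(se)):
            se = None
        label = ""
        if "label" in df and len(df) and isinstance(df["label"].iloc[0], str):
            label = df["label"].iloc[0]
        return cls(df["stimulus"].to_numpy(), df["value"].to_numpy(), se, label)


def _combine_se(a: np.ndarray | None, b: np.ndarray | None) -> np.ndarray | None:
    # Worst-case independent-error propagation; curves estimated with common
    # random numbers carry their own paired SE and bypass this.
    if a is None and b is None:
        return None
    if a is None:
        return b
    if b is None:
        return a
    return np.sqrt(a**2 + b**2)
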