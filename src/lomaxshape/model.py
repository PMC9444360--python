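"""Lomax (Pareto type II) distribution primitives.

The Lomax law has density

    f(x; shape, scale) = (shape/scale) * (1 + x/scale)^-(shape+1),   x >= 0,

survival function (1 + t/scale)^-shape and CDF 1 minus that.  Throughout
this package the scale ``delta`` is treated as a known constant and the
shape ``theta`` (the tail index) is the estimation target.

The central reduction used everywhere downstream: if X ~ Lomax(theta, delta)
then ln(1 + X/delta) is exponential with rate theta, so the statistic

    T = sum_i ln(1 + x_i/delta)  ~  Gamma(n, rate=theta)

is complete and sufficient for theta.  :func:`sufficient_stat` computes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "LomaxParams",
    "Sample",
    "SufficientStat",
    "pdf",
    "cdf",
    "survival",
    "quantile",
    "sample",
    "sufficient_stat",
    "read_sample",
    "write_sample",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class LomaxParams:
    """A (shape, scale) pair; both must be strictly positive."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0):
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class Sample:
    """Observed nonnegative failure times, in any order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("sample must be a nonempty 1-d array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("sample values must be finite and nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SufficientStat:
    """(n, T) with T = sum of ln(1 + x_i/scale); T ~ Gamma(n, rate=shape)."""

    n: int
    T: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.T < 0:
            raise ValueError("T must be nonnegative")


def _check_nonneg(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def pdf(x: ArrayLike, params: LomaxParams) -> ArrayLike:
    """Density (shape/scale)(1 + x/scale)^-(shape+1) at x >= 0."""
    arr = _check_nonneg(x, "x")
    out = (params.shape / params.scale) * (1.0 + arr / params.scale) ** -(params.shape + 1.0)
    return out if arr.ndim else float(out)


def cdf(x: ArrayLike, params: LomaxParams) -> ArrayLike:
    """Distribution function 1 - (1 + x/scale)^-shape at x >= 0."""
    arr = _check_nonneg(x, "x")
    out = 1.0 - (1.0 + arr / params.scale) ** -params.shape
    return out if arr.ndim else float(out)


def survival(t: ArrayLike, params: LomaxParams) -> ArrayLike:
    """Reliability R(t) = (1 + t/scale)^-shape at t >= 0."""
    arr = _check_nonneg(t, "t")
    out = (1.0 + arr / params.scale) ** -params.shape
    return out if arr.ndim else float(out)


def quantile(u: ArrayLike, params: LomaxParams) -> ArrayLike:
    """Inverse CDF: x = scale * ((1-u)^(-1/shape) - 1) for u in [0, 1)."""
    arr = np.asarray(u, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("u must lie in [0, 1)")
    out = params.scale * ((1.0 - arr) ** (-1.0 / params.shape) - 1.0)
    return out if arr.ndim else float(out)


def sample(params: LomaxParams, n: int, rng: np.random.Generator) -> Sample:
    """Draw n i.i.d. values by the inverse-CDF transform.

    Uses x = scale * ((1 - U)^(-1/shape) - 1) on U ~ Uniform(0,1), keeping
    the (1 - U) orientation so a recorded uniform stream reproduces the
    draws bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    return Sample(params.scale * ((1.0 - u) ** (-1.0 / params.shape) - 1.0))


def sufficient_stat(samp: Sample, scale: float) -> SufficientStat:
    """T = sum of ln(1 + x_i/scale); permutation invariant by construction."""
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    return SufficientStat(n=samp.n, T=float(np.log1p(samp.values / scale).sum()))


def read_sample(path: Union[str, Path]) -> Sample:
    """Read a sample from single-column plain text or CSV with header ``x``."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0].strip()
    if first.lower() == "x":
        values = pd.read_csv(path)["x"].to_numpy(dtype=float)
    else:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    return Sample(values)


def write_sample(samp: Sample, path: Union[str, Path]) -> None:
    """Write a sample as CSV with header ``x``."""
    pd.DataFrame({"x": samp.values}).to_csv(path, index=False)
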