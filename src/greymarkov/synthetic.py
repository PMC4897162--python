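"""Synthetic series with the model's assumed structure.

Every stage of the package is testable without real data: series are
drawn from the model's own generating assumption — an exponential
trend ``x0(k) = 2*M*exp(a*(k-1))`` perturbed by *multiplicative* noise
on the ratio scale, either a uniform band or a hidden discrete-state
Markov chain whose state selects the band (the structure the state
layer is designed to recover).  Additive noise is deliberately not
offered: the model's accuracy indicator is a ratio, so only ratio-scale
perturbations keep the generating process inside the model family.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream; the fitting path itself is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import StatePath, StateSpace
from .series import TimeSeries

__all__ = ["SyntheticSpec", "generate_gray_series", "generate_state_series"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for a synthetic annual series.

    ``a`` and ``M`` are the true trend parameters (``a < 0`` gives a
    declining series like the case study); ``noise`` is ``"none"`` or
    ``"uniform"`` with ``band = (lo, hi)`` multiplicative bounds;
    ``chain`` (row-stochastic matrix) plus ``space`` drive the
    state-modulated generator.  ``first_label`` is the first period.
    """

    a: float
    M: float
    n: int
    seed: int = 0
    noise: str = "none"
    band: tuple[float, float] = (0.95, 1.05)
    chain: np.ndarray | None = None
    space: StateSpace | None = None
    first_label: int = 2001

    def __post_init__(self):
        if self.n < 6:
            raise ValueError("n must be >= 6")
        if self.M <= 0:
            raise ValueError("M must be positive")
        if self.noise not in ("none", "uniform", "state"):
            raise ValueError(f"unknown noise kind {self.noise!r}")
        if self.noise == "uniform" and self.band[0] <= 0:
            raise ValueError("noise band must exclude 0 (multiplicative)")
        if self.chain is not None:
            p = np.asarray(self.chain, dtype=float)
            if p.ndim != 2 or p.shape[0] != p.shape[1]:
                raise ValueError("chain must be a square matrix")
            if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError("chain rows must be probabilities summing to 1")


def _trend(spec: SyntheticSpec) -> np.ndarray:
    k = np.arange(1, spec.n + 1, dtype=float)
    return 2.0 * spec.M * np.exp(spec.a * (k - 1))


def generate_gray_series(spec: SyntheticSpec) -> TimeSeries:
    """Exponential-trend series with optional uniform ratio-band noise."""
    if spec.noise not in ("none", "uniform"):
        raise ValueError("generate_gray_series supports noise 'none' or 'uniform'")
    values = _trend(spec)
    if spec.noise == "uniform":
        rng = np.random.default_rng(spec.seed)
        values = values * rng.uniform(spec.band[0], spec.band[1], size=spec.n)
    labels = range(spec.first_label, spec.first_label + spec.n)
    return TimeSeries.from_pairs(zip(labels, values))


def generate_state_series(spec: SyntheticSpec) -> tuple[TimeSeries, StatePath]:
    """Series whose ratio noise is driven by a hidden Markov chain.

    A state path is sampled from ``spec.chain`` (initial state uniform);
    each period's multiplicative factor is drawn uniformly inside the
    current state's ratio band from ``spec.space``.  Returns the series
    together with the true path for recovery tests.  Bands must not
    overlap (they are contiguous intervals of a :class:`StateSpace`) and
    must be positive.
    """
    if spec.chain is None or spec.space is None:
        raise ValueError("state generation requires both chain and space")
    m = spec.space.m
    if np.asarray(spec.chain).shape != (m, m):
        raise ValueError("chain size must match the number of states")
    if spec.space.boundaries[0] <= 0:
        raise ValueError("ratio bands must be strictly positive")
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.chain, dtype=float)
    states = np.empty(spec.n, dtype=int)
    states[0] = rng.integers(1, m + 1)
    for t in range(1, spec.n):
        states[t] = rng.choice(m, p=p[states[t - 1] - 1]) + 1
    eta = np.empty(spec.n)
    for t, s in enumerate(states):
        lo, hi = spec.space.interval(int(s))
        eta[t] = rng.uniform(lo, hi)
    values = _trend(spec) * eta
    labels = range(spec.first_label, spec.first_label + spec.n)
    series = TimeSeries.from_pairs(zip(labels, values))
    return series, StatePath(states=tuple(int(s) for s in states), space=spec.space)
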