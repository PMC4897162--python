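"""Markov state adjustment of the fit-ratio indicator.

The ratio ``Y(k) = actual / predicted`` is discretised into ``m``
contiguous interval states ``E_i = [lo_i, hi_i)`` (top interval
closed).  Transition probabilities between states are estimated by
counting ``r``-step pairs along the observed state path; the next
state is the argmax of the current state's row of the one-step
matrix, with multi-step matrices consulted on ties.  A forecast is
adjusted by replacing the point ratio with the predicted state's
interval midpoint: ``adjusted = base * (lo_i + hi_i) / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import diags
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "StateSpace",
    "StatePath",
    "TransitionModel",
    "AdjustedForecast",
    "divide_states",
    "assign_states",
    "transition_model",
    "predict_state",
    "adjust_forecast",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered, contiguous ratio-band states.

    ``boundaries`` has ``m + 1`` strictly increasing entries; state
    ``i`` (1-based) spans ``[boundaries[i-1], boundaries[i])``, the top
    state is closed above.  Labels default to ``E1..Em``.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.boundaries) < 2:
            raise ValueError("need at least 2 boundaries (1 state)")
        b = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not self.labels:
            object.__setattr__(
                self, "labels",
                tuple(f"E{i}" for i in range(1, len(self.boundaries))),
            )
        if len(self.labels) != self.m:
            raise ValueError("one label per state required")

    @property
    def m(self) -> int:
        return len(self.boundaries) - 1

    def interval(self, state: int) -> tuple[float, float]:
        """Ratio band ``[lo, hi]`` of 1-based state ``state``."""
        if not 1 <= state <= self.m:
            raise ValueError(f"state must be in 1..{self.m}")
        return self.boundaries[state - 1], self.boundaries[state]

    def midpoint(self, state: int) -> float:
        lo, hi = self.interval(state)
        return (lo + hi) / 2.0

    def offsets(self, ratio: float, state: int) -> tuple[float, float]:
        """Constants ``(A, B)`` such that the band is ``[Y+A, Y+B]`` for
        ratio ``Y`` — the time-varying form of the interval bounds."""
        lo, hi = self.interval(state)
        return lo - ratio, hi - ratio


@dataclass(frozen=True)
class StatePath:
    """1-based state assignments for consecutive indices."""

    states: tuple[int, ...]
    space: StateSpace

    def __post_init__(self):
        if any(not 1 <= s <= self.space.m for s in self.states):
            raise ValueError("state path contains an unknown state")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class TransitionModel:
    """r-step transition counts and row-normalised probabilities.

    ``counts[i, j]`` is the number of observed ``E_{i+1} -> E_{j+1}``
    transitions ``r`` steps apart; ``visits[i]`` their row sums.  Rows
    with no visits have NaN probabilities and are flagged undefined.
    """

    step: int
    counts: np.ndarray
    visits: np.ndarray
    probabilities: np.ndarray

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    def row_defined(self, state: int) -> bool:
        return bool(self.visits[state - 1] > 0)

    def to_frame(self):
        """Probability matrix as a labelled DataFrame (CSV-exportable)."""
        import pandas as pd

        labels = [f"E{i}" for i in range(1, self.m + 1)]
        return pd.DataFrame(self.probabilities, index=labels, columns=labels)

    def row(self, state: int) -> np.ndarray:
        """Probability row of 1-based ``state`` (uniform fallback, with a
        warning, when the state was never visited with a successor)."""
        if not self.row_defined(state):
            warnings.warn(
                f"state E{state} has no observed {self.step}-step "
                "transitions; using a uniform row", stacklevel=2,
            )
            return np.full(self.m, 1.0 / self.m)
        return self.probabilities[state - 1]


@dataclass(frozen=True)
class AdjustedForecast:
    """A point forecast replaced by the predicted band's midpoint ratio."""

    base_value: float
    state: int
    interval: tuple[float, float]
    adjusted_ratio: float
    adjusted_value: float

    @property
    def rounded(self) -> int:
        return int(round(self.adjusted_value))


def divide_states(ratios: Sequence[float], m: int = 4, method: str = "cluster",
                  boundaries: Sequence[float] | None = None) -> StateSpace:
    """Divide the ratio range into ``m`` contiguous interval states.

    ``method="fixed"`` uses explicit ``boundaries``; ``"equal_width"``
    splits ``[min, max]`` evenly; ``"cluster"`` runs 1-D agglomerative
    clustering (complete linkage, contiguity-constrained) and places
    boundaries at midpoints between adjacent clusters.  Cluster and
    equal-width outer bounds are padded outward to whole percents so
    the bands read naturally (e.g. 60%-75%).
    """
    if method == "fixed":
        if boundaries is None:
            raise ValueError("fixed method requires explicit boundaries")
        return StateSpace(tuple(float(b) for b in boundaries))
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("ratios must be non-empty")
    if m < 1:
        raise ValueError("m must be >= 1")
    distinct = np.unique(r)
    if m > distinct.size:
        raise ValueError(
            f"cannot form {m} states from {distinct.size} distinct ratios"
        )
    lo = np.floor(r.min() * 100.0) / 100.0
    hi = np.ceil(r.max() * 100.0) / 100.0
    if method == "equal_width":
        return StateSpace(tuple(np.linspace(lo, hi, m + 1)))
    if method != "cluster":
        raise ValueError(f"unknown method {method!r}; "
                         "choose fixed, equal_width or cluster")
    if m == 1:
        return StateSpace((lo, hi))
    order = np.argsort(distinct)  # already sorted; explicit for clarity
    x = distinct[order].reshape(-1, 1)
    # chain connectivity restricts merges to neighbours in ratio order,
    # so clusters are contiguous intervals on the line
    conn = diags([1.0, 1.0], [-1, 1], shape=(x.shape[0], x.shape[0]),
                 format="csr")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn notes the connectivity graph
        labels = AgglomerativeClustering(
            n_clusters=m, linkage="complete", connectivity=conn,
        ).fit_predict(x)
    # order cluster ids by position and cut at midpoints between clusters
    cuts = []
    for i in range(1, x.shape[0]):
        if labels[i] != labels[i - 1]:
            cuts.append((x[i - 1, 0] + x[i, 0]) / 2.0)
    bounds = [lo, *sorted(cuts), hi]
    return StateSpace(tuple(bounds))


def assign_states(ratios: Sequence[float], space: StateSpace) -> StatePath:
    """Map each ratio to its state by the half-open convention.

    Out-of-range ratios are clipped to the nearest extreme state with a
    warning.
    """
    b = np.asarray(space.boundaries)
    out = []
    for y in np.asarray(ratios, dtype=float):
        if y < b[0] or y > b[-1]:
            warnings.warn(
                f"ratio {y:.4f} outside [{b[0]}, {b[-1]}]; "
                "clipped to the nearest extreme state", stacklevel=2,
            )
            out.append(1 if y < b[0] else space.m)
            continue
        # np.searchsorted with side='right' gives the half-open rule
        # [lo, hi); the top boundary folds into the last state
        s = int(np.searchsorted(b, y, side="right"))
        out.append(min(s, space.m))
    return StatePath(states=tuple(out), space=space)


def transition_model(path: StatePath, step: int = 1) -> TransitionModel:
    """Count ``step``-apart state pairs along the path and normalise rows."""
    if step <= 0:
        raise ValueError("step must be a positive integer")
    if len(path) <= step:
        raise ValueError(f"path of length {len(path)} has no {step}-step pairs")
    m = path.space.m
    counts = np.zeros((m, m), dtype=int)
    s = path.states
    for i, j in zip(s[:-step], s[step:]):
        counts[i - 1, j - 1] += 1
    visits = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / visits[:, None]
    probs[visits == 0] = np.nan
    return TransitionModel(step=step, counts=counts, visits=visits,
                           probabilities=probs)


def _argmax_candidates(row: np.ndarray, candidates: list[int]) -> list[int]:
    sub = row[[c - 1 for c in candidates]]
    best = sub.max()
    return [c for c, v in zip(candidates, sub) if np.isclose(v, best, atol=1e-12)]


def predict_state(models: Sequence[TransitionModel], current: int) -> int:
    """Most likely next state from ``current``.

    Takes the argmax of the current state's row of the 1-step matrix;
    ties are broken by consulting the supplied higher-step matrices in
    order, then by proximity to the current state, then by the lower
    state index.
    """
    if not models:
        raise ValueError("at least the 1-step transition model is required")
    candidates = list(range(1, models[0].m + 1))
    for model in models:
        candidates = _argmax_candidates(model.row(current), candidates)
        if len(candidates) == 1:
            return candidates[0]
    nearest = min(abs(c - current) for c in candidates)
    candidates = [c for c in candidates if abs(c - current) == nearest]
    return min(candidates)


def adjust_forecast(base_value: float, state: int, space: StateSpace) -> AdjustedForecast:
    """Adjust a base prediction by the state's interval-midpoint ratio."""
    if base_value <= 0:
        raise ValueError("base_value must be positive")
    lo, hi = space.interval(state)
    ratio = (lo + hi) / 2.0
    return AdjustedForecast(
        base_value=float(base_value), state=state, interval=(lo, hi),
        adjusted_ratio=ratio, adjusted_value=float(base_value) * ratio,
    )
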