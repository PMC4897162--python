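"""End-to-end forecasting pipeline and report writers.

``run_pipeline`` composes the three stages in order — grey fit,
iterated residual correction, Markov state adjustment — and returns a
fully deterministic :class:`ForecastReport`: per-year fitted, amended
and state-adjusted values with their absolute relative errors, the
state space and transition matrices, and a decline-rate summary.

Horizon forecasting freezes everything estimated on the training
window: the grey parameters, every residual layer (applied with its
extrapolation sign), and the transition matrices; the state chain is
propagated by repeated one-step prediction from the last observed
state.  Nothing is refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, markov, residual
from .errors import DegenerateTrendError
from .series import TimeSeries

__all__ = [
    "PipelineConfig",
    "ForecastReport",
    "run_pipeline",
    "average_decline_rate",
    "extrapolate_decline",
    "write_report",
    "read_report",
]

logger = logging.getLogger("greymarkov")

REPORT_FORMATS = ("json", "csv", "table")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline settings.

    ``exponent_shift=1`` evaluates restored values as
    ``2*M*exp(a*k)`` — the published-table convention of the case
    study; ``0`` uses the model's own ``exp(a*(k-1))`` anchoring.
    ``boundaries`` forces fixed state bands; otherwise ``state_method``
    (``cluster`` or ``equal_width``) divides the observed ratios into
    ``m`` states.  ``max_transition_step`` caps the multi-step matrices
    used for tie-breaking.
    """

    tol: float = 0.10
    max_rounds: int = 3
    state_method: str = "cluster"
    boundaries: tuple[float, ...] | None = None
    m: int = 4
    horizon: int = 0
    max_transition_step: int = 3
    exponent_shift: int = 1

    def __post_init__(self):
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.boundaries is not None:
            b = np.asarray(self.boundaries, dtype=float)
            if np.any(np.diff(b) <= 0):
                raise ValueError("boundaries must be strictly increasing")


@dataclass(frozen=True)
class ReportRow:
    """One period of the report (in-sample or horizon)."""

    label: int
    k: int
    actual: float | None
    grey: float
    amended: float
    ratio: float | None
    state: int | None
    predicted_state: int | None
    markov: float | None
    grey_error: float | None = None
    amended_error: float | None = None
    markov_error: float | None = None


@dataclass(frozen=True)
class ForecastReport:
    """Deterministic result of a pipeline run; serialises to plain JSON."""

    params: core.SCGMParameters
    stack: residual.CorrectionStack
    space: markov.StateSpace
    transitions: tuple[markov.TransitionModel, ...]
    rows: tuple[ReportRow, ...]
    decline_rate: float
    decline_window: tuple[int, int]
    projected_next: int
    config: PipelineConfig

    def row_for(self, label: int) -> ReportRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(f"no report row for label {label}")

    def to_dict(self) -> dict:
        p = self.params
        return {
            "parameters": {
                "a": p.a, "b": _none_if_nan(p.b), "c": _none_if_nan(p.c),
                "U": _none_if_nan(p.U), "M": p.M, "degenerate": p.degenerate,
            },
            "exponent_shift": self.config.exponent_shift,
            "offset_exponent_note": (
                "the offset c uses regressor exp(a*k), one step ahead of "
                "the amplitude regressor exp(a*(k-1))"
            ),
            "correction": {
                "tol": _json_num(self.stack.tol),
                "rounds": self.stack.rounds,
                "stopped_by": self.stack.stopped_by,
                "layers": [
                    {
                        "order": L.order, "a": L.a, "b": L.b, "M": L.M,
                        "kind": L.kind, "constant": L.constant,
                        "ks": list(L.ks), "signs": list(L.sign_map),
                        "extrapolation_sign": L.extrapolation_sign,
                    }
                    for L in self.stack.layers
                ],
            },
            "states": {
                "boundaries": list(self.space.boundaries),
                "labels": list(self.space.labels),
            },
            "transitions": [
                {
                    "step": t.step,
                    "counts": t.counts.tolist(),
                    "probabilities": [
                        [None if not np.isfinite(v) else v for v in row]
                        for row in t.probabilities
                    ],
                }
                for t in self.transitions
            ],
            "rows": [
                {
                    "label": r.label, "k": r.k, "actual": r.actual,
                    "grey": r.grey, "amended": r.amended, "ratio": r.ratio,
                    "state": r.state, "predicted_state": r.predicted_state,
                    "markov": r.markov, "grey_error": r.grey_error,
                    "amended_error": r.amended_error,
                    "markov_error": r.markov_error,
                }
                for r in self.rows
            ],
            "decline": {
                "window": list(self.decline_window),
                "rate_percent": self.decline_rate,
                "projected_next": self.projected_next,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def display_frame(self) -> pd.DataFrame:
        """Table-style view: integer counts, whole-percent ratios,
        3-decimal errors (presentation only; JSON keeps full precision)."""
        recs = []
        for r in self.rows:
            recs.append({
                "year": r.label,
                "actual": None if r.actual is None else int(round(r.actual)),
                "grey": int(round(r.grey)),
                "amended": int(round(r.amended)),
                "ratio_pct": None if r.ratio is None else int(round(r.ratio * 100)),
                "state": None if r.state is None else f"E{r.state}",
                "markov": None if r.markov is None else int(round(r.markov)),
                "amended_err": _round3(r.amended_error),
                "markov_err": _round3(r.markov_error),
            })
        return pd.DataFrame.from_records(recs)


def _none_if_nan(v: float) -> float | None:
    return None if v is None or not np.isfinite(v) else float(v)


def _json_num(v: float):
    return None if np.isinf(v) else v


def _round3(v: float | None) -> float | None:
    return None if v is None else round(v, 3)


def average_decline_rate(values: Sequence[float]) -> float:
    """Mean year-over-year percent decline, ``100*(1 - v_t/v_{t-1})``,
    over a window of consecutive values; reported to 1 decimal."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    declines = 100.0 * (1.0 - v[1:] / v[:-1])
    return float(round(float(np.mean(declines)), 1))


def extrapolate_decline(last_value: float, rate: float) -> int:
    """Project one step ahead at a constant percent decline rate."""
    if rate >= 100:
        raise ValueError("rate must be below 100%")
    return int(round(last_value * (1.0 - rate / 100.0)))


class _StageContext:
    """Logs the active stage and attaches its name to escaping errors."""

    def __init__(self):
        self.name = "setup"

    def __call__(self, name: str):
        self.name = name
        logger.info("stage: %s", name)


def run_pipeline(series: TimeSeries, config: PipelineConfig | None = None) -> ForecastReport:
    """Fit, correct, state-adjust and (optionally) forecast a horizon."""
    config = config or PipelineConfig()
    stage = _StageContext()
    try:
        return _run(series, config, stage)
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage.name}")
        raise


def _run(series: TimeSeries, config: PipelineConfig, _stage) -> ForecastReport:
    n = series.n
    shift = config.exponent_shift

    _stage("grey fit")
    params = core.fit(series)
    logger.info("parameters: a=%.6g b=%.6g M=%.6g degenerate=%s",
                params.a, params.b, params.M, params.degenerate)
    if params.degenerate and config.horizon > 0:
        raise DegenerateTrendError(
            "series has no exponential trend (a ~ 0); refusing to extrapolate"
        )

    _stage("residual correction")
    stack = residual.iterate_corrections(
        series, params, tol=config.tol, max_rounds=config.max_rounds, shift=shift,
    )
    logger.info("correction stopped by %s after %d round(s)",
                stack.stopped_by, stack.rounds)
    ks = list(range(2, n + 1))
    grey_fit = core.restored_fit(params, ks, shift=shift)
    amended = residual.apply_corrections(grey_fit, stack, ks)
    diag = core.diagnostics(series, amended)
    ratios = diag.ratio

    _stage("state division")
    if config.boundaries is not None:
        space = markov.divide_states(ratios, method="fixed",
                                     boundaries=config.boundaries)
    else:
        space = markov.divide_states(ratios, m=config.m,
                                     method=config.state_method)
    path = markov.assign_states(ratios, space)
    logger.info("states: %s", list(zip(space.labels, zip(space.boundaries,
                                                         space.boundaries[1:]))))

    _stage("transition estimation")
    models = tuple(
        markov.transition_model(path, step=r)
        for r in range(1, config.max_transition_step + 1)
        if len(path) > r
    )

    actual = series.array()
    rows: list[ReportRow] = []
    for i, k in enumerate(ks):
        label = series.label_for_index(k)
        act = float(actual[k - 1])
        state = path.states[i]
        pred_state = None
        mk_value = None
        mk_err = None
        if i > 0:
            # one-step-ahead adjustment: predict this year's state from
            # the previous year's observed state, frozen matrices
            pred_state = markov.predict_state(models, path.states[i - 1])
            adj = markov.adjust_forecast(float(amended[i]), pred_state, space)
            mk_value = adj.adjusted_value
            mk_err = abs(mk_value - act) / act
        rows.append(ReportRow(
            label=label, k=k, actual=act,
            grey=float(grey_fit[i]), amended=float(amended[i]),
            ratio=float(ratios[i]), state=state, predicted_state=pred_state,
            markov=mk_value,
            grey_error=abs(float(grey_fit[i]) - act) / act,
            amended_error=abs(float(amended[i]) - act) / act,
            markov_error=mk_err,
        ))

    if config.horizon > 0:
        _stage("horizon forecast")
        h_ks = list(range(n + 1, n + 1 + config.horizon))
        h_grey = core.restored_fit(params, h_ks, shift=shift)
        h_amended = residual.apply_corrections(h_grey, stack, h_ks)
        state = path.states[-1]
        for i, k in enumerate(h_ks):
            state = markov.predict_state(models, state)
            adj = markov.adjust_forecast(float(h_amended[i]), state, space)
            rows.append(ReportRow(
                label=series.label_for_index(k), k=k, actual=None,
                grey=float(h_grey[i]), amended=float(h_amended[i]),
                ratio=None, state=None, predicted_state=state,
                markov=adj.adjusted_value,
            ))

    _stage("decline summary")
    rate = average_decline_rate(actual)
    projected = extrapolate_decline(actual[-1], rate)
    return ForecastReport(
        params=params, stack=stack, space=space, transitions=models,
        rows=tuple(rows), decline_rate=rate,
        decline_window=(series.labels[0], series.labels[-1]),
        projected_next=projected, config=config,
    )


def render_table(report: ForecastReport) -> str:
    """Plain-text table mirroring the published layout."""
    frame = report.display_frame()
    p = report.params
    lines = [
        f"SCGM(1,1)_c fit: a={p.a:.6f}  b={p.b:.1f}  M={p.M:.1f}"
        + ("  [degenerate]" if p.degenerate else ""),
        f"residual correction: {report.stack.rounds} round(s), "
        f"stopped by {report.stack.stopped_by}",
        "states: " + ", ".join(
            f"{lab} [{lo:.2f}, {hi:.2f})"
            for lab, lo, hi in zip(report.space.labels,
                                   report.space.boundaries,
                                   report.space.boundaries[1:])
        ),
        "",
        frame.to_string(index=False, na_rep="-"),
        "",
        f"average decline rate {report.decline_window[0]}-"
        f"{report.decline_window[1]}: {report.decline_rate}%  "
        f"(next-year projection at that rate: {report.projected_next})",
    ]
    return "\n".join(lines)


def write_report(report: ForecastReport, path: str | Path, format: str = "json") -> Path:
    """Serialise a report.  ``json`` is canonical full precision;
    ``csv`` and ``table`` apply the display rounding."""
    if format not in REPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; choose one of {', '.join(REPORT_FORMATS)}"
        )
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json() + "\n", encoding="utf-8")
    elif format == "csv":
        report.display_frame().to_csv(path, index=False)
    else:
        path.write_text(render_table(report) + "\n", encoding="utf-8")
    return path


def read_report(path: str | Path) -> dict:
    """Load a JSON report back into its dictionary form (the canonical
    representation; compare with ``report.to_dict()``)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
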