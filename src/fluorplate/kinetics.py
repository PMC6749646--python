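"""NPQ induction/relaxation kinetics: exponential fits and half-times.

After a step change in actinic PPFD, non-photochemical quenching moves
exponentially toward a new steady state.  A step down is followed by a
relaxation, modelled as

    y(t) = baseline + a * exp(-b * t)

and a step up by a saturating induction,

    y(t) = plateau - a * exp(-b * t),

with rate b (s⁻¹), time constant t = 1/b and half-time ln(2)/b.  The
half-times are the R50 (relaxation) and I50 (induction) summary
statistics.  The asymptote (baseline/plateau) is fixed to the final
observed value of the segment by default — a pure zero-baseline decay is
biased whenever NPQ relaxes to a nonzero minimum, which it does in
practice — and both a literal zero-asymptote decay and a free or
user-supplied asymptote are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocol import LightProtocol

__all__ = [
    "KineticsFit",
    "NPQDynamicsSummary",
    "Segment",
    "FitError",
    "AlignmentError",
    "half_time",
    "fit_relaxation",
    "fit_induction",
    "segment_series",
    "npq_dynamics_summary",
    "analyze_npq_dynamics",
]

_LN2 = math.log(2.0)
_MAX_ITER = 500
_XTOL = 1e-10


class FitError(RuntimeError):
    """Raised when an exponential fit cannot be performed or converge."""


class AlignmentError(ValueError):
    """Raised when a parameter table does not match the stated protocol."""


def half_time(b: float) -> float:
    """Half-time ln(2)/b of a first-order process with rate ``b`` (s⁻¹)."""
    if b <= 0:
        raise ValueError(f"rate b must be > 0, got {b}")
    return _LN2 / b


@dataclass(frozen=True)
class KineticsFit:
    """Result of a single-exponential fit to an NPQ segment."""

    direction: str  # {"relaxation", "induction"}
    a: float        # amplitude at segment start, relative to the asymptote
    b: float        # rate, s⁻¹
    baseline: float  # asymptote used by the model form
    rmse: float
    n_points: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise FitError(f"fitted rate must be > 0, got {self.b}")
        if self.n_points < 3:
            raise FitError("a kinetics fit needs at least 3 points")

    @property
    def t(self) -> float:
        """Time constant 1/b, seconds."""
        return 1.0 / self.b

    @property
    def half_time_s(self) -> float:
        return half_time(self.b)


def _prepare(times_s, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(t) < 3:
        raise FitError(f"need >= 3 points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(y) == 0:
        raise FitError("constant series: rate is unidentifiable")
    return t, y


def _init_rate(t: np.ndarray, resid: np.ndarray) -> tuple[float, float]:
    """Initial (a, b) from a log-linear regression of positive residuals."""
    pos = resid > 0
    if pos.sum() < 2:
        raise FitError("cannot initialize: fewer than 2 positive residuals")
    slope, intercept = np.polyfit(t[pos], np.log(resid[pos]), 1)
    b0 = max(-slope, 1e-6)
    return float(np.exp(intercept)), float(b0)


def _low_confidence_flags(t: np.ndarray, b: float) -> tuple[str, ...]:
    dt = float(np.median(np.diff(t)))
    if half_time(b) < dt:
        return ("half_time_below_sampling_interval",)
    return ()


def _fit_decay(t, resid, p0):
    def model(x, a, b):
        return a * np.exp(-b * x)

    try:
        popt, _ = curve_fit(
            model, t, resid, p0=p0, maxfev=_MAX_ITER * len(t), xtol=_XTOL
        )
    except RuntimeError as exc:
        raise FitError(
            f"exponential fit did not converge (initial estimates a={p0[0]:.4g}, "
            f"b={p0[1]:.4g})"
        ) from exc
    a, b = float(popt[0]), float(popt[1])
    if b <= 0:
        raise FitError(f"fit produced non-positive rate b={b:.4g}")
    rmse = float(np.sqrt(np.mean((model(t, a, b) - resid) ** 2)))
    return a, b, rmse


def _resolve_asymptote(y: np.ndarray, asymptote, direction: str) -> float:
    if asymptote == "last":
        return float(y[-1])
    if asymptote == "zero":
        return 0.0
    if isinstance(asymptote, (int, float)) and not isinstance(asymptote, bool):
        return float(asymptote)
    raise ValueError(
        f"{direction} asymptote must be 'last', 'zero' or a number, got {asymptote!r}"
    )


def fit_relaxation(times_s, npq_values, baseline="last") -> KineticsFit:
    """Fit a baseline-offset exponential decay to a relaxation segment.

    ``baseline`` is ``"last"`` (asymptote fixed to the final observed
    value; default), ``"zero"`` (the literal two-parameter decay), or a
    number.  Times are internally re-zeroed to the segment start, so the
    fit is invariant to the time origin.
    """
    t, y = _prepare(times_s, npq_values)
    t = t - t[0]
    if np.any(np.diff(y) > 0):
        warnings.warn(
            "relaxation segment is not monotonically decreasing; fitting anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    c = _resolve_asymptote(y, baseline, "relaxation")
    resid = y - c
    a0, b0 = _init_rate(t, resid)
    a, b, rmse = _fit_decay(t, resid, (a0, b0))
    return KineticsFit(
        direction="relaxation", a=a, b=b, baseline=c, rmse=rmse,
        n_points=len(t), flags=_low_confidence_flags(t, b),
    )


def fit_induction(times_s, npq_values, plateau="last") -> KineticsFit:
    """Fit a saturating exponential rise to an induction segment.

    The model is ``y = plateau - a * exp(-b t)``, i.e. an exponential
    decay of the deficit ``plateau - y``.  ``plateau`` is ``"last"``
    (default), ``"zero"`` is meaningless here and rejected, or a number.
    """
    t, y = _prepare(times_s, npq_values)
    t = t - t[0]
    if plateau == "zero":
        raise ValueError("an induction plateau of zero is not meaningful")
    c = _resolve_asymptote(y, plateau, "induction")
    resid = c - y
    if np.all(resid <= 0) or np.ptp(resid) == 0:
        raise FitError("series already at or above plateau: rate unidentifiable")
    a0, b0 = _init_rate(t, resid)
    a, b, rmse = _fit_decay(t, resid, (a0, b0))
    return KineticsFit(
        direction="induction", a=a, b=b, baseline=c, rmse=rmse,
        n_points=len(t), flags=_low_confidence_flags(t, b),
    )


@dataclass(frozen=True)
class Segment:
    """One lit phase of NPQ observations, times re-zeroed at phase start."""

    phase_index: int
    label: str
    ppfd: float
    prev_ppfd: float
    direction: str  # {"induction", "relaxation"}
    times_s: np.ndarray
    npq: np.ndarray
    prev_last_npq: float  # NPQ at the moment of the step (last value before)


def segment_series(cf_table: pd.DataFrame, protocol: LightProtocol) -> list[Segment]:
    """Split one sample's NPQ series into per-lit-phase segments.

    A phase following a step down in PPFD is a relaxation segment, a step
    up an induction segment (the first lit phase, dark -> light, is an
    induction).  Times are re-zeroed at phase start.
    """
    if "sample_id" in cf_table.columns and cf_table["sample_id"].nunique() > 1:
        raise ValueError("segment_series expects a single sample's table")
    table = cf_table.sort_values("time_s")
    times = table["time_s"].to_numpy(dtype=float)
    npq = table["npq"].to_numpy(dtype=float)
    if len(times) == 0 or times[-1] > protocol.total_duration_s + 1e-9:
        raise AlignmentError("parameter table does not fit inside the protocol")
    segments: list[Segment] = []
    starts = protocol.phase_starts()
    prev_ppfd = 0.0
    for i, phase in enumerate(protocol.phases):
        t0, t1 = starts[i], starts[i] + phase.duration_s
        if phase.kind == "dark_adapt":
            prev_ppfd = phase.ppfd
            continue
        sel = (times > t0 + 1e-9) & (times <= t1 + 1e-9)
        if not sel.any():
            raise AlignmentError(
                f"no pulses fall inside lit phase {i} ({phase.ppfd} PPFD): "
                "protocol/table mismatch"
            )
        before = times <= t0 + 1e-9
        prev_last = float(npq[before][-1]) if before.any() else 0.0
        direction = "induction" if phase.ppfd > prev_ppfd else "relaxation"
        segments.append(
            Segment(
                phase_index=i,
                label=phase.label or f"phase{i}",
                ppfd=phase.ppfd,
                prev_ppfd=prev_ppfd,
                direction=direction,
                times_s=times[sel] - t0,
                npq=npq[sel],
                prev_last_npq=prev_last,
            )
        )
        prev_ppfd = phase.ppfd
    return segments


@dataclass(frozen=True)
class NPQDynamicsSummary:
    """Step-protocol NPQ dynamics metrics for one sample.

    ``min_npq``/``max_npq`` are the extrema over the low-light
    (relaxation) and subsequent high-light (induction) segments;
    ``pct_decrease`` is relative to the NPQ at the moment of the step
    down; ``fold_increase`` is max/min; R50/I50 are the fitted
    half-times.
    """

    sample_id: int | None
    min_npq: float
    max_npq: float
    pct_decrease: float
    fold_increase: float
    r50_s: float
    i50_s: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def npq_dynamics_summary(
    segments: list[Segment],
    fits: dict[int, KineticsFit],
    sample_id: int | None = None,
) -> NPQDynamicsSummary:
    """Summarise a step protocol from its segments and per-segment fits.

    ``fits`` maps phase_index -> KineticsFit.  The relaxation segment is
    the first step-down phase; the induction segment is the following
    step-up phase.
    """
    relax = next((s for s in segments if s.direction == "relaxation"), None)
    if relax is None:
        raise ValueError("no relaxation segment present")
    induct = next(
        (s for s in segments
         if s.direction == "induction" and s.phase_index > relax.phase_index),
        None,
    )
    if induct is None:
        raise ValueError("no induction segment follows the relaxation segment")
    flags: list[str] = []
    min_npq = float(relax.npq.min())
    max_npq = float(induct.npq.max())
    ref = relax.prev_last_npq
    pct_decrease = 100.0 * (ref - min_npq) / ref if ref > 0 else math.nan
    if ref <= 0:
        flags.append("pct_decrease_undefined")
    if min_npq > 0:
        fold_increase = max_npq / min_npq
    else:
        fold_increase = math.nan
        flags.append("fold_increase_undefined")
    r_fit = fits.get(relax.phase_index)
    i_fit = fits.get(induct.phase_index)
    for f in (r_fit, i_fit):
        if f is not None:
            flags.extend(f.flags)
    return NPQDynamicsSummary(
        sample_id=sample_id,
        min_npq=min_npq,
        max_npq=max_npq,
        pct_decrease=pct_decrease,
        fold_increase=fold_increase,
        r50_s=r_fit.half_time_s if r_fit else math.nan,
        i50_s=i_fit.half_time_s if i_fit else math.nan,
        flags=tuple(dict.fromkeys(flags)),
    )


def analyze_npq_dynamics(
    cf_table: pd.DataFrame,
    protocol: LightProtocol,
    baseline="last",
    plateau="last",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample segmentation, fitting and summary over a full CF table.

    Returns ``(kinetics_table, summary_table)``: one kinetics row per
    fitted segment (sample_id, phase label, direction, a, b, t,
    half_time_s, baseline, rmse, n_points, flags) and one summary row per
    sample mirroring :class:`NPQDynamicsSummary`.  Samples whose fits
    fail are reported with a ``fit_failed`` flag instead of aborting the
    whole table.
    """
    kin_rows, sum_rows = [], []
    for sid, sub in cf_table.groupby("sample_id"):
        lit = sub[sub["npq"].notna()]
        segments = segment_series(lit, protocol)
        fits: dict[int, KineticsFit] = {}
        for seg in segments:
            try:
                if seg.direction == "relaxation":
                    fit = fit_relaxation(seg.times_s, seg.npq, baseline=baseline)
                else:
                    fit = fit_induction(seg.times_s, seg.npq, plateau=plateau)
            except FitError as exc:
                kin_rows.append({
                    "sample_id": sid, "phase": seg.label,
                    "direction": seg.direction, "a": math.nan, "b": math.nan,
                    "t": math.nan, "half_time_s": math.nan,
                    "baseline": math.nan, "rmse": math.nan,
                    "n_points": len(seg.times_s),
                    "flags": f"fit_failed:{exc}",
                })
                continue
            fits[seg.phase_index] = fit
            kin_rows.append({
                "sample_id": sid, "phase": seg.label, "direction": fit.direction,
                "a": fit.a, "b": fit.b, "t": fit.t,
                "half_time_s": fit.half_time_s, "baseline": fit.baseline,
                "rmse": fit.rmse, "n_points": fit.n_points,
                "flags": ";".join(fit.flags),
            })
        try:
            summary = npq_dynamics_summary(segments, fits, sample_id=int(sid))
            sum_rows.append({
                "sample_id": int(sid),
                "min_npq": summary.min_npq,
                "max_npq": summary.max_npq,
                "pct_decrease": summary.pct_decrease,
                "fold_increase": summary.fold_increase,
                "r50_s": summary.r50_s,
                "i50_s": summary.i50_s,
                "flags": ";".join(summary.flags),
            })
        except ValueError:
            pass  # protocol without a down/up step pair has no summary
    return pd.DataFrame(kin_rows), pd.DataFrame(sum_rows)
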