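"""Descriptor state functions and dissociation-transition detection.

The bound state is characterised by bell-shaped distributions of q (fraction
of native contacts), d1 (VH-VL COM distance) and d2 (CH1-CL COM distance).
A half-sigmoid is fitted to one flank of each bound histogram — increasing
on the left flank of q, decreasing on the right flanks of d1 and d2 — and
the fitted logistic

    L(x) = 1 / (1 + exp(-s (x - x0)))

is projected onto the umbrella-sampling descriptor values.  The product of
the three factors is the bound-state function S: 1 in the bound state,
smoothly approaching 0 as the structure leaves it; the first sustained drop
below a small threshold marks the bound -> encounter-complex transition.

The encounter -> unbound transition is defined on the q and SASA timeseries:
each is fitted with a four-parameter logistic in time, min-max normalized to
[0, 1] with 1 at the bound end (the increasing SASA curve is inverted), and
multiplied; the transition is the frame where the product approaches 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "LogisticParams", "BoundStateModel", "UnboundStateModel", "TransitionReport",
    "evaluate_logistic", "fit_half_sigmoid", "bound_state_function",
    "detect_bound_encounter", "fit_unbound_model", "detect_encounter_unbound",
]


@dataclass(frozen=True)
class LogisticParams:
    """Slope ``s`` (sign encodes direction) and turning point ``x0``."""

    s: float
    x0: float

    def __post_init__(self):
        if self.s == 0:
            raise ValueError("slope s must be nonzero")
        if not np.isfinite(self.x0):
            raise ValueError("turning point x0 must be finite")

    def __call__(self, x):
        return evaluate_logistic(self, x)


def evaluate_logistic(p: LogisticParams, x):
    """1 / (1 + exp(-s (x - x0))), numerically stable for large arguments."""
    return expit(p.s * (np.asarray(x, dtype=float) - p.x0))


def fit_half_sigmoid(samples, side: str, n_bins: int = 60) -> LogisticParams:
    """Fit a logistic to one flank of a bell-shaped descriptor histogram.

    The histogram (``n_bins`` over the sampled range, peak-normalized to 1)
    is restricted to the bins on the stated side of the mode bin (mode
    inclusive): ``left_increasing`` fits an increasing logistic (s > 0) on
    the bins at and below the mode, ``right_decreasing`` a decreasing one
    (s < 0) at and above it.  Modal ties break toward the bound side
    (high q for the left fit, low distance for the right fit).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1000:
        raise ValueError("need at least 1000 samples for a stable flank fit")
    if side not in ("left_increasing", "right_decreasing"):
        raise ValueError(f"unknown side {side!r}")
    counts, edges = np.histogram(samples, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = np.flatnonzero(counts == counts.max())
    mode = peaks[-1] if side == "left_increasing" else peaks[0]
    if mode in (0, n_bins - 1):
        raise ValueError("histogram mode at the edge; no flank to fit "
                         "(distribution is not unimodal over the range)")
    y = counts / counts.max()
    if side == "left_increasing":
        xs, ys = centers[: mode + 1], y[: mode + 1]
    else:
        xs, ys = centers[mode:], y[mode:]
    # fit in standardized flank coordinates so the result is exactly
    # equivariant under rescaling of the descriptor units
    x_mid, x_span = xs[0], max(xs[-1] - xs[0], 1e-300)
    z = (xs - x_mid) / x_span
    sgn = 1.0 if side == "left_increasing" else -1.0
    z0_guess = float(z[np.argmin(np.abs(ys - 0.5))])
    try:
        popt, _ = curve_fit(lambda zz, sz, z0: expit(sgn * np.abs(sz) * (zz - z0)),
                            z, ys, p0=[4.0, z0_guess], maxfev=20_000)
    except RuntimeError as err:
        raise RuntimeError(f"half-sigmoid fit failed on side {side}: {err}") from err
    s_z, z0 = abs(float(popt[0])), float(popt[1])
    return LogisticParams(s=sgn * s_z / x_span, x0=x_mid + z0 * x_span)


# --------------------------------------------------------------------------- #
# Bound -> encounter complex
# --------------------------------------------------------------------------- #

@dataclass
class BoundStateModel:
    """Fitted logistics for q / d1 / d2 plus detection threshold and dwell."""

    logistic_q: LogisticParams
    logistic_d1: LogisticParams
    logistic_d2: LogisticParams
    theta_b: float = 0.01
    dwell: int = 10

    def __post_init__(self):
        if self.logistic_q.s <= 0:
            raise ValueError("q logistic must be increasing (s > 0)")
        if self.logistic_d1.s >= 0 or self.logistic_d2.s >= 0:
            raise ValueError("d1/d2 logistics must be decreasing (s < 0)")
        if not 0 < self.theta_b < 1:
            raise ValueError("theta_b must lie in (0, 1)")
        if self.dwell < 1:
            raise ValueError("dwell must be >= 1")

    @classmethod
    def fit(cls, bound_trace: pd.DataFrame, n_bins: int = 60,
            theta_b: float = 0.01, dwell: int = 10) -> "BoundStateModel":
        """Fit the three half-sigmoids on a bound-ensemble descriptor trace."""
        return cls(
            logistic_q=fit_half_sigmoid(bound_trace["q"], "left_increasing", n_bins),
            logistic_d1=fit_half_sigmoid(bound_trace["d1_nm"], "right_decreasing", n_bins),
            logistic_d2=fit_half_sigmoid(bound_trace["d2_nm"], "right_decreasing", n_bins),
            theta_b=theta_b, dwell=dwell,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def bound_state_function(model: BoundStateModel, trace: pd.DataFrame) -> np.ndarray:
    """Per-frame product state S = L_q(q) * L_d1(d1) * L_d2(d2) in [0, 1]."""
    if len(trace) == 0:
        raise ValueError("empty descriptor trace")
    return (evaluate_logistic(model.logistic_q, trace["q"].to_numpy())
            * evaluate_logistic(model.logistic_d1, trace["d1_nm"].to_numpy())
            * evaluate_logistic(model.logistic_d2, trace["d2_nm"].to_numpy()))


def _first_sustained_below(values: np.ndarray, threshold: float, dwell: int):
    below = values < threshold
    if dwell == 1:
        idx = np.flatnonzero(below)
        return int(idx[0]) if idx.size else None
    run = np.convolve(below.astype(int), np.ones(dwell, dtype=int), mode="valid")
    idx = np.flatnonzero(run == dwell)
    return int(idx[0]) if idx.size else None


def detect_bound_encounter(S: np.ndarray, cv: np.ndarray,
                           theta_b: float = 0.01, dwell: int = 10):
    """First frame where S stays below ``theta_b`` for ``dwell`` frames.

    Frames are expected in increasing-CV order.  Returns ``(frame, cv)`` or
    ``None`` if the bound state never empties.
    """
    S = np.asarray(S, dtype=float)
    if np.any((S < 0) | (S > 1)):
        raise ValueError("state values must lie in [0, 1]")
    frame = _first_sustained_below(S, theta_b, dwell)
    if frame is None:
        return None
    return frame, float(np.asarray(cv)[frame])


# --------------------------------------------------------------------------- #
# Encounter complex -> unbound
# --------------------------------------------------------------------------- #

def _fit_time_logistic(t, y, increasing: bool):
    lo0, hi0 = float(np.min(y)), float(np.max(y))
    if hi0 - lo0 < 1e-9 * max(abs(hi0), 1.0):
        raise ValueError("descriptor timeseries is constant; no transition to fit")
    span = t[-1] - t[0]
    s0 = (8.0 / span) * (1.0 if increasing else -1.0)
    # half-way crossing as the midpoint guess
    t0 = float(t[np.argmin(np.abs(y - 0.5 * (lo0 + hi0)))])
    bounds = ([lo0 - (hi0 - lo0), 0.0, 1e-9 / span, t[0] - span],
              [hi0 + (hi0 - lo0), 2.0 * (hi0 - lo0), np.inf, t[-1] + span]) \
        if increasing else \
        ([lo0 - (hi0 - lo0), 0.0, -np.inf, t[0] - span],
         [hi0 + (hi0 - lo0), 2.0 * (hi0 - lo0), -1e-9 / span, t[-1] + span])
    popt, _ = curve_fit(lambda x, b, a, s, x0: b + a * expit(s * (x - x0)),
                        t, y, p0=[lo0, hi0 - lo0, s0, t0], bounds=bounds,
                        maxfev=20_000)
    return popt  # baseline, amplitude, slope, midpoint


@dataclass
class UnboundStateModel:
    """Time-domain logistic fits of q and SASA with the normalized product."""

    q_fit: tuple                 # (baseline, amplitude, slope, midpoint)
    sasa_fit: tuple
    frames: np.ndarray
    cv: np.ndarray
    product: np.ndarray          # normalized product curve, 1 at the bound end
    theta_u: float = 0.01

    def __post_init__(self):
        if not 0 < self.theta_u < 1:
            raise ValueError("theta_u must lie in (0, 1)")


def fit_unbound_model(trace: pd.DataFrame, theta_u: float = 0.01) -> UnboundStateModel:
    """Fit the q / SASA time sigmoids and store their normalized product.

    Each fitted curve is min-max normalized over the trace span; the SASA
    curve (increasing on dissociation) is inverted so both factors equal 1
    at the bound end.
    """
    t = trace["frame"].to_numpy(dtype=float)
    q_fit = _fit_time_logistic(t, trace["q"].to_numpy(dtype=float), increasing=False)
    s_fit = _fit_time_logistic(t, trace["sasa_nm2"].to_numpy(dtype=float),
                               increasing=True)

    def norm_curve(p):
        b, a, s, x0 = p
        y = b + a * expit(s * (t - x0))
        lo, hi = y.min(), y.max()
        return (y - lo) / (hi - lo)

    nq = norm_curve(q_fit)          # decreasing: already 1 at the bound end
    ns = 1.0 - norm_curve(s_fit)    # invert the increasing SASA curve
    return UnboundStateModel(q_fit=tuple(q_fit), sasa_fit=tuple(s_fit),
                             frames=trace["frame"].to_numpy(),
                             cv=trace["cv_nm"].to_numpy(),
                             product=nq * ns, theta_u=theta_u)


def detect_encounter_unbound(model: UnboundStateModel,
                             theta_u: float | None = None):
    """First frame where the normalized product drops below ``theta_u``.

    Returns ``(frame, cv)`` or ``None`` if the product never approaches 0.
    """
    theta = model.theta_u if theta_u is None else theta_u
    idx = np.flatnonzero(model.product < theta)
    if idx.size == 0:
        return None
    i = int(idx[0])
    return int(model.frames[i]), float(model.cv[i])


# --------------------------------------------------------------------------- #
# Transition report
# --------------------------------------------------------------------------- #

@dataclass
class TransitionReport:
    """Detected transitions of one system plus per-region dissociation flags."""

    bound_encounter: tuple | None       # (frame, cv_nm) or None
    encounter_unbound: tuple | None
    fv_dissociated: bool = True
    ch1cl_dissociated: bool = True
    theta_b: float = 0.01
    theta_u: float = 0.01
    dwell: int = 10

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionReport":
        d = json.loads(Path(path).read_text())
        for k in ("bound_encounter", "encounter_unbound"):
            if d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def detect_transitions(trace: pd.DataFrame, bound_model: BoundStateModel,
                       theta_u: float = 0.01,
                       d_dissociation_rise: float = 0.5) -> TransitionReport:
    """Run both detections on a CV-ordered descriptor trace.

    A region counts as dissociated if its COM distance (d1 for Fv, d2 for
    CH1-CL) rises at least ``d_dissociation_rise`` nm above its starting
    value anywhere in the trace.
    """
    S = bound_state_function(bound_model, trace)
    be = detect_bound_encounter(S, trace["cv_nm"].to_numpy(),
                                bound_model.theta_b, bound_model.dwell)
    try:
        unbound = fit_unbound_model(trace, theta_u=theta_u)
        eu = detect_encounter_unbound(unbound)
    except ValueError:
        eu = None
    d1 = trace["d1_nm"].to_numpy()
    d2 = trace["d2_nm"].to_numpy()
    return TransitionReport(
        bound_encounter=be, encounter_unbound=eu,
        fv_dissociated=bool(d1.max() - d1[0] >= d_dissociation_rise),
        ch1cl_dissociated=bool(d2.max() - d2[0] >= d_dissociation_rise),
        theta_b=bound_model.theta_b, theta_u=theta_u, dwell=bound_model.dwell)
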