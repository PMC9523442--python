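"""Transepithelial Na⁺-transport quantification from Ussing-chamber traces.

A fetal distal lung epithelial (FDLE) monolayer is mounted between apical
and basolateral half-chambers; a fluid column on one side applies a
hydrostatic pressure.  In current clamp the transepithelial potential V_te
(mV) and resistance R_te (Ω·cm²) are recorded every 20 s and the equivalent
short-circuit current follows from Ohm's law, I_sc = V_te / R_te.  In
voltage clamp I_sc (µA/cm²) is recorded directly every 5 s.

The analysis steps are:

* quality control — only monolayers whose baseline R_te strictly exceeds
  300 Ω·cm² enter the analysis;
* plateau detection — a sliding window is stable when its least-squares
  slope, normalized by the window mean, falls below a relative tolerance;
* inhibitor deltas — the drop between the plateau just before and the
  plateau after an inhibitor addition: apical amiloride isolates the
  ENaC-mediated component (ΔV_amil or ΔI_sc), basolateral ouabain the
  Na,K-ATPase component (ΔV_ouab);
* amil_max — after basolateral permeabilization with amphotericin B under a
  145:5 apical:basolateral Na⁺ gradient, the maximal I_sc minus the plateau
  after basolateral amiloride gives the maximal amiloride-sensitive apical
  membrane permeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_LABELS",
    "UssingTrace",
    "TransportSummary",
    "PlateauResult",
    "InhibitorDelta",
    "EventNotFoundError",
    "PlateauNotFoundError",
    "short_circuit_current",
    "qc_filter",
    "baseline_rte",
    "detect_plateau",
    "inhibitor_delta",
    "amil_max",
    "process_trace",
    "group_table",
    "QC_THRESHOLD_OHM_CM2",
]

EVENT_LABELS = (
    "amiloride_apical",
    "ouabain_basolateral",
    "amphotericin_basolateral",
    "amiloride_basolateral",
)

#: Monolayer inclusion gate on baseline transepithelial resistance.
QC_THRESHOLD_OHM_CM2 = 300.0

#: Pressure limits (cmH2O): basolateral columns above 12.5 detach the cells.
MAX_PRESSURE = {"none": 0.0, "basolateral": 12.5, "apical": 30.0}

DEFAULT_PLATEAU_WINDOW = 6  # samples: 2 min at the 20 s current-clamp cadence
DEFAULT_SLOPE_TOL = 0.01  # relative slope per sample


class EventNotFoundError(RuntimeError):
    """A required inhibitor event is absent from the trace."""


class PlateauNotFoundError(RuntimeError):
    """No stable plateau exists in the examined segment."""


@dataclass(frozen=True)
class UssingTrace:
    """One Ussing-chamber recording with its inhibitor events.

    Current clamp carries ``v_te_mV``; voltage clamp carries
    ``i_sc_uA_cm2``.  ``events`` maps inhibitor additions to times (s).
    """

    time_s: np.ndarray
    r_te_ohm_cm2: np.ndarray
    v_te_mV: np.ndarray | None = None
    i_sc_uA_cm2: np.ndarray | None = None
    events: tuple = ()
    pressure_cmH2O: float = 0.0
    pressure_side: str = "none"
    clamp_mode: str = "current_clamp"
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        r = np.asarray(self.r_te_ohm_cm2, dtype=float)
        if t.size == 0 or t.size != r.size:
            raise ValueError("time and R_te must be equal-length and nonempty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("R_te must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "r_te_ohm_cm2", r)
        if self.clamp_mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown clamp mode {self.clamp_mode!r}")
        primary = self.v_te_mV if self.clamp_mode == "current_clamp" else self.i_sc_uA_cm2
        if primary is None:
            raise ValueError(
                "current clamp requires v_te_mV; voltage clamp requires i_sc_uA_cm2"
            )
        y = np.asarray(primary, dtype=float)
        if y.size != t.size:
            raise ValueError("signal length must match time")
        if self.clamp_mode == "current_clamp":
            object.__setattr__(self, "v_te_mV", y)
        else:
            object.__setattr__(self, "i_sc_uA_cm2", y)
        for et, lbl in self.events:
            if lbl not in EVENT_LABELS:
                raise ValueError(f"unknown event label {lbl!r}")
            if not t[0] <= et <= t[-1]:
                raise ValueError(f"event {lbl!r} at {et} s lies outside the trace")
        if self.pressure_side not in MAX_PRESSURE:
            raise ValueError(f"unknown pressure side {self.pressure_side!r}")
        if self.pressure_cmH2O < 0:
            raise ValueError("pressure must be nonnegative")
        limit = MAX_PRESSURE[self.pressure_side]
        if self.pressure_cmH2O > limit:
            raise ValueError(
                f"{self.pressure_side} pressure {self.pressure_cmH2O} cmH2O exceeds the "
                f"{limit} cmH2O protocol limit"
            )

    def __len__(self) -> int:
        return self.time_s.size

    def signal(self) -> np.ndarray:
        """The analyzed channel: V_te (mV) in current clamp, I_sc (µA/cm²) in voltage clamp."""
        return self.v_te_mV if self.clamp_mode == "current_clamp" else self.i_sc_uA_cm2

    def event_time(self, label: str) -> float:
        for et, lbl in self.events:
            if lbl == label:
                return float(et)
        raise EventNotFoundError(f"event {label!r} not present in trace {self.label!r}")

    def has_event(self, label: str) -> bool:
        return any(lbl == label for _, lbl in self.events)


class PlateauResult(NamedTuple):
    start_index: int
    mean: float


class InhibitorDelta(NamedTuple):
    pre_plateau: float
    post_plateau: float
    delta: float


def short_circuit_current(v_te_mV, r_te_ohm_cm2):
    """Equivalent short-circuit current from Ohm's law, I_sc = V_te / R_te.

    mV over Ω·cm² yields µA/cm² after unit conversion (×1000).
    """
    v = np.asarray(v_te_mV, dtype=float)
    r = np.asarray(r_te_ohm_cm2, dtype=float)
    if np.any(r <= 0):
        raise ValueError("R_te must be positive")
    out = v / r * 1000.0
    return out if out.ndim else float(out)


def baseline_rte(trace: UssingTrace, window_n: int = DEFAULT_PLATEAU_WINDOW) -> float:
    """Mean R_te before the first inhibitor event (whole trace if none)."""
    if trace.events:
        t0 = min(et for et, _ in trace.events)
        mask = trace.time_s < t0
        r = trace.r_te_ohm_cm2[mask] if mask.any() else trace.r_te_ohm_cm2[:window_n]
    else:
        r = trace.r_te_ohm_cm2
    return float(np.mean(r[-window_n:] if r.size > window_n else r))


def qc_filter(
    traces: Iterable[UssingTrace], threshold_ohm_cm2: float = QC_THRESHOLD_OHM_CM2
) -> list[UssingTrace]:
    """Keep only monolayers whose baseline R_te strictly exceeds the threshold."""
    return [t for t in traces if baseline_rte(t) > threshold_ohm_cm2]


def _window_slopes(y: np.ndarray, window_n: int) -> np.ndarray:
    """Least-squares slope (per sample) of every length-``window_n`` window."""
    x = np.arange(window_n, dtype=float)
    x = x - x.mean()
    windows = np.lib.stride_tricks.sliding_window_view(y, window_n)
    return windows @ x / np.sum(x * x)


def detect_plateau(
    values,
    window_n: int = DEFAULT_PLATEAU_WINDOW,
    rel_slope_tol: float = DEFAULT_SLOPE_TOL,
    last: bool = False,
) -> PlateauResult | None:
    """Earliest (or latest, ``last=True``) stable sliding window in a series.

    A window is stable when |slope| / max(|mean|, ε) < ``rel_slope_tol``,
    slope in signal units per sample.  Returns ``None`` when no window
    qualifies (flagged absence rather than an exception, since a missing
    plateau is an expected data condition).
    """
    y = np.asarray(values, dtype=float)
    if y.size < window_n:
        raise ValueError(f"need at least {window_n} samples, got {y.size}")
    slopes = _window_slopes(y, window_n)
    means = np.convolve(y, np.ones(window_n) / window_n, mode="valid")
    denom = np.maximum(np.abs(means), 1e-9)
    stable = np.flatnonzero(np.abs(slopes) / denom < rel_slope_tol)
    if stable.size == 0:
        return None
    i = int(stable[-1] if last else stable[0])
    return PlateauResult(start_index=i, mean=float(means[i]))


def inhibitor_delta(
    trace: UssingTrace,
    event_label: str,
    window_n: int = DEFAULT_PLATEAU_WINDOW,
    rel_slope_tol: float = DEFAULT_SLOPE_TOL,
) -> InhibitorDelta:
    """Inhibitor-sensitive signal component around one event.

    delta = (plateau just before the event) − (settled plateau after it);
    positive when the inhibitor reduces transport.  On V_te this yields
    ΔV_amil / ΔV_ouab, on clamped current ΔI_sc.
    """
    t_event = trace.event_time(event_label)
    y = trace.signal()
    pre = y[trace.time_s < t_event]
    post = y[trace.time_s >= t_event]
    if pre.size < window_n or post.size < window_n:
        raise PlateauNotFoundError(
            f"fewer than {window_n} samples on one side of {event_label!r}"
        )
    # pre: the plateau closest to the addition; post: the settled level
    p_pre = detect_plateau(pre, window_n, rel_slope_tol, last=True)
    p_post = detect_plateau(post, window_n, rel_slope_tol, last=True)
    if p_pre is None or p_post is None:
        raise PlateauNotFoundError(f"no stable plateau around {event_label!r}")
    return InhibitorDelta(
        pre_plateau=p_pre.mean,
        post_plateau=p_post.mean,
        delta=p_pre.mean - p_post.mean,
    )


def amil_max(
    trace: UssingTrace,
    window_n: int = DEFAULT_PLATEAU_WINDOW,
    rel_slope_tol: float = DEFAULT_SLOPE_TOL,
) -> float:
    """Maximal amiloride-sensitive apical permeability (µA/cm²).

    (Peak I_sc after basolateral amphotericin permeabilization) minus (the
    plateau after basolateral amiloride).  Requires a voltage-clamp trace
    carrying both events.
    """
    if trace.clamp_mode != "voltage_clamp":
        raise ValueError("amil_max requires a voltage-clamp trace")
    t_perm = trace.event_time("amphotericin_basolateral")
    t_amil = trace.event_time("amiloride_basolateral")
    y = trace.signal()
    rise = y[(trace.time_s >= t_perm) & (trace.time_s < t_amil)]
    post = y[trace.time_s >= t_amil]
    if rise.size == 0 or post.size == 0:
        raise EventNotFoundError("no samples between/after the permeabilization events")
    if post.size < window_n:
        raise PlateauNotFoundError(f"fewer than {window_n} samples after basolateral amiloride")
    p_post = detect_plateau(post, window_n, rel_slope_tol, last=True)
    if p_post is None:
        raise PlateauNotFoundError("no stable post-amiloride plateau")
    return float(np.max(rise) - p_post.mean)


@dataclass(frozen=True)
class TransportSummary:
    """Per-trace transport decomposition (units: mV, Ω·cm², µA/cm², cmH2O)."""

    label: str
    pressure_cmH2O: float
    pressure_side: str
    qc_pass: bool
    v_base_mV: float = float("nan")
    v_amil_mV: float = float("nan")
    delta_amil_mV: float = float("nan")
    delta_ouab_mV: float = float("nan")
    amil_max_uA_cm2: float = float("nan")
    r_te_at_plateau: float = float("nan")
    i_sc_base_uA_cm2: float = float("nan")
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "label", "pressure_cmH2O", "pressure_side", "qc_pass", "v_base_mV",
            "v_amil_mV", "delta_amil_mV", "delta_ouab_mV", "amil_max_uA_cm2",
            "r_te_at_plateau", "i_sc_base_uA_cm2",
        )}
        d["flags"] = ";".join(self.flags)
        return d


def process_trace(
    trace: UssingTrace,
    window_n: int = DEFAULT_PLATEAU_WINDOW,
    rel_slope_tol: float = DEFAULT_SLOPE_TOL,
    qc_threshold: float = QC_THRESHOLD_OHM_CM2,
) -> TransportSummary:
    """Full per-trace analysis: QC, plateaus, inhibitor deltas, amil_max.

    The additive decomposition V_base = V_amil + ΔV_amil holds by
    construction (both terms come from the same pre/post plateau means).
    Missing events or plateaus are recorded in ``flags`` rather than raised,
    so cohort processing is robust to incomplete traces.
    """
    flags: list[str] = []
    qc = baseline_rte(trace, window_n) > qc_threshold
    fields: dict = {}
    y = trace.signal()

    def _try(label: str):
        try:
            return inhibitor_delta(trace, label, window_n, rel_slope_tol)
        except (EventNotFoundError, PlateauNotFoundError) as err:
            flags.append(f"{label}: {err}")
            return None

    if trace.clamp_mode == "current_clamp":
        d_am = _try("amiloride_apical") if trace.has_event("amiloride_apical") else None
        d_ou = _try("ouabain_basolateral") if trace.has_event("ouabain_basolateral") else None
        base = d_am or d_ou
        if base is not None:
            fields["v_base_mV"] = base.pre_plateau
        if d_am is not None:
            fields["v_amil_mV"] = d_am.post_plateau
            fields["delta_amil_mV"] = d_am.delta
        if d_ou is not None:
            fields["delta_ouab_mV"] = d_ou.delta
        if not trace.has_event("amiloride_apical") and not trace.has_event("ouabain_basolateral"):
            flags.append("no inhibitor event in current-clamp trace")
        # R_te and I_sc at the pre-event plateau
        if trace.events:
            t0 = min(et for et, _ in trace.events)
            pre_mask = trace.time_s < t0
        else:
            pre_mask = np.ones(len(trace), dtype=bool)
        if pre_mask.sum() >= window_n:
            p = detect_plateau(y[pre_mask], window_n, rel_slope_tol, last=True)
            if p is not None:
                sl = slice(p.start_index, p.start_index + window_n)
                fields["r_te_at_plateau"] = float(np.mean(trace.r_te_ohm_cm2[pre_mask][sl]))
                if "v_base_mV" in fields:
                    fields["i_sc_base_uA_cm2"] = short_circuit_current(
                        fields["v_base_mV"], fields["r_te_at_plateau"]
                    )
    else:
        try:
            fields["amil_max_uA_cm2"] = amil_max(trace, window_n, rel_slope_tol)
            t_amil = trace.event_time("amiloride_basolateral")
            peak_mask = trace.time_s < t_amil
            i_peak = int(np.argmax(y[peak_mask]))
            fields["r_te_at_plateau"] = float(trace.r_te_ohm_cm2[peak_mask][i_peak])
        except (EventNotFoundError, PlateauNotFoundError, ValueError) as err:
            flags.append(f"amil_max: {err}")

    return TransportSummary(
        label=trace.label,
        pressure_cmH2O=trace.pressure_cmH2O,
        pressure_side=trace.pressure_side,
        qc_pass=bool(qc),
        flags=tuple(flags),
        **fields,
    )


def group_table(summaries: Sequence[TransportSummary]) -> pd.DataFrame:
    """Per-pressure-group mean ± SEM of every transport quantity (QC-passing traces)."""
    rows = [s.to_dict() for s in summaries if s.qc_pass]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    value_cols = [
        "v_base_mV", "v_amil_mV", "delta_amil_mV", "delta_ouab_mV",
        "amil_max_uA_cm2", "r_te_at_plateau", "i_sc_base_uA_cm2",
    ]
    grouped = df.groupby(["pressure_side", "pressure_cmH2O"])[value_cols]
    out = grouped.agg(["mean", "sem", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
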