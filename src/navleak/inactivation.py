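"""Fast-inactivation analyses: peak/steady currents, availability (h-infinity),
G-V, Q-V, gating-charge immobilization and tail-kinetics-versus-duration.

All operations consume :class:`~navleak.simulate.SweepSet` families carrying
their protocol metadata, and return tidy summaries plus fit objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curvefit import (
    AssociationFit,
    BoltzmannFit,
    ExpFit,
    fit_association,
    fit_boltzmann,
    fit_exponentials,
    fit_exponentials_aic,
    weighted_tau,
)
from .simulate import SweepSet

__all__ = ["CurrentSummary", "ImmobilizationCurve", "peak_and_steady",
           "h_infinity", "gv_curve", "qv_curve", "immobilization",
           "tail_tau_vs_duration", "epoch_bounds"]

DEFAULT_BLANKING = 0.3  # ms, ~4 clamp settling time constants
DEFAULT_STEADY_FRACTION = 0.1


def epoch_bounds(sweepset: SweepSet, sweep_value: float,
                 epoch_index: int) -> tuple[float, float]:
    """Start/end time (ms, on the sweep time base) of one protocol epoch,
    accounting for the pre-holding segment and a duration sweep axis."""
    proto = sweepset.protocol()
    pre = float(sweepset.metadata.get("pre_holding_ms", 0.0))
    epochs = proto.epochs_for(sweep_value)
    t0 = pre + sum(e.duration for e in epochs[:epoch_index])
    return t0, t0 + epochs[epoch_index].duration


# ---------------------------------------------------------------------------
# peak / steady-state currents
# ---------------------------------------------------------------------------

@dataclass
class CurrentSummary:
    table: pd.DataFrame  # sweep, i_peak, i_ss, ratio
    blanking: float
    steady_fraction: float

    def ratio_at(self, sweep_value: float) -> float:
        row = self.table[self.table.sweep == sweep_value]
        return float(row.ratio.iloc[0])


def peak_and_steady(t: np.ndarray, y: np.ndarray, pulse: tuple[float, float],
                    blanking: float = DEFAULT_BLANKING,
                    steady_fraction: float = DEFAULT_STEADY_FRACTION,
                    ) -> tuple[float, float, float]:
    """Signed peak, steady-state mean and their ratio for one pulse.

    ``i_peak`` is the signed extremum after the blanking window; ``i_ss`` the
    mean over the final ``steady_fraction`` of the pulse.
    """
    t0, t1 = pulse
    if t1 - t0 <= blanking + steady_fraction * (t1 - t0):
        raise ValueError("pulse shorter than blanking plus steady windows")
    # strict upper bound: the sample at exactly t1 belongs to the next epoch
    sel = (t >= t0 + blanking) & (t < t1 - 1e-9)
    if not np.any(sel):
        raise ValueError("empty analysis window")
    yw = y[sel]
    i_peak = yw[int(np.argmax(np.abs(yw)))]
    ss_sel = (t >= t1 - steady_fraction * (t1 - t0)) & (t < t1 - 1e-9)
    i_ss = float(np.mean(y[ss_sel]))
    ratio = i_ss / i_peak if i_peak != 0 else float("nan")
    return float(i_peak), i_ss, float(ratio)


def current_summary(sweepset: SweepSet, pulse_epoch: int = 0,
                    blanking: float = DEFAULT_BLANKING,
                    steady_fraction: float = DEFAULT_STEADY_FRACTION,
                    ) -> CurrentSummary:
    rows = []
    for sv in sweepset.sweep_values:
        pulse = epoch_bounds(sweepset, sv, pulse_epoch)
        ip, iss, ratio = peak_and_steady(sweepset.time, sweepset.sweeps[sv],
                                         pulse, blanking, steady_fraction)
        rows.append({"sweep": sv, "i_peak": ip, "i_ss": iss, "ratio": ratio})
    return CurrentSummary(pd.DataFrame(rows), blanking, steady_fraction)


# ---------------------------------------------------------------------------
# availability (h-infinity)
# ---------------------------------------------------------------------------

def h_infinity(sweepset: SweepSet, conditioning_epoch: int = 0,
               test_epoch: int | None = None,
               blanking: float = DEFAULT_BLANKING,
               ) -> tuple[pd.DataFrame, BoltzmannFit]:
    """Availability curve from a conditioning-then-test protocol.

    Test-pulse peak currents are normalized to the most hyperpolarized
    conditioning voltage and fitted with the two-state availability curve.
    """
    proto = sweepset.protocol()
    if proto.sweep_axis is None or proto.sweep_axis.attr != "voltage":
        raise ValueError("availability needs a conditioning-voltage sweep axis")
    if test_epoch is None:
        test_epoch = conditioning_epoch + 1
    if test_epoch >= len(proto.epochs):
        raise ValueError("protocol has no test epoch after the conditioning epoch")

    rows = []
    for sv in sweepset.sweep_values:
        t0, t1 = epoch_bounds(sweepset, sv, test_epoch)
        sel = (sweepset.time >= t0 + blanking) & (sweepset.time < t1 - 1e-9)
        yw = sweepset.sweeps[sv][sel]
        peak = yw[int(np.argmax(np.abs(yw)))]
        rows.append({"v_cond": sv, "i_peak": float(peak)})
    df = pd.DataFrame(rows).sort_values("v_cond", ignore_index=True)
    ref = df.i_peak.iloc[0]  # most hyperpolarized conditioning point
    if ref == 0:
        raise ValueError("reference test-pulse current is zero")
    df["available"] = df.i_peak / ref
    temperature = sweepset.conditions().temperature
    fit = fit_boltzmann(df.v_cond.to_numpy(), df.available.to_numpy(),
                        mode="h_inf", temperature=temperature)
    return df, fit


# ---------------------------------------------------------------------------
# conductance-voltage and charge-voltage curves
# ---------------------------------------------------------------------------

def gv_curve(sweepset: SweepSet, v_rev: float, mode: str = "peak",
             pulse_epoch: int = 0, blanking: float = DEFAULT_BLANKING,
             steady_fraction: float = DEFAULT_STEADY_FRACTION,
             ) -> tuple[pd.DataFrame, BoltzmannFit]:
    """Normalized conductance-voltage relation, G = I/(V - V_rev).

    ``mode="peak"`` uses peak currents, ``mode="steady"`` the steady-state
    level (the readout for the leaky inactivated state).  Sweeps within 2 mV
    of the reversal potential are excluded.
    """
    if mode not in ("peak", "steady"):
        raise ValueError("mode must be 'peak' or 'steady'")
    rows = []
    for sv in sweepset.sweep_values:
        if abs(sv - v_rev) < 2.0:
            continue
        pulse = epoch_bounds(sweepset, sv, pulse_epoch)
        ip, iss, _ = peak_and_steady(sweepset.time, sweepset.sweeps[sv], pulse,
                                     blanking, steady_fraction)
        i = ip if mode == "peak" else iss
        rows.append({"v": sv, "i": i, "g": i / (sv - v_rev)})
    if len(rows) < 5:
        raise ValueError("fewer than 5 usable sweeps away from the reversal")
    df = pd.DataFrame(rows).sort_values("v", ignore_index=True)
    df["g_norm"] = df.g / df.g.abs().max()
    temperature = sweepset.conditions().temperature
    fit = fit_boltzmann(df.v.to_numpy(), df.g_norm.to_numpy(), mode="gv",
                        temperature=temperature)
    return df, fit


def qv_curve(sweepset: SweepSet, pulse_epoch: int = 0,
             steady_fraction: float = DEFAULT_STEADY_FRACTION,
             ) -> tuple[pd.DataFrame, BoltzmannFit]:
    """Normalized charge-voltage relation from on-gating integrals.

    The baseline (mean of the final ``steady_fraction`` of the pulse, assumed
    settled) is removed before integration; unsettled sweeps are flagged.
    """
    if sweepset.kind != "gating":
        raise ValueError("Q-V analysis requires a gating-current sweep set")
    rows = []
    flagged = False
    for sv in sweepset.sweep_values:
        t0, t1 = epoch_bounds(sweepset, sv, pulse_epoch)
        sel = (sweepset.time >= t0) & (sweepset.time < t1 - 1e-9)
        tt = sweepset.time[sel]
        yy = sweepset.sweeps[sv][sel]
        base_sel = tt >= t1 - steady_fraction * (t1 - t0)
        base = yy[base_sel].mean()
        if np.abs(base) > 0.05 * np.max(np.abs(yy)):
            flagged = True
        q = np.trapezoid(yy - base, tt)
        rows.append({"v": sv, "q": float(q)})
    df = pd.DataFrame(rows).sort_values("v", ignore_index=True)
    qmax = df.q.abs().max()
    df["q_norm"] = df.q / (qmax if df.q.max() > 0 else -qmax)
    temperature = sweepset.conditions().temperature
    fit = fit_boltzmann(df.v.to_numpy(), df.q_norm.to_numpy(), mode="qv",
                        temperature=temperature)
    fit.flagged = fit.flagged or flagged
    return df, fit


# ---------------------------------------------------------------------------
# charge immobilization
# ---------------------------------------------------------------------------

@dataclass
class ImmobilizationCurve:
    """Immobilized-charge fraction versus conditioning duration."""

    table: pd.DataFrame  # t_cp, fraction, fraction_sum, flagged
    fits: dict[float, ExpFit] = field(default_factory=dict)
    association: AssociationFit | None = None

    @property
    def plateau(self) -> float:
        return self.association.plateau if self.association else float("nan")

    @property
    def onset_tau(self) -> float:
        return self.association.tau_fast if self.association else float("nan")


def immobilization(sweepset: SweepSet, off_epoch: int = 1,
                   tau_clamp: float = 0.075,
                   denominator: str = "integral") -> ImmobilizationCurve:
    """Immobilized-charge fraction from off-gating currents.

    Per conditioning duration, the off-gating current (starting three clamp
    time constants after the return step) is fitted with a two-component
    exponential decay without offset; the fraction is the slow-component
    charge A_slow τ_slow over the total off charge.  The total is the trace
    integral plus the fitted tail beyond the window (``denominator=
    "integral"``) or the analytic sum of both components (``"sum"``); both
    are reported when they differ by more than 2%.
    """
    if sweepset.kind != "gating":
        raise ValueError("immobilization requires a gating-current sweep set")
    proto = sweepset.protocol()
    if proto.sweep_axis is None or proto.sweep_axis.attr != "duration":
        raise ValueError("immobilization needs a conditioning-duration sweep axis")
    rows = []
    fits: dict[float, ExpFit] = {}
    for t_cp in sweepset.sweep_values:
        t0, t1 = epoch_bounds(sweepset, t_cp, off_epoch)
        start = t0 + 3 * tau_clamp
        fit = fit_exponentials(sweepset.time, sweepset.sweeps[t_cp],
                               window=(start, t1), n_components=2,
                               with_offset=False)
        fits[t_cp] = fit
        if fit.n_components < 2 or not fit.converged:
            rows.append({"t_cp": t_cp, "fraction": 0.0, "fraction_sum": 0.0,
                         "flagged": True})
            continue
        (a_f, tau_f), (a_s, tau_s) = fit.components
        flag = (tau_s / tau_f) < 3.0
        q_slow = abs(a_s * tau_s)
        q_sum = abs(a_f * tau_f) + q_slow
        if q_sum > 0 and abs(a_f * tau_f) / q_sum < 1e-4:
            # the fast component vanished: the decay is single-exponential,
            # i.e. there is no distinct slow (immobilized) fraction
            rows.append({"t_cp": t_cp, "fraction": 0.0, "fraction_sum": 0.0,
                         "flagged": True})
            continue
        # total off charge: integral from the return-step onset over the whole
        # off epoch, plus the fitted tail beyond the window
        sel = (sweepset.time >= t0) & (sweepset.time <= t1)
        q_int = abs(np.trapezoid(sweepset.sweeps[t_cp][sel], sweepset.time[sel]))
        span = t1 - start
        tail = abs(a_f) * tau_f * np.exp(-span / tau_f) + \
            abs(a_s) * tau_s * np.exp(-span / tau_s)
        q_int += tail
        rows.append({"t_cp": t_cp,
                     "fraction": min(q_slow / q_int, 1.0) if q_int else 0.0,
                     "fraction_sum": q_slow / q_sum if q_sum else 0.0,
                     "flagged": flag})
    df = pd.DataFrame(rows).sort_values("t_cp", ignore_index=True)
    col = "fraction" if denominator == "integral" else "fraction_sum"
    assoc = fit_association(df.t_cp.to_numpy(), df[col].to_numpy(),
                            n_components=1)
    return ImmobilizationCurve(table=df, fits=fits, association=assoc)


# ---------------------------------------------------------------------------
# tail kinetics versus depolarization duration
# ---------------------------------------------------------------------------

def tail_tau_vs_duration(sweepset: SweepSet, tail_epoch: int = 1,
                         blanking: float = DEFAULT_BLANKING,
                         tail_window: float | None = None,
                         noise_floor: float = 0.0,
                         ) -> tuple[pd.DataFrame, AssociationFit, dict[float, ExpFit]]:
    """Weighted tail time constant versus depolarization duration.

    Per duration, the tail is fitted with one or two exponential components
    (AIC-selected) and the weighted time constant computed; the resulting
    series is fitted with a two-component exponential association whose fast
    time constant tracks the fast-inactivation time constant.
    """
    proto = sweepset.protocol()
    if proto.sweep_axis is None or proto.sweep_axis.attr != "duration":
        raise ValueError("tail analysis needs a depolarization-duration sweep axis")
    rows = []
    fits: dict[float, ExpFit] = {}
    for dur in sweepset.sweep_values:
        t0, t1 = epoch_bounds(sweepset, dur, tail_epoch)
        if tail_window is not None:
            t1 = min(t1, t0 + tail_window)
        y = sweepset.sweeps[dur]
        sel = (sweepset.time >= t0 + blanking) & (sweepset.time <= t1)
        if noise_floor > 0 and np.max(np.abs(y[sel])) < noise_floor:
            continue
        fit = fit_exponentials_aic(sweepset.time, y,
                                   window=(t0 + blanking, t1), with_offset=True)
        fits[dur] = fit
        rows.append({"duration": dur, "tau_w": weighted_tau(fit),
                     "n_components": fit.n_components})
    df = pd.DataFrame(rows).sort_values("duration", ignore_index=True)
    assoc = fit_association(df.duration.to_numpy(), df.tau_w.to_numpy(),
                            n_components=2)
    return df, assoc, fits
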