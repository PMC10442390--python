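"""Time-resolved selectivity: instantaneous I-V, reversal potentials and the
GHK relative Na+/K+ permeability.

Under bi-ionic conditions (external Na+, internal K+) the reversal potential
of the instantaneous current measured at time t during a depolarization obeys

    V_rev(t) = (RT/F) ln( P_Na [Na+]_o / P_K [K+]_i )

so that tracking V_rev against depolarization time resolves the selectivity
of the state mixture the channel population occupies at that instant -- the
readout that exposes the reduced Na+ selectivity of the leaky inactivated
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curvefit import ExpFit, fit_exponentials, fit_exponentials_aic
from .model_core import IonicConditions
from .simulate import SweepSet
from .inactivation import DEFAULT_BLANKING, epoch_bounds

__all__ = ["SelectivityTimeCourse", "instantaneous_iv", "reversal_potential",
           "permeability_ratio", "reversal_from_ratio", "selectivity_time_course"]


# ---------------------------------------------------------------------------
# instantaneous I-V
# ---------------------------------------------------------------------------

def instantaneous_iv(sweepset: SweepSet, tail_epoch: int = 1,
                     blanking: float = 0.45,
                     tau_clamp: float = 0.075,
                     ) -> pd.DataFrame:
    """Instantaneous tail-current amplitudes across tail voltages.

    Per tail voltage, a single exponential (with offset) is fitted over
    [blanking, blanking + 5 tau] after the step and back-extrapolated to the
    step instant, removing capacitive contamination and deactivation decay.
    The blanking window (default 6 clamp time constants) and a fitted-tau
    floor of 4 clamp time constants keep the fit from locking onto the
    residual clamp-settling edge, whose back-extrapolation would recover the
    pre-step current instead of the tail-voltage response.  Failed fits are
    dropped with a record.
    """
    proto = sweepset.protocol()
    if proto.sweep_axis is None or proto.sweep_axis.attr != "voltage" or \
            proto.sweep_axis.epoch != tail_epoch:
        raise ValueError("instantaneous I-V needs a tail-voltage sweep axis")
    tau_floor = 4.0 * tau_clamp
    rows = []
    for v_tail in sweepset.sweep_values:
        t0, t1 = epoch_bounds(sweepset, v_tail, tail_epoch)
        y = sweepset.sweeps[v_tail]
        try:
            coarse = fit_exponentials(sweepset.time, y,
                                      window=(t0 + blanking, t1),
                                      n_components=1, with_offset=True)
            tau_hat = min(max(coarse.tau, tau_floor), (t1 - t0 - blanking))
            fit = fit_exponentials(
                sweepset.time, y,
                window=(t0 + blanking, min(t0 + blanking + 5 * tau_hat, t1)),
                n_components=1, with_offset=True)
            if not fit.converged:
                raise RuntimeError("tail fit failed")
            a, tau = fit.components[0]
            if tau < tau_floor:
                # relaxation indistinguishable from clamp settling: the level
                # just after blanking is the best instantaneous estimate
                i_inst = a + fit.offset
            else:
                i_inst = a * math.exp(blanking / tau) + fit.offset
            rows.append({"v": v_tail, "i_inst": i_inst, "tau": tau,
                         "dropped": False})
        except (RuntimeError, ValueError) as err:
            rows.append({"v": v_tail, "i_inst": float("nan"),
                         "tau": float("nan"), "dropped": True,
                         "reason": str(err)})
    return pd.DataFrame(rows).sort_values("v", ignore_index=True)


def reversal_potential(v: np.ndarray, i: np.ndarray,
                       refit_halfwidth: float = 40.0) -> tuple[float, dict]:
    """Zero-current crossing of an instantaneous I-V by linear fit.

    A first-pass ordinary-least-squares line locates the crossing; the line is
    refitted once using only points within ``refit_halfwidth`` mV of it to
    guard against GHK curvature far from the reversal.  Points must bracket
    zero current.
    """
    v = np.asarray(v, float)
    i = np.asarray(i, float)
    ok = np.isfinite(v) & np.isfinite(i)
    v, i = v[ok], i[ok]
    if len(v) < 2 or not (i.min() < 0 < i.max()):
        raise ValueError("I-V points do not bracket zero current")

    def ols(vv, ii):
        A = np.vstack([vv, np.ones_like(vv)]).T
        (slope, intercept), res, *_ = np.linalg.lstsq(A, ii, rcond=None)
        ss_tot = np.sum((ii - ii.mean()) ** 2)
        r2 = 1.0 - (res[0] / ss_tot if len(res) and ss_tot > 0 else 0.0)
        return slope, intercept, r2

    slope, intercept, r2 = ols(v, i)
    if slope == 0:
        raise ValueError("degenerate I-V (zero slope)")
    v_rev = -intercept / slope
    sel = np.abs(v - v_rev) <= refit_halfwidth
    if sel.sum() >= 3 and sel.sum() < len(v):
        slope, intercept, r2 = ols(v[sel], i[sel])
        v_rev = -intercept / slope
    return float(v_rev), {"slope": float(slope), "r2": float(r2),
                          "n_points": int(sel.sum() if sel.sum() >= 3 else len(v))}


# ---------------------------------------------------------------------------
# GHK permeability ratio
# ---------------------------------------------------------------------------

def permeability_ratio(v_rev: float, cond: IonicConditions) -> float:
    """P_Na/P_K from a bi-ionic reversal potential:
    P_Na/P_K = ([K+]_i / [Na+]_o) exp(F V_rev / RT)."""
    na_o = cond.conc_out.get("Na", 0.0)
    k_i = cond.conc_in.get("K", 0.0)
    if na_o <= 0 or k_i <= 0:
        raise ValueError("bi-ionic bookkeeping needs [Na]_o > 0 and [K]_i > 0")
    return (k_i / na_o) * math.exp(v_rev / cond.rt_over_f)


def reversal_from_ratio(p_na_over_p_k: float, cond: IonicConditions) -> float:
    """Forward GHK bi-ionic relation: V_rev = (RT/F) ln(P_Na [Na]_o / P_K [K]_i)."""
    na_o = cond.conc_out.get("Na", 0.0)
    k_i = cond.conc_in.get("K", 0.0)
    if na_o <= 0 or k_i <= 0 or p_na_over_p_k <= 0:
        raise ValueError("need positive concentrations and ratio")
    return cond.rt_over_f * math.log(p_na_over_p_k * na_o / k_i)


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

@dataclass
class SelectivityTimeCourse:
    """P_Na/P_K and V_rev versus depolarization time, with the exponential
    fit of the permeability relaxation."""

    table: pd.DataFrame  # t_dep, v_rev, p_ratio, slope, r2
    fit: ExpFit | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def tau_fast(self) -> float:
        if self.fit is None:
            return float("nan")
        return min(tau for _, tau in self.fit.components)

    def ratio_at(self, t_dep: float) -> float:
        row = self.table[self.table.t_dep == t_dep]
        return float(row.p_ratio.iloc[0])


def selectivity_time_course(sweepsets: dict[float, SweepSet],
                            cond: IonicConditions | None = None,
                            tail_epoch: int = 1,
                            blanking: float = DEFAULT_BLANKING,
                            ) -> SelectivityTimeCourse:
    """Compose instantaneous I-V -> V_rev -> P_Na/P_K across depolarization
    times and fit the permeability relaxation with exponential(s).

    ``sweepsets`` maps depolarization duration (ms) to the corresponding
    variable-tail-voltage sweep family.
    """
    if len(sweepsets) < 4:
        raise ValueError("need at least 4 depolarization times")
    rows = []
    for t_dep in sorted(sweepsets):
        ss = sweepsets[t_dep]
        c = cond or ss.conditions()
        iv = instantaneous_iv(ss, tail_epoch=tail_epoch, blanking=blanking)
        good = iv[~iv.dropped]
        v_rev, diag = reversal_potential(good.v.to_numpy(), good.i_inst.to_numpy())
        rows.append({"t_dep": t_dep, "v_rev": v_rev,
                     "p_ratio": permeability_ratio(v_rev, c),
                     "slope": diag["slope"], "r2": diag["r2"]})
    df = pd.DataFrame(rows).sort_values("t_dep", ignore_index=True)
    fit = None
    if len(df) >= 4 and np.ptp(df.p_ratio.to_numpy()) > 1e-6:
        fit = fit_exponentials_aic(df.t_dep.to_numpy(), df.p_ratio.to_numpy(),
                                   with_offset=True, min_samples_per_param=1)
    return SelectivityTimeCourse(table=df, fit=fit)
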