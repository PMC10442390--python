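"""Fitting primitives shared by all analysis pipelines.

Three model classes cover every quantitative readout in the study:

* mono/bi-exponential decays with optional steady offset, for inactivation,
  deactivation (tail) and off-gating kinetics;
* the amplitude-weighted time constant of a two-component fit;
* two-state Boltzmann curves in three flavours: steady-state availability
  (h-infinity, decreasing with a non-inactivating floor ``base``), G-V and
  Q-V (increasing, asymptote ~1).

Exponential fits use peeling-based initial guesses plus a small log-spaced
multistart; uncertainties come from the Jacobian-based covariance at the
optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import thermal_voltage_mV

__all__ = ["ExpFit", "BoltzmannFit", "AssociationFit", "fit_exponentials",
           "weighted_tau", "fit_boltzmann", "fit_association"]


# ---------------------------------------------------------------------------
# exponentials
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    """Result of a 1- or 2-component exponential-decay fit.

    Components are (amplitude, tau) referred to the start of the fit window,
    ordered by ascending tau.  ``offset`` is the steady level (fixed at 0 in
    off-gating mode).
    """

    components: list[tuple[float, float]]
    offset: float
    window: tuple[float, float]
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    aic: float = float("nan")
    n_points: int = 0

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def tau(self) -> float:
        """Time constant of a single-component fit (or the dominant one)."""
        if self.n_components == 1:
            return self.components[0][1]
        amps = [abs(a) for a, _ in self.components]
        return self.components[int(np.argmax(amps))][1]

    @property
    def tau_w(self) -> float:
        return weighted_tau(self)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Model prediction; t measured on the trace's own time base."""
        t0 = self.window[0]
        y = np.full_like(np.asarray(t, dtype=float), self.offset)
        for a, tau in self.components:
            y = y + a * np.exp(-(np.asarray(t, float) - t0) / tau)
        return y

    def to_dict(self) -> dict:
        return {
            "components": [[a, tau] for a, tau in self.components],
            "offset": self.offset,
            "window": list(self.window),
            "stderr": dict(self.stderr),
            "converged": self.converged,
            "aic": self.aic,
            "n_points": self.n_points,
        }


def weighted_tau(fit: ExpFit) -> float:
    """Amplitude-weighted time constant (A1 τ1 + A2 τ2)/(A1 + A2) of a
    two-component fit; collapses to τ for a degenerate single component."""
    if fit.n_components == 1:
        return fit.components[0][1]
    if fit.n_components != 2:
        raise ValueError("weighted tau requires exactly two components")
    (a1, t1), (a2, t2) = fit.components
    if a1 + a2 == 0:
        raise ZeroDivisionError("weighted tau undefined: amplitudes sum to zero")
    return (a1 * t1 + a2 * t2) / (a1 + a2)


def _peel_guess(t: np.ndarray, y: np.ndarray, offset: float,
                n_components: int) -> list[tuple[float, float]]:
    """Peeling: estimate the slow component from the trace tail, subtract,
    estimate the fast one from the residual head."""
    r = y - offset
    span = t[-1] - t[0]
    sign = 1.0 if abs(r[: max(3, len(r) // 10)].mean()) == 0 else np.sign(
        r[: max(3, len(r) // 10)].mean())
    amp0 = r[0] if r[0] != 0 else sign * max(np.max(np.abs(r)), 1e-12)

    def est_tau(tt, rr):
        good = np.abs(rr) > 0.05 * np.max(np.abs(rr))
        if good.sum() < 3:
            return span / 3
        # log-linear slope
        tt, rr = tt[good], np.abs(rr[good])
        A = np.vstack([tt, np.ones_like(tt)]).T
        slope, _ = np.linalg.lstsq(A, np.log(rr), rcond=None)[0]
        if slope >= -1e-12:
            return span / 3
        return min(max(-1.0 / slope, span / 200), span * 5)

    if n_components == 1:
        return [(amp0, est_tau(t - t[0], r))]
    half = len(t) // 2
    tau_s = est_tau(t[half:] - t[0], r[half:])
    slow_amp = r[half] * math.exp((t[half] - t[0]) / tau_s) if abs(
        r[half]) > 0 else 0.3 * amp0
    resid = r - slow_amp * np.exp(-(t - t[0]) / tau_s)
    tau_f = est_tau(t[:half] - t[0], resid[:half])
    if tau_f >= tau_s:
        tau_f = tau_s / 5
    return [(amp0 - slow_amp, tau_f), (slow_amp, tau_s)]


def fit_exponentials(t: np.ndarray, y: np.ndarray,
                     window: tuple[float, float] | None = None,
                     n_components: int = 1,
                     with_offset: bool = True,
                     min_samples_per_param: int = 3) -> ExpFit:
    """Nonlinear least-squares exponential-decay fit.

    ``window`` is (t_start, t_end) on the trace's time base; amplitudes are
    referred to t_start.  Raises on windows shorter than three samples; a fit
    that fails to converge from every start is returned flagged.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if window is None:
        window = (t[0], t[-1])
    sel = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    tt, yy = t[sel], y[sel]
    n_par = 2 * n_components + (1 if with_offset else 0)
    if len(tt) < 3:
        raise ValueError("fit window shorter than three samples")
    if len(tt) < min_samples_per_param * n_par:
        raise ValueError(
            f"window has {len(tt)} samples for {n_par} parameters")
    t0 = tt[0]
    span = tt[-1] - tt[0]

    offset0 = yy[-max(3, len(yy) // 10):].mean() if with_offset else 0.0
    guesses = [_peel_guess(tt, yy, offset0, n_components)]
    # multistart: 3 log-spaced tau seeds
    amp0 = yy[0] - offset0
    for tau_seed in np.geomspace(span / 50, span / 1.5, 3):
        if n_components == 1:
            guesses.append([(amp0, tau_seed)])
        else:
            guesses.append([(amp0 * 0.6, tau_seed / 4), (amp0 * 0.4, tau_seed)])

    def pack(comps, off):
        p = []
        for a, tau in comps:
            p.extend([a, math.log(max(tau, 1e-9))])
        if with_offset:
            p.append(off)
        return np.array(p)

    def unpack(p):
        comps = [(p[2 * i], math.exp(p[2 * i + 1])) for i in range(n_components)]
        off = p[-1] if with_offset else 0.0
        return comps, off

    def resid(p):
        comps, off = unpack(p)
        m = np.full_like(yy, off)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            for a, tau in comps:
                m = m + a * np.exp(np.clip(-(tt - t0) / tau, -700.0, 50.0))
        return m - yy

    best = None
    for g in guesses:
        try:
            sol = least_squares(resid, pack(g, offset0), method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-300:
            best = sol
    if best is None:
        return ExpFit(components=[(float("nan"), float("nan"))] * n_components,
                      offset=float("nan"), window=window, converged=False,
                      n_points=len(tt))

    comps, off = unpack(best.x)
    comps.sort(key=lambda c: c[1])
    # collapse near-duplicate time constants
    if n_components == 2 and abs(comps[0][1] - comps[1][1]) / comps[1][1] < 1e-3:
        comps = [(comps[0][0] + comps[1][0], comps[1][1])]

    # covariance from the Jacobian
    stderr: dict[str, float] = {}
    try:
        J = best.jac
        dof = max(len(tt) - len(best.x), 1)
        cov = np.linalg.inv(J.T @ J) * 2 * best.cost / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        names = []
        for i in range(n_components):
            names += [f"A{i + 1}", f"log_tau{i + 1}"]
        if with_offset:
            names.append("offset")
        stderr = dict(zip(names, se))
    except np.linalg.LinAlgError:
        pass

    rss = 2 * best.cost
    n = len(tt)
    aic = n * math.log(max(rss / n, 1e-300)) + 2 * len(best.x)
    return ExpFit(components=comps, offset=off, window=(t0, tt[-1]),
                  stderr=stderr, converged=best.status > 0, aic=aic, n_points=n)


def fit_exponentials_aic(t: np.ndarray, y: np.ndarray,
                         window: tuple[float, float] | None = None,
                         with_offset: bool = True,
                         min_samples_per_param: int = 3) -> ExpFit:
    """Fit with one and two components and keep the AIC-preferred model."""
    f1 = fit_exponentials(t, y, window, 1, with_offset,
                          min_samples_per_param=min_samples_per_param)
    try:
        f2 = fit_exponentials(t, y, window, 2, with_offset,
                              min_samples_per_param=min_samples_per_param)
    except ValueError:
        return f1
    if not f2.converged or f2.n_components == 1:
        return f1
    return f2 if f2.aic < f1.aic else f1


# ---------------------------------------------------------------------------
# Boltzmann curves
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannFit:
    """Two-state Boltzmann fit: mode ``h_inf`` (decreasing, floor ``base``),
    ``gv`` or ``qv`` (increasing, amplitude ``gmax``)."""

    v_half: float  # mV
    z: float  # elementary charges
    mode: str
    base: float = 0.0
    gmax: float = 1.0
    stderr: dict[str, float] = field(default_factory=dict)
    flagged: bool = False
    temperature: float = 11.5

    def evaluate(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, float)
        f_rt = 1.0 / thermal_voltage_mV(self.temperature)
        arg = np.clip(-self.z * f_rt * (V - self.v_half), -700.0, 700.0)
        boltz = 1.0 / (1.0 + np.exp(arg))
        if self.mode == "h_inf":
            return 1.0 - (1.0 - self.base) * boltz
        return self.gmax * boltz

    def to_dict(self) -> dict:
        return {"v_half": self.v_half, "z": self.z, "mode": self.mode,
                "base": self.base, "gmax": self.gmax,
                "stderr": dict(self.stderr), "flagged": self.flagged}


def fit_boltzmann(x: np.ndarray, y: np.ndarray, mode: str,
                  temperature: float = 11.5) -> BoltzmannFit:
    """Least-squares two-state Boltzmann fit of normalized data.

    h_inf mode fits ``1 - (1-base)/(1+exp(-zF(V-V1/2)/RT))``; gv/qv fit
    ``gmax/(1+exp(-zF(V-V1/2)/RT))``.  Requires >= 5 points spanning the
    transition; flat data raise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if mode not in ("h_inf", "gv", "qv"):
        raise ValueError("mode must be h_inf, gv or qv")
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(y) < 1e-6 * max(np.max(np.abs(y)), 1e-30):
        raise ValueError("no transition in the data (values effectively constant)")
    f_rt = 1.0 / thermal_voltage_mV(temperature)

    # initial guesses from the midpoint crossing
    if mode == "h_inf":
        y_mid = (y.max() + y.min()) / 2
        order = np.argsort(x)
        v0 = float(np.interp(-y_mid, -y[order], x[order]))
    else:
        y_mid = y.max() / 2
        order = np.argsort(x)
        v0 = float(np.interp(y_mid, y[order], x[order]))
    z0 = 3.0

    def model(p):
        if mode == "h_inf":
            v_half, z, base = p
            return 1.0 - (1.0 - base) / (1.0 + np.exp(-z * f_rt * (x - v_half)))
        v_half, z, gmax = p
        return gmax / (1.0 + np.exp(-z * f_rt * (x - v_half)))

    if mode == "h_inf":
        p0 = np.array([v0, z0, max(min(y.min(), 0.99), 0.0)])
        lo = [-150.0, 1e-3, 0.0]
        hi = [100.0, 15.0, 1.0 - 1e-9]
    else:
        p0 = np.array([v0, z0, max(y.max(), 0.5)])
        lo = [-150.0, 1e-3, 0.1]
        hi = [100.0, 15.0, 2.0]

    sol = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p = sol.x
    flagged = bool(np.any(np.isclose(p, lo) | np.isclose(p, hi)))

    stderr: dict[str, float] = {}
    try:
        J = sol.jac
        dof = max(len(x) - 3, 1)
        cov = np.linalg.inv(J.T @ J) * 2 * sol.cost / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        names = ["v_half", "z", "base" if mode == "h_inf" else "gmax"]
        stderr = dict(zip(names, se))
    except np.linalg.LinAlgError:
        pass

    if mode == "h_inf":
        return BoltzmannFit(v_half=p[0], z=p[1], mode=mode, base=p[2],
                            stderr=stderr, flagged=flagged, temperature=temperature)
    return BoltzmannFit(v_half=p[0], z=p[1], mode=mode, gmax=p[2],
                        stderr=stderr, flagged=flagged, temperature=temperature)


# ---------------------------------------------------------------------------
# exponential association (for immobilization and tail-slowing series)
# ---------------------------------------------------------------------------

@dataclass
class AssociationFit:
    """y(t) = y0 + sum_i A_i (1 - exp(-t/tau_i)); taus ascending."""

    y0: float
    components: list[tuple[float, float]]
    converged: bool = True

    @property
    def plateau(self) -> float:
        return self.y0 + sum(a for a, _ in self.components)

    @property
    def tau_fast(self) -> float:
        return self.components[0][1]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        y = np.full_like(t, self.y0)
        for a, tau in self.components:
            y = y + a * (1.0 - np.exp(-t / tau))
        return y

    def to_dict(self) -> dict:
        return {"y0": self.y0,
                "components": [[a, tau] for a, tau in self.components],
                "converged": self.converged}


def fit_association(t: np.ndarray, y: np.ndarray,
                    n_components: int = 1) -> AssociationFit:
    """Exponential-association fit of a summary series (e.g. immobilized
    fraction or weighted tail tau versus conditioning duration)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    span = max(t.max(), 1e-9)
    amp = y[-1] - y[0]

    def resid(p):
        y0 = p[0]
        m = np.full_like(y, y0)
        for i in range(n_components):
            a, ltau = p[1 + 2 * i], p[2 + 2 * i]
            m = m + a * (1.0 - np.exp(-t / math.exp(ltau)))
        return m - y

    best = None
    for tau_seed in np.geomspace(span / 30, span, 4):
        p0 = [y[0]]
        for i in range(n_components):
            p0 += [amp / n_components, math.log(tau_seed * (3.0 ** i))]
        try:
            sol = least_squares(resid, np.array(p0), method="lm",
                                xtol=1e-14, ftol=1e-14, max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return AssociationFit(y0=float("nan"),
                              components=[(float("nan"), float("nan"))],
                              converged=False)
    p = best.x
    comps = [(p[1 + 2 * i], math.exp(p[2 + 2 * i])) for i in range(n_components)]
    comps.sort(key=lambda c: c[1])
    return AssociationFit(y0=p[0], components=comps, converged=best.status > 0)
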