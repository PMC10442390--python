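"""Master-equation integration and synthetic voltage-clamp recordings.

This module is the synthetic-data stage: it propagates the eight-state
occupancy under a voltage protocol, renders ionic currents through the GHK
flux equation and gating currents from voltage-sensor flux, and emulates the
acquisition chain (clamp settling, 4-pole Bessel filtering, capacitive
transients, Gaussian noise, online P/N subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.signal import bessel, lfilter

from .constants import thermal_voltage_mV
from .model_core import (
    Epoch,
    IonicConditions,
    StateModel,
    VoltageProtocol,
    equilibrium_distribution,
    rate_matrix,
)

__all__ = [
    "OccupancyTrace",
    "SweepSet",
    "AcquisitionSettings",
    "integrate_occupancies",
    "ionic_current",
    "gating_current",
    "gating_charge",
    "ghk_flux",
    "record",
    "run_protocol",
]


# ---------------------------------------------------------------------------
# occupancy integration
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTrace:
    time: np.ndarray  # ms
    occupancy: np.ndarray  # (n_samples, n_states)
    voltage: np.ndarray  # mV, post clamp settling

    def __post_init__(self):
        occ = self.occupancy
        if occ.min() < -1e-8 or occ.max() > 1 + 1e-8:
            raise ValueError("occupancies outside [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("occupancy rows do not sum to 1")


def command_voltage(protocol: VoltageProtocol, sweep_value: float,
                    include_holding: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample grid and command-voltage series for one sweep."""
    epochs = protocol.epochs_for(sweep_value)
    dt = protocol.sample_interval
    segs = []
    if include_holding > 0:
        segs.append(Epoch(include_holding, protocol.holding))
    segs.extend(epochs)
    total = sum(e.duration for e in segs)
    n = int(round(total / dt))
    t = np.arange(n + 1) * dt
    v = np.empty(n + 1)
    edges = np.cumsum([0.0] + [e.duration for e in segs])
    for (t0, t1), e in zip(zip(edges[:-1], edges[1:]), segs):
        sel = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
        v[sel] = e.voltage
    v[-1] = segs[-1].voltage
    return t, v


def settled_voltage(t: np.ndarray, v_cmd: np.ndarray, holding: float,
                    tau_clamp: float) -> np.ndarray:
    """Membrane voltage after single-pole clamp settling (tau in ms)."""
    if tau_clamp <= 0:
        return v_cmd.copy()
    dt = t[1] - t[0]
    a = np.exp(-dt / tau_clamp)
    v = np.empty_like(v_cmd)
    v[0] = holding
    for k in range(1, len(v_cmd)):
        v[k] = v_cmd[k] + (v[k - 1] - v_cmd[k]) * a
    return v


def integrate_occupancies(model: StateModel, protocol: VoltageProtocol,
                          sweep_value: float = 0.0,
                          conditions: IonicConditions | None = None,
                          tau_clamp: float = 0.075,
                          backend: str = "expm",
                          pre_holding: float = 1.0) -> OccupancyTrace:
    """Propagate state occupancies over one sweep.

    The initial condition is the equilibrium distribution at the holding
    voltage.  Voltage steps are low-pass filtered with the clamp settling
    time constant (default 75 µs); within each sample interval the voltage
    is treated as constant at the interval midpoint, and the master equation
    is advanced either by matrix exponentials (``backend="expm"``, cached per
    distinct voltage) or by stiff ODE integration (``backend="ode"``).
    """
    T = conditions.temperature if conditions is not None else 11.5
    dt = protocol.sample_interval
    t, v_cmd = command_voltage(protocol, sweep_value, include_holding=pre_holding)
    v = settled_voltage(t, v_cmd, protocol.holding, tau_clamp)
    v_mid = 0.5 * (v[:-1] + v[1:])

    p0 = equilibrium_distribution(model, protocol.holding, T)
    n = model.n_states
    occ = np.empty((len(t), n))
    occ[0] = p0

    if backend == "expm":
        cache: dict[float, np.ndarray] = {}
        p = p0
        for k, vm in enumerate(v_mid):
            M = cache.get(vm)
            if M is None:
                M = expm(rate_matrix(model, vm, T) * dt)
                cache[vm] = M
            p = M @ p
            occ[k + 1] = p
    elif backend == "ode":
        from scipy.integrate import solve_ivp

        def rhs(tt, p):
            k = min(int(tt / dt), len(v_mid) - 1)
            return rate_matrix(model, v_mid[k], T) @ p

        sol = solve_ivp(rhs, (0.0, t[-1]), p0, t_eval=t, method="LSODA",
                        max_step=dt, rtol=1e-10, atol=1e-12)
        occ = sol.y.T
    else:
        raise ValueError("backend must be 'expm' or 'ode'")

    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=1, keepdims=True)
    return OccupancyTrace(time=t, occupancy=occ, voltage=v)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def ghk_flux(V: np.ndarray | float, z: int, conc_in: float, conc_out: float,
             rt_over_f: float) -> np.ndarray:
    """GHK flux factor z^2 u (c_i - c_o e^{-z u}) / (1 - e^{-z u}), u = V/(RT/F).

    Per unit permeability; the V -> 0 singularity is handled analytically.
    Positive values are outward current.
    """
    V = np.asarray(V, dtype=float)
    u = V / rt_over_f
    a = z * u
    small = np.abs(a) < 1e-6
    a_safe = np.where(small, 1.0, a)
    full = z * a_safe * (conc_in - conc_out * np.exp(-a_safe)) / (-np.expm1(-a_safe))
    series = z * (conc_in - conc_out) + z * a * (conc_in + conc_out) / 2.0
    return np.where(small, series, full)


def gating_charge(occ: OccupancyTrace, model: StateModel,
                  scale: float = 0.02) -> np.ndarray:
    """Cumulative gating charge Q(t) = scale * w . p(t) (the exact time
    integral of the gating current; w is the per-state charge coordinate)."""
    w = model.charge_coordinate()
    return scale * (occ.occupancy @ w)


def _conductance_series(occ: OccupancyTrace, cond: IonicConditions,
                        model: StateModel) -> np.ndarray:
    """Total current per state occupancy, summed over species (µA)."""
    rt_f = cond.rt_over_f
    total = np.zeros(len(occ.time))
    for sp in cond.species:
        perm = model.conductance_vector(sp.name)
        if not np.any(perm):
            continue
        flux = ghk_flux(occ.voltage, sp.valence, cond.conc_in.get(sp.name, 0.0),
                        cond.conc_out.get(sp.name, 0.0), rt_f)
        total += (occ.occupancy @ perm) * flux
    return model.p_max_Na * total


def ionic_current(occ: OccupancyTrace, cond: IonicConditions,
                  model: StateModel) -> np.ndarray:
    """Ionic current trace (µA, outward positive) for one sweep."""
    if not any(s.conducting for s in model.states):
        raise ValueError("model has no conducting state")
    return _conductance_series(occ, cond, model)


def gating_current(occ: OccupancyTrace, model: StateModel,
                   scale: float = 0.02) -> np.ndarray:
    """Gating current (µA): rate of gating-charge displacement.

    Computed as w . (A p) where w is the per-state charge coordinate, so the
    on- and off-charge integrals cancel exactly over a closed cycle.
    ``scale`` converts e0/ms per channel-population to µA.
    """
    w = model.charge_coordinate()
    if not np.any(w):
        raise ValueError("model carries no gating charge")
    T = 11.5
    ig = np.empty(len(occ.time))
    cache: dict[float, np.ndarray] = {}
    for k, vk in enumerate(occ.voltage):
        row = cache.get(vk)
        if row is None:
            row = w @ rate_matrix(model, vk, T)
            cache[vk] = row
        ig[k] = row @ occ.occupancy[k]
    return scale * ig


# ---------------------------------------------------------------------------
# acquisition chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSettings:
    """Recording emulation: filtering, artifacts, noise, subtraction."""

    filter_cutoff_kHz: float = 20.0
    noise_sigma: float = 0.0  # µA, before filtering
    capacitance: float = 0.0  # µA·ms per mV of step (linear transient amplitude)
    leak_conductance: float = 0.0  # µA per mV (linear leak)
    tau_clamp: float = 0.075  # ms
    apply_subtraction: bool = False

    def to_dict(self) -> dict:
        return {
            "filter_cutoff_kHz": self.filter_cutoff_kHz,
            "noise_sigma": self.noise_sigma,
            "capacitance": self.capacitance,
            "leak_conductance": self.leak_conductance,
            "tau_clamp": self.tau_clamp,
            "apply_subtraction": self.apply_subtraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSettings":
        return cls(**d)


@dataclass
class SweepSet:
    """Time base plus per-sweep current traces and regeneration metadata."""

    time: np.ndarray  # ms
    sweeps: dict[float, np.ndarray]  # µA, keyed by sweep-axis value
    kind: str  # ionic | gating | mixed
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("ionic", "gating", "mixed"):
            raise ValueError("kind must be ionic, gating or mixed")
        for k, y in self.sweeps.items():
            if len(y) != len(self.time):
                raise ValueError(f"sweep {k} does not share the time grid")

    @property
    def sweep_values(self) -> list[float]:
        return sorted(self.sweeps)

    def protocol(self) -> VoltageProtocol:
        return VoltageProtocol.from_dict(self.metadata["protocol"])

    def conditions(self) -> IonicConditions:
        return IonicConditions.from_dict(self.metadata["conditions"])


def _bessel_filter(y: np.ndarray, dt_ms: float, cutoff_kHz: float) -> np.ndarray:
    if cutoff_kHz <= 0:
        return y
    fs = 1.0 / (dt_ms * 1e-3)  # Hz
    fc = cutoff_kHz * 1e3
    if fc >= fs / 2:
        return y
    b, a = bessel(4, fc, fs=fs, norm="mag")
    # seed filter state with the initial value to avoid a start-up transient
    y0 = np.full(64, y[0])
    out = lfilter(b, a, np.concatenate([y0, y]))
    return out[64:]


def _linear_artifacts(t: np.ndarray, v: np.ndarray, acq: AcquisitionSettings) -> np.ndarray:
    """Linear leak plus capacitive transient current for a settled voltage
    trace; C dV/dt with the clamp-settled waveform."""
    art = acq.leak_conductance * v
    if acq.capacitance > 0:
        dv = np.gradient(v, t)
        art = art + acq.capacitance * dv
    return art


def record(raw: dict[float, np.ndarray], t: np.ndarray,
           voltages: dict[float, np.ndarray],
           acquisition: AcquisitionSettings, seed: int | None,
           kind: str, metadata: dict,
           sub_raw: dict[float, list[np.ndarray]] | None = None,
           sub_voltages: dict[float, list[np.ndarray]] | None = None) -> SweepSet:
    """Apply the acquisition chain to raw model currents.

    With ``apply_subtraction`` the P/N sub-sweep responses (model current plus
    linear components, individually filtered and noised) are summed onto the
    main sweep and the pre-step baseline is removed, cancelling linear leak
    and capacitive components exactly in the noiseless case.
    """
    rng = np.random.default_rng(seed) if acquisition.noise_sigma > 0 else None
    if acquisition.noise_sigma > 0 and seed is None:
        raise ValueError("seed is mandatory when noise sigma > 0")
    dt = t[1] - t[0]
    out: dict[float, np.ndarray] = {}
    warn_flags: list[float] = []
    for key, y in raw.items():
        v = voltages[key]
        trace = y + _linear_artifacts(t, v, acquisition)
        if rng is not None:
            trace = trace + rng.normal(0.0, acquisition.noise_sigma, len(trace))
        trace = _bessel_filter(trace, dt, acquisition.filter_cutoff_kHz)
        if acquisition.apply_subtraction and sub_raw is not None:
            for ys, vs in zip(sub_raw[key], sub_voltages[key]):
                s = ys + _linear_artifacts(t, vs, acquisition)
                if rng is not None:
                    s = s + rng.normal(0.0, acquisition.noise_sigma, len(s))
                s = _bessel_filter(s, dt, acquisition.filter_cutoff_kHz)
                trace = trace + s
                if np.max(np.abs(vs)) > 200:
                    warn_flags.append(key)
            # remove the DC offset using the pre-step baseline
            n_base = max(4, int(0.5 / dt))
            trace = trace - trace[:n_base].mean()
        out[key] = trace
    md = dict(metadata)
    md["acquisition"] = acquisition.to_dict()
    md["seed"] = seed
    if warn_flags:
        md["subtraction_voltage_warning"] = sorted(set(warn_flags))
    return SweepSet(time=t, sweeps=out, kind=kind, metadata=md)


# ---------------------------------------------------------------------------
# protocol runner
# ---------------------------------------------------------------------------

def _sub_protocol(protocol: VoltageProtocol, sweep_value: float,
                  sub: "Subtraction") -> list[tuple[np.ndarray, np.ndarray]]:
    """Command voltages of the P/N sub-sweeps for one main sweep."""
    t, v_main = command_voltage(protocol, sweep_value, include_holding=1.0)
    n = abs(sub.n)
    sign = 1.0 if sub.n > 0 else -1.0
    subs = []
    for _ in range(n):
        v_sub = sub.holding + sign * (v_main - protocol.holding) / n
        subs.append((t, v_sub))
    return subs


def run_protocol(variant: str, protocol: VoltageProtocol,
                 conditions: IonicConditions,
                 acquisition: AcquisitionSettings | None = None,
                 seed: int | None = None,
                 kind: str = "ionic",
                 gating_scale: float = 0.02,
                 model: StateModel | None = None) -> SweepSet:
    """Simulate a full sweep family: integrate occupancies, render currents,
    apply the acquisition chain.

    ``kind="gating"`` forces all permeabilities to zero (TTX/impermeant-ion
    mode) and renders the gating current; ``kind="mixed"`` sums both.
    """
    from .model_core import build_state_model

    acq = acquisition or AcquisitionSettings()
    if model is None:
        model = build_state_model(variant)

    raw: dict[float, np.ndarray] = {}
    volts: dict[float, np.ndarray] = {}
    sub_raw: dict[float, list[np.ndarray]] = {}
    sub_volts: dict[float, list[np.ndarray]] = {}
    t_ref = None
    for sv in protocol.sweep_values():
        occ = integrate_occupancies(model, protocol, sv, conditions,
                                    tau_clamp=acq.tau_clamp)
        y = np.zeros(len(occ.time))
        if kind in ("ionic", "mixed") and any(s.conducting for s in model.states):
            y = y + ionic_current(occ, conditions, model)
        if kind in ("gating", "mixed") and np.any(model.charge_coordinate()):
            y = y + gating_current(occ, model, scale=gating_scale)
        raw[sv] = y
        volts[sv] = occ.voltage
        if t_ref is None or len(occ.time) > len(t_ref):
            t_ref = occ.time
        if acq.apply_subtraction and protocol.subtraction is not None:
            subs_y, subs_v = [], []
            for ts, vs in _sub_protocol(protocol, sv, protocol.subtraction):
                occ_s = _integrate_along(model, ts, vs, protocol.subtraction.holding,
                                         conditions, acq.tau_clamp)
                ys = np.zeros(len(ts))
                if kind in ("ionic", "mixed") and any(s.conducting for s in model.states):
                    ys = ys + ionic_current(occ_s, conditions, model)
                if kind in ("gating", "mixed") and np.any(model.charge_coordinate()):
                    ys = ys + gating_current(occ_s, model, scale=gating_scale)
                subs_y.append(ys)
                subs_v.append(occ_s.voltage)
            sub_raw[sv] = subs_y
            sub_volts[sv] = subs_v

    # variable-duration families: right-pad sweeps with their final value so
    # every sweep shares the longest grid
    assert t_ref is not None
    for sv, y in raw.items():
        if len(y) < len(t_ref):
            pad = len(t_ref) - len(y)
            raw[sv] = np.concatenate([y, np.full(pad, y[-1])])
            volts[sv] = np.concatenate([volts[sv], np.full(pad, volts[sv][-1])])
            if sv in sub_raw:
                sub_raw[sv] = [np.concatenate([s, np.full(pad, s[-1])])
                               for s in sub_raw[sv]]
                sub_volts[sv] = [np.concatenate([s, np.full(pad, s[-1])])
                                 for s in sub_volts[sv]]

    metadata = {
        "variant": variant,
        "protocol": protocol.to_dict(),
        "conditions": conditions.to_dict(),
        "kind": kind,
        "gating_scale": gating_scale,
        "pre_holding_ms": 1.0,
        "schema_version": 1,
    }
    return record(raw, t_ref, volts, acq, seed, kind, metadata,
                  sub_raw=sub_raw or None, sub_voltages=sub_volts or None)


def _integrate_along(model: StateModel, t: np.ndarray, v_cmd: np.ndarray,
                     holding: float, conditions: IonicConditions,
                     tau_clamp: float) -> OccupancyTrace:
    """Integrate along an explicit command-voltage series (sub-sweeps)."""
    T = conditions.temperature
    dt = t[1] - t[0]
    v = settled_voltage(t, v_cmd, holding, tau_clamp)
    v_mid = 0.5 * (v[:-1] + v[1:])
    p = equilibrium_distribution(model, holding, T)
    occ = np.empty((len(t), model.n_states))
    occ[0] = p
    cache: dict[float, np.ndarray] = {}
    for k, vm in enumerate(v_mid):
        M = cache.get(vm)
        if M is None:
            M = expm(rate_matrix(model, vm, T) * dt)
            cache[vm] = M
        p = M @ p
        occ[k + 1] = p
    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=1, keepdims=True)
    return OccupancyTrace(time=t, occupancy=occ, voltage=v)
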