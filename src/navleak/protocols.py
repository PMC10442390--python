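"""Shipped voltage-protocol builders mirroring the study's recording
conditions (holding near -100 mV, -80 mV tails, +60 mV test depolarizations,
P/-4 subtraction available where relevant)."""

from __future__ import annotations

from .model_core import Epoch, Subtraction, SweepAxis, VoltageProtocol

__all__ = ["step_protocol", "iv_family", "hinf_protocol", "tails_protocol",
           "immobilization_protocol", "qv_protocol", "instantaneous_iv_protocol"]


def step_protocol(step_mV: float = 60.0, duration: float = 30.0,
                  holding: float = -100.0, tail: float = -80.0,
                  tail_duration: float = 10.0,
                  sample_interval: float = 0.01,
                  subtraction: bool = False) -> VoltageProtocol:
    """Single depolarizing step followed by a repolarizing tail."""
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(duration, step_mV), Epoch(tail_duration, tail)),
        subtraction=Subtraction(-4, -120.0) if subtraction else None,
        sample_interval=sample_interval,
    )


def iv_family(v_min: float = -80.0, v_max: float = 80.0, dv: float = 10.0,
              duration: float = 30.0, holding: float = -100.0,
              sample_interval: float = 0.02) -> VoltageProtocol:
    """Voltage family for peak/steady I-V and G-V analysis."""
    values = tuple(v_min + dv * k for k in range(int(round((v_max - v_min) / dv)) + 1))
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(duration, 0.0), Epoch(10.0, -80.0)),
        sweep_axis=SweepAxis(epoch=0, attr="voltage", values=values),
        sample_interval=sample_interval,
    )


def hinf_protocol(v_min: float = -100.0, v_max: float = -10.0, dv: float = 5.0,
                  conditioning: float = 40.0, test_mV: float = 60.0,
                  test_duration: float = 12.0, holding: float = -120.0,
                  sample_interval: float = 0.02) -> VoltageProtocol:
    """Conditioning pulses across voltage followed by a fixed test pulse."""
    values = tuple(v_min + dv * k for k in range(int(round((v_max - v_min) / dv)) + 1))
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(conditioning, 0.0), Epoch(test_duration, test_mV),
                Epoch(8.0, holding)),
        sweep_axis=SweepAxis(epoch=0, attr="voltage", values=values),
        sample_interval=sample_interval,
    )


def tails_protocol(durations=(0.3, 0.5, 0.8, 1.2, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0),
                   step_mV: float = 60.0, tail: float = -80.0,
                   tail_duration: float = 15.0, holding: float = -100.0,
                   sample_interval: float = 0.01) -> VoltageProtocol:
    """Variable-duration depolarization followed by a fixed -80 mV tail."""
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(max(durations), step_mV), Epoch(tail_duration, tail)),
        sweep_axis=SweepAxis(epoch=0, attr="duration", values=tuple(durations)),
        sample_interval=sample_interval,
    )


def immobilization_protocol(durations=(0.3, 0.5, 0.8, 1.2, 2.0, 3.0, 5.0,
                                       8.0, 12.0, 18.0, 25.0),
                            step_mV: float = 60.0, off_mV: float = -100.0,
                            off_duration: float = 20.0,
                            holding: float = -120.0,
                            sample_interval: float = 0.01) -> VoltageProtocol:
    """Conditioning pulses of increasing duration, off-gating at return."""
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(max(durations), step_mV), Epoch(off_duration, off_mV)),
        sweep_axis=SweepAxis(epoch=0, attr="duration", values=tuple(durations)),
        sample_interval=sample_interval,
    )


def qv_protocol(v_min: float = -120.0, v_max: float = 40.0, dv: float = 10.0,
                duration: float = 60.0, holding: float = -120.0,
                sample_interval: float = 0.02) -> VoltageProtocol:
    """On-gating pulses for the charge-voltage relation."""
    values = tuple(v_min + dv * k for k in range(int(round((v_max - v_min) / dv)) + 1))
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(duration, 0.0), Epoch(15.0, holding)),
        sweep_axis=SweepAxis(epoch=0, attr="voltage", values=values),
        sample_interval=sample_interval,
    )


def instantaneous_iv_protocol(t_dep: float, step_mV: float = 60.0,
                              tail_min: float = -60.0, tail_max: float = 60.0,
                              dv: float = 10.0, tail_duration: float = 10.0,
                              holding: float = -100.0,
                              sample_interval: float = 0.01) -> VoltageProtocol:
    """Fixed-duration depolarization, variable tail voltage (one family per
    depolarization time)."""
    values = tuple(tail_min + dv * k
                   for k in range(int(round((tail_max - tail_min) / dv)) + 1))
    return VoltageProtocol(
        holding=holding,
        epochs=(Epoch(t_dep, step_mV), Epoch(tail_duration, 0.0)),
        sweep_axis=SweepAxis(epoch=1, attr="voltage", values=values),
        sample_interval=sample_interval,
    )
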