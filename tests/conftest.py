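"""Shared fixtures: solutions, acquisition settings, and cached simulation
runs reused across test modules (all noiseless and deterministic)."""

import numpy as np
import pytest

import navleak
from navleak import protocols
from navleak.simulate import AcquisitionSettings, run_protocol


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def cond_na():
    return navleak.na_out_na_in()


@pytest.fixture(scope="session")
def cond_bi():
    return navleak.biionic_na_out_k_in()


@pytest.fixture(scope="session")
def cond_gating():
    return navleak.gating_solutions()


@pytest.fixture(scope="session")
def wt_model():
    return navleak.build_state_model("WT")


@pytest.fixture(scope="session")
def step_sweeps(acq, cond_na):
    """30 ms step to +60 mV for WT / DIIIAA / DIVAA."""
    return {v: run_protocol(v, protocols.step_protocol(), cond_na, acq)
            for v in ("WT", "DIIIAA", "DIVAA")}


@pytest.fixture(scope="session")
def diiiaa_tails(acq, cond_na):
    return run_protocol("DIIIAA", protocols.tails_protocol(), cond_na, acq)


@pytest.fixture(scope="session")
def wt_gating_family(acq, cond_gating):
    return run_protocol("WT", protocols.immobilization_protocol(), cond_gating,
                        acq, kind="gating")


@pytest.fixture(scope="session")
def hinf_fits(acq, cond_na):
    from navleak.inactivation import h_infinity
    out = {}
    for v in ("WT", "DIIIAA"):
        ss = run_protocol(v, protocols.hinf_protocol(), cond_na, acq)
        out[v] = h_infinity(ss)
    return out


def two_state_model(k12: float, k21: float, z: float = 0.0,
                    conducting: bool = True):
    """Minimal two-state model for closed-form oracles."""
    from navleak.model_core import GatingState, StateModel, Transition
    states = (
        GatingState(1, "C", False, {"Na": 0.0, "K": 0.0}),
        GatingState(2, "O", conducting,
                    {"Na": 1.0, "K": 1.0 / 11.0} if conducting
                    else {"Na": 0.0, "K": 0.0}),
    )
    trans = (Transition(1, 2, k12, k21, z_eff=z, delta=0.5, q_gating=z),)
    return StateModel(states=states, transitions=trans, p_max_Na=1.0,
                      total_gating_charge=max(z, 1.0))
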