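"""Time-resolved Na+/K+ selectivity during depolarization.

Simulates instantaneous I-V families (bi-ionic: 57.5 mM Na+ out, 120 mM K+
in) at several times during a +60 mV pulse, extracts the reversal potential
by linear fit and converts it to P_Na/P_K through the bi-ionic GHK relation.
For the quadruple S6 mutant the ratio falls from ~2.4 at the pulse onset to
~1.5 at steady state: the leaky inactivated pore is less Na+ selective.
"""

import navleak
from navleak import protocols
from navleak.selectivity import selectivity_time_course
from navleak.simulate import AcquisitionSettings, run_protocol

cond = navleak.biionic_na_out_k_in()
acq = AcquisitionSettings()

for variant in ("WT", "DIII_IVAA"):
    fams = {t: run_protocol(variant, protocols.instantaneous_iv_protocol(t),
                            cond, acq)
            for t in (0.3, 0.6, 1.0, 2.0, 5.0, 20.0)}
    tc = selectivity_time_course(fams)
    print(f"\n{variant}:")
    print(tc.table[["t_dep", "v_rev", "p_ratio", "r2"]].to_string(index=False))

print("\nWT stays at its resting selectivity (~11); the quadruple mutant's "
      "reversal moves\nnegative as the population enters the leaky "
      "inactivated state.")
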