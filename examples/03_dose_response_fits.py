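"""Hill fits of channel activation and inhibition dose-response data.

Simulates noisy fold-increase measurements for an activating steroid
(true EC50 10 uM) and an inhibiting one (true IC50 8.6 uM), fits both
Hill models and prints the recovered parameters.  The fold increase is
the treated/control current ratio at -80 mV; the ramp example at the end
shows how that ratio is measured from simulated voltage-ramp recordings.
"""

import numpy as np

from myoflow import (current_at, fit_hill_activation, fit_hill_inhibition,
                     fold_increase, generate_dose_response,
                     generate_ramp_recording)

conc = np.geomspace(0.3, 300, 9)

act = fit_hill_activation(
    generate_dose_response(10.0, 1.5, 4.6, conc, noise_sd=0.15, seed=1))
print(f"activation:  EC50 {act.half_max:5.2f} uM (true 10.0), "
      f"hill {act.hill_coefficient:.2f}, plateau {act.plateau:.2f}-fold")

inh = fit_hill_inhibition(
    generate_dose_response(8.6, 1.2, 4.0, conc, noise_sd=0.15, seed=2,
                           mode="inhibition"))
print(f"inhibition:  IC50 {inh.half_max:5.2f} uM (true 8.6), "
      f"hill {inh.hill_coefficient:.2f}, top {inh.plateau:.2f}-fold")

control = generate_ramp_recording(conductance=1.0, capacitance=14.0)
treated = generate_ramp_recording(conductance=4.57, capacitance=14.0)
fi = fold_increase(current_at(treated, -80.0), current_at(control, -80.0))
print(f"ramp pair:   I(-80 mV) {current_at(control, -80.0):.1f} -> "
      f"{current_at(treated, -80.0):.1f} pA, fold increase {fi:.2f}")
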