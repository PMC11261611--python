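"""Onset and lingering kinetics relative to the fluorescein reference.

Runs the calibrated kinetics scenarios for a high advantame dose and a
high sucrose dose (each one agonist injection followed by a fluorescein
injection in the same run) on twenty independently simulated arrays, and
prints the median sensory-analog metrics: onset (peak-maximum delay
behind the dye peak) and Δfwhm lingering (excess width of the response
peak over the dye peak).
"""

import numpy as np

from tonguechip import kinetics_run, preset

scenarios = preset("table2_kinetics")
for key, sample in (
    ("advantame_high", "advantame_0.015mM"),
    ("sucrose_high", "sucrose_100mM"),
):
    onsets, lingers, rel_rises = [], [], []
    for seed in range(1, 21):
        traces = scenarios[key].simulate(seed=seed)
        m = kinetics_run(traces, sample)
        onsets.append(m.onset)
        lingers.append(m.delta_fwhm_lingering or 0.0)
        rel_rises.append(m.rel_rise)
    print(
        f"{key:15s}: onset {np.median(onsets):4.1f} s, "
        f"lingering {np.median(lingers):4.1f} s, "
        f"relative rise {np.median(rel_rises):3.0f}%   (medians of 20 arrays)"
    )
print(
    "\nAdvantame peaks almost with the dye (fast onset) but its response"
    "\nstays wide (long lingering); sucrose peaks later and decays quickly."
)
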