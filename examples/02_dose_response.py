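"""Sweet-receptor dose-response: from raw traces to EC50 and EC10.

Generates the sucrose dose series (five ascending injections over an
array with 11 sweet-receptor spots plus umami/mock/sensor controls) for
five independently simulated arrays, processes the two-channel traces,
fits the Hill curve to the per-dose responses of the umami-corrected
mean trace of each array, and prints the recovered EC50s together with
the EC10 "taste threshold" analog of the median fit.
"""

import numpy as np

from tonguechip import dose_response_fit, ec_fraction, preset

scenario = preset("fig2_sucrose_series")
fits = []
for seed in range(1, 6):
    traces = scenario.simulate(seed=seed)
    fit = dose_response_fit(traces, dict(scenario.sample_doses), aggregate="mean_trace")
    fits.append(fit)
    print(f"array {seed}: EC50 {fit.ec50:5.1f} mM, Hill slope {fit.hill:.2f}")

median_fit = sorted(fits, key=lambda f: f.ec50)[len(fits) // 2]
print(f"\ndoses tested : {sorted(scenario.sample_doses.values())} mM")
print(f"median EC50  : {median_fit.ec50:.1f} mM  (generator midpoint: 35 mM)")
print(f"EC10 threshold of the median fit: {ec_fraction(median_fit, 0.1):.1f} mM")
print(
    "\nThe EC50 is the concentration at half-maximal iRatio response; the"
    "\nEC10 is the proposed in vitro analog of the human taste threshold."
)
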