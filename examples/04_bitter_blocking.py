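"""Bitter off-taste of saccharine and its blocking by cyclamate.

Simulates the nine-injection blocking series (blank, sucrose, blank,
saccharine, saccharine+cyclamate, saccharine, cyclamate, blank, sucrose)
over an array carrying the sweet receptor and six bitter receptors, fits
the per-receptor mixed model of log iRatio with spot as a random
intercept, and prints the multiplicative injection effects and the
derived blocking percentages.
"""

from tonguechip import blocking_analysis, preset

traces = preset("fig4_blocking").simulate(seed=1)
result = blocking_analysis(traces)

print("contrast estimates vs blank (multiplicative; * = 95% CI excludes 1):")
for c in result.contrasts:
    if c.receptor.startswith("TAS2R") and c.receptor in ("TAS2R8", "TAS2R31", "TAS2R43"):
        star = "*" if c.significant else " "
        print(
            f"  {c.receptor:8s} {c.treatment:22s} "
            f"{c.estimate:5.2f} [{c.ci_low:.2f}, {c.ci_high:.2f}] {star}"
        )
print("\nblocking percentages (reduction of the excess saccharine effect):")
for receptor in ("TAS2R8", "TAS2R31", "TAS2R43"):
    if receptor in result.blocking:
        print(f"  {receptor:8s} {result.blocking[receptor]:5.1f} %")
print(
    "\nTAS2R43 is blocked almost completely (its mixture effect returns to"
    "\n~1), TAS2R31 partially, TAS2R8 least - the off-taste interaction."
)
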