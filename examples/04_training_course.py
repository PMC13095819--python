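"""A simulated 10-session neurofeedback course with a difficulty ramp.

Each session recalibrates the decoder on a fresh open-loop run, then the
simulated subject attempts six exercises whose state count and temporal
tightness ramp up across sessions.  Prints the per-session composite
difficulty and success rate (successes / attempts); feasibility shows as
high success rates that persist while difficulty grows, with the hardest
late-course exercises finally exceeding the subject's decode latency.
"""

import warnings

import numpy as np

import mibci

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    records = mibci.simulate_training_course(n_sessions=10, erd_depth=0.5,
                                             seed=0)

print("session  difficulty  success_rate")
for rec in records:
    print(f"   t{rec.session_index:<5d} {rec.difficulties[0]:9.2f}"
          f"  {rec.success_rate:11.2f}")
rates = [r.success_rate for r in records]
print(f"median success rate across sessions: {float(np.median(rates)):.2f}")
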