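"""Score freezing across fear-extinction sessions and renewal testing.

Synthetic immobility traces decline in post-tone freezing across five
extinction sessions (per-CS probability decays geometrically); the
renewal test in the conditioning context shows the return of fear.
Freezing = immobility bouts of at least 1 s, scored in the 20-s window
following each tone.
"""

import numpy as np

from cagewalk import session_freezing, simulate_freezing

result = simulate_freezing(
    n_animals=8, extinction_rate=0.7, renewal_gain=2.0, seed=5, n_sessions=5
)

print("mean freezing (% of observations) per extinction session:")
for s, traces in enumerate(result.extinction_sessions, start=1):
    mean = np.mean([session_freezing(tr)[1] for tr in traces])
    print(f"  session {s}: {mean:5.1f} %")

test_b = np.mean([session_freezing(tr)[1] for tr in result.test_b])
test_a = np.mean([session_freezing(tr)[1] for tr in result.test_a])
print(f"test in extinction context B: {test_b:5.1f} %")
print(f"renewal test in conditioning context A: {test_a:5.1f} % "
      "(fear returns in the original context)")
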