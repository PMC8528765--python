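"""Expected recovery curve and dynamic failure boundary for one patient.

Generates a synthetic archival pool, then follows a deteriorating patient
session by session: at each session from 6 on, the nearest improving
archival neighbors are re-selected, the log-time mixed model refit, and the
failure boundary (upper limit of the 90% interval for a new patient)
updated.  The patient's observed impairment crosses the boundary after the
deterioration sets in.
"""

import numpy as np

from otrack.synthetic import CohortConfig, generate_archival
from otrack.trajectory import TrajectoryConfig, dynamic_boundary_sequence

cfg = CohortConfig(archival_n=300, n_therapists=10)
pool = generate_archival(cfg, seed=7)
print(f"archival pool: {len(pool)} patients, "
      f"{len(pool.improving())} with improving courses")

# an index patient who deteriorates from session 10 onward
T = 20
s = np.arange(1, T + 1)
curve = cfg.beta0 + cfg.beta_ln_s * np.log(s) + cfg.beta_T * T \
    + cfg.beta_ln_s_T * np.log(s) * T
observed = curve + 0.7 * (s >= 10)
history = dict(zip(s.tolist(), observed.tolist()))

fb = dynamic_boundary_sequence(0, history, pool, TrajectoryConfig(k=50),
                               total_sessions=T)
print(f"\n{'session':>7} {'observed':>9} {'expected':>9} {'boundary':>9}  status")
for sess, e, u in zip(fb.sessions, fb.expected, fb.upper):
    o = history[sess]
    print(f"{sess:>7} {o:>9.2f} {e:>9.2f} {u:>9.2f}  "
          f"{'ABOVE boundary' if o > u else 'under'}")
print("\nThe boundary is the expected value plus 1.645 prediction SEs; "
      "sessions above it\nwould emit off-track warning signals.")
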