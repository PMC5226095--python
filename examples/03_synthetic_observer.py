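"""Track a target with the synthetic observer and measure the confusion effect.

The observer pursues the target with lag, gain and motor jitter, and
sometimes swaps the identity it believes it is tracking — more often when
the swarm is locally dense. Mean cursor-target distance over the final
4000 ms is the tracking error; it grows with group size.
"""

import numpy as np

from dazzletrack import observer_synth as osn, swarm_sim, tracking_metrics as tm

params = osn.ObserverParams()
print(f"observer: lag {params.lag_ms:.0f} ms, gain {params.pursuit_gain}, "
      f"motor SD {params.motor_sd} px")

for n in (1, 10, 30, 50):
    cfg = swarm_sim.trial_config_for(n, "trinary", "constant", seed=0)
    trajs = swarm_sim.simulate_trials(cfg, range(40))
    rngs = [np.random.default_rng((n, i)) for i in range(40)]
    xy, _ = osn._cursor_batch(trajs, params, rngs)
    idx = trajs[0].sample_indices()
    tgt = np.stack([t.target_series()[1] for t in trajs])
    errs = tm.batch_mean_error(tgt, xy[:, idx], trajs[0].times_ms[idx])
    print(f"n = {n:2d}: mean error {errs.mean():6.1f} px "
          f"(log error {np.log(errs).mean():.2f})")
# Error rises steeply from 1 to 10 items and then decelerates — the
# confusion effect saturating at large group sizes.
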