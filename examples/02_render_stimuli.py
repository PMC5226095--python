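"""Build the three target colorations and rasterize one stimulus frame.

Targets wear either a trinary noise patch (like the background) or a
100%-contrast square-wave grating of wavelength 8 px, oriented orthogonal
or parallel to the square's motion.
"""

import numpy as np

from dazzletrack import pattern_render as pr, swarm_sim

rng = np.random.default_rng(0)

trinary = pr.make_trinary_texture(32, element=2, rng=rng)
print("trinary levels:", sorted(np.unique(trinary.pixels)))

grating = pr.make_grating_texture(32, wavelength=8)
runs = np.diff(np.concatenate([[-1], np.nonzero(np.diff(grating.pixels[0]))[0], [31]]))
print("grating stripe widths (px):", sorted(set(runs.tolist())), "-> wavelength 8")

heading = np.pi / 4  # moving up-right
ortho = pr.orient_texture(grating, heading, "orthogonal")
par = pr.orient_texture(grating, heading, "parallel")
print(f"stripe normal (orthogonal mode): {np.degrees(ortho.orientation):.0f} deg "
      f"= heading; (parallel mode): {np.degrees(par.orientation):.0f} deg = heading + 90")

traj = swarm_sim.simulate_trial(
    swarm_sim.trial_config_for(10, "orthogonal", "constant", seed=3)
)
raster = pr.render_trajectory_frame(traj, frame=100)
pr.save_png(raster, "stimulus_frame.png")
print(f"wrote stimulus_frame.png ({raster.shape[0]}x{raster.shape[1]} px, "
      "10 striped squares on trinary noise)")
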