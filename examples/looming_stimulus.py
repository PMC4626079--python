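"""Build a looming-approach stimulus and inspect its optical variables.

An object of half-size l approaches at speed v; its angular size
Theta = 2*arctan(l/x) expands ever faster until projected collision.  The
lowpass-filtered copies (zeta = 0.95, ~20 ms lag) are what drives the
membrane model.
"""

import numpy as np

from loomsim import ApproachSpec, make_stimulus

spec = ApproachSpec.from_l_over_v(0.03)  # l/v = 30 ms, collision at 0.5 s
trace = make_stimulus(spec, zeta0=0.95, zeta1=0.95)

print(f"half-size l = {spec.half_size_l} m, speed v = {spec.velocity_v} m/s, "
      f"x0 = {spec.initial_distance_x0} m -> t_c = {spec.t_collision} s")
print(f"{len(trace)} samples at dt = {spec.dt_stim*1000:.0f} ms")
for t in (0.0, 0.25, 0.4, 0.45, 0.49, 0.5):
    k = int(round(t / spec.dt_stim))
    print(f"  t={t:4.2f} s  Theta={np.degrees(trace.theta[k]):6.2f} deg  "
          f"Theta_dot={trace.theta_dot[k]:8.2f} rad/s  "
          f"(lowpassed: {np.degrees(trace.theta_lp[k]):6.2f} deg, "
          f"{trace.theta_dot_lp[k]:7.2f} rad/s)")
print("The filtered signals lag the raw ones; the lag is what later breaks")
print("the approach/recession symmetry of the membrane model.")
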