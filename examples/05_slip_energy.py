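"""Step-length geometry and energy conservation of the pendulum gait model.

During stance the body behaves like a spring-loaded inverted pendulum:
step length follows from leg length, leg bending at contact and the
span-leg angle; the energy conserved across a step contact falls as the
step lengthens, which is why long steps need more external work.
"""

import numpy as np

from gaitspeed import conserved_energy, slip_nsl, slip_step_length

l1 = 0.53 * 160.0  # leg length, cm (leg/height ratio 0.53, height 160 cm)
beta0, angle = 0.97, 19.0
ls = slip_step_length(l1, beta0, angle)
nsl = slip_nsl(0.53, beta0, angle)
print(f"leg {l1:.1f} cm, bending {beta0}, span angle {angle} deg "
      f"-> step length {ls:.1f} cm, NSL {nsl:.3f}")

m1, l_l, omega1 = 60.0, 0.9, 2.0  # kg, m, rad/s
for ls_m in np.linspace(0.0, 2 * l_l, 5):
    e = conserved_energy(m1, l_l, omega1, ls_m)
    print(f"  step length {ls_m:4.2f} m -> conserved energy {e:6.1f} J")
print("Energy decreases monotonically from m*l^2*w^2/2 at zero step length "
      "to 0 at the geometric maximum (twice the leg length).")
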