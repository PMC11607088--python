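"""Deformable-mirror modal control: influence matrix, SVD truncation, blink hold.

Builds the synthetic Gaussian influence matrix of the 97-actuator mirror,
inverts it keeping 85 system modes, and runs integral-control updates on a
static error, including the blink-hold behaviour.
"""

import numpy as np

from aoloop import (DMConfig, DMState, LensletGeometry, build_control_matrix,
                    build_influence_matrix, control_update, dm_response)

dm = DMConfig()
geom = LensletGeometry()
influence = build_influence_matrix(dm, geom)
print(f"influence matrix: {influence.shape[0]} slopes x "
      f"{influence.shape[1]} actuators "
      f"(nearest-neighbour coupling {dm.coupling:.0%})")

ctrl = build_control_matrix(influence, n_drop=12)
print(f"control matrix retains {ctrl.retained_modes} of "
      f"{dm.n_actuators} system modes "
      f"(condition number of retained part "
      f"{ctrl.singular_values[0] / ctrl.singular_values[84]:.1f})")

# a target shape within the controllable subspace
rng = np.random.default_rng(0)
_, _, vt = np.linalg.svd(influence, full_matrices=False)
target = vt[:85].T @ rng.normal(0.0, 0.1, 85)

state = DMState(commands=np.zeros(97), previous_commands=np.zeros(97))
for step in range(3):
    slopes = influence @ (state.commands - target)
    residual = np.linalg.norm(slopes)
    blink = step == 1  # simulate a blink on the second frame
    state = control_update(state, slopes, ctrl, gain=0.5, blink=blink)
    held = " (blink: shape held)" if state.held_for_blink else ""
    print(f"step {step}: residual slope norm {residual:.2e}{held}")

settled = dm_response(state, 10 * dm.tau, dm)
moving = dm_response(state, dm.tau, dm)
frac = np.linalg.norm(moving - state.previous_commands) / np.linalg.norm(
    settled - state.previous_commands)
print(f"\nDM transient: {frac:.1%} of the last step applied after one time "
      f"constant ({dm.tau * 1e3:.2f} ms); fully settled well before the "
      f"{dm.t_dm * 1e3:.2f} ms settle window ends.")
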