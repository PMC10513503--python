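"""Single-dipole localization on a noisy synthetic torso phantom.

Generates the reference phantom (128-electrode strip montage, ellipsoidal
torso, 162 candidate source vertices on the ventricular surface), simulates
a 30 ms ectopic-beat map at 20 dB SNR from a known vertex, and localizes the
source by scanning the relative residual error over all candidates.
"""

import numpy as np

from ecgidipole import (
    PhantomSpec,
    assemble_bem,
    build_transfer_stack,
    localization_error,
    make_phantom,
    scan_positions,
    simulate_pvc_map,
)

spec = PhantomSpec(true_vertex=42, snr_db=20.0, seed=3)
vc, heart = make_phantom(spec)
system = assemble_bem(vc)
stack = build_transfer_stack(system, heart)
bsp, truth, _ = simulate_pvc_map(vc, heart, spec, system=system)

sol = scan_positions(stack, bsp)
le = localization_error(sol.position, truth)

print(f"phantom: M={stack.n_electrodes} electrodes, J={stack.n_positions} candidates, SNR=20 dB")
print(f"true origin:      vertex {spec.true_vertex} at {np.round(truth, 1).tolist()} mm")
print(f"estimated origin: vertex {sol.position_index} at {np.round(sol.position, 1).tolist()} mm")
print(f"minimum RRE = {sol.rre_min:.4f} at sample t* = {sol.t_star}")
print(f"localization error = {le:.2f} mm  (0 means the exact candidate vertex was recovered)")
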