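"""From a hyperpolarizability tensor to the measurable HRS response.

beta_HRS = sqrt(<beta_ZZZ^2> + <beta_ZXX^2>) is rotation-invariant, so
it characterizes a freely tumbling molecule in solution.  The closed
form is contracted from exact SO(3) moment tensors; a brute-force Euler
angle quadrature double-checks it.
"""

import numpy as np

from nloswitch import (
    BetaTensor,
    is_effectively_centrosymmetric,
    numerical_orientational_average,
    orientational_invariants,
)

# A one-dimensional charge-transfer chromophore: only beta_zzz nonzero.
flat = [0.0] * 26 + [1000.0]
tensor = BetaTensor.from_flat(flat)
inv = orientational_invariants(tensor)
print(f"<b2_ZZZ> = {inv.mean_sq_ZZZ:10.1f} a.u.^2   (b^2/7)")
print(f"<b2_ZXX> = {inv.mean_sq_ZXX:10.1f} a.u.^2   (b^2/35)")
print(f"beta_HRS = {inv.beta_hrs:10.1f} a.u.     (sqrt(6/35) x 1000)")

# The quadrature oracle converges to the same invariants.
num = numerical_orientational_average(tensor, 12, 16, 12)
print(f"quadrature beta_HRS = {num.beta_hrs:.4f} a.u.")

# Rotating the molecular frame changes components, not the response.
rng = np.random.default_rng(0)
from scipy.spatial.transform import Rotation

rot = Rotation.random(random_state=rng).as_matrix()
print(f"after a random rotation: {orientational_invariants(tensor.rotated(rot)).beta_hrs:.4f} a.u.")

# Centrosymmetric species have a null tensor, hence zero response; the
# 10 a.u. threshold flags near-centrosymmetric OFF states.
zero = orientational_invariants(BetaTensor.zero())
print(f"centrosymmetric state: beta_HRS = {zero.beta_hrs} a.u., "
      f"effectively centrosymmetric: {is_effectively_centrosymmetric(zero.beta_hrs)}")
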