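"""The Cartesian trick: frames, superposition, and std conversion.

Shows why the mixture never sees raw angles: a chi quadruple is
superposed into a canonical frame where the dihedral is atan2(y, x) of
the fourth atom, and a Gaussian peak's spread converts back to an
angular std via the one-sigma ellipse (closed form arctan(s/r) in the
isotropic case).
"""

import numpy as np

import rotafit as rf

# a butane-like gauche quadruple, then rigidly moved in space
quad = np.array([
    [1.44, 0.00, -0.51],   # a
    [0.00, 0.00, 0.00],    # b
    [0.00, 0.00, 1.53],    # c
    [0.7225, 1.2514, 2.04],  # d at +60 degrees

])
rot = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
rot *= np.sign(np.linalg.det(rot))
moved = quad @ rot.T + np.array([5.0, -3.0, 2.0])

frame = rf.ReferenceFrame.from_quadruple(moved)
fourth = rf.superpose_quadruple(moved, frame)
print(f"dihedral after arbitrary rigid motion: "
      f"{rf.dihedral_from_point(fourth, frame):+.3f} deg (expected +60)")

# std conversion: isotropic spread 0.2 A at radius 1.5 A
mean = [1.5, 0.0, 2.0]
ang, std = rf.cartesian_peak_to_dihedral(mean, [0.2, 0.2, 0.3], std_floor=0.0)
print(f"converted well: mean {ang:.1f} deg, std {std:.3f} deg "
      f"(closed form {np.degrees(np.arctan(0.2 / 1.5)):.3f})")
# The frame makes dihedral statistics a plain Euclidean problem, so
# Gaussian mixtures apply without wrap-around artifacts.
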