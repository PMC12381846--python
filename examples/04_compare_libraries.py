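"""Compare two rotamer libraries: well matching and divergence.

Builds a small library, perturbs one well by 10 degrees, and reports the
matched-well deltas plus the total variation distance between the
density vectors.
"""

import rotafit as rf
from rotafit.pipeline import compare_distributions

wells_a = [
    rf.DihedralWell((-60.0, 180.0), (9.0, 10.0), 0.55, (1, 3)),
    rf.DihedralWell((60.0, 60.0), (8.0, 8.0), 0.30, (2, 2)),
    rf.DihedralWell((180.0, -60.0), (10.0, 9.0), 0.15, (3, 1)),
]
lib_a = rf.RotamerLibrary(residue_code="AAA", wells=wells_a, n_chi=2)

wells_b = [
    rf.DihedralWell((-50.0, 180.0), (9.0, 10.0), 0.50, (1, 3)),  # chi1 off by 10
    rf.DihedralWell((60.0, 60.0), (8.0, 8.0), 0.35, (2, 2)),
    rf.DihedralWell((180.0, -60.0), (10.0, 9.0), 0.15, (3, 1)),
]
lib_b = rf.RotamerLibrary(residue_code="BBB", wells=wells_b, n_chi=2)

result = compare_distributions(lib_a, lib_b)
print(f"matched wells: {result['n_matched']}")
for row in result["matched_wells"]:
    print(f"  {row['a_means']} vs {row['b_means']}: "
          f"mean delta {row['mean_delta']:.1f} deg, "
          f"p {row['density_a']:.2f} vs {row['density_b']:.2f}")
print(f"total variation distance: {result['total_variation']:.3f}")
# Matching is order-free (greedy nearest in circular distance), so well
# permutations cost nothing; the 10-degree shift and the 0.05 density
# transfer show up directly.
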