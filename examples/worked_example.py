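"""Build the three-spot reference LDM and score it.

Three 5x5 exposure templates are stamped at centroids (7,5), (5,8), (9,7)
of a 13x12 target grid (1-based; 0-based internally) with a 1 mm/pixel
conversion ratio, then the four performance indices are computed.
"""

import numpy as np

from ldmkit import (
    compute_indices,
    consecutive_distances,
    coverage_areas,
    nearest_neighbor_distances,
    synthesize_ldm,
)

spots = [(6.0, 4.0), (4.0, 7.0), (8.0, 6.0)]  # 0-based (row, col)
ldm = synthesize_ldm(spots, dims=(13, 12), template_side=5)

print("Exposure-count grid (alpha = max redundancy):")
print(ldm.grid)

profile = coverage_areas(ldm)
print(f"\nA0 = {profile.A0} target pixels; A_k (pixels covered >= k) = {profile.A.tolist()}")
print(f"d_c = {np.round(consecutive_distances(spots), 2).tolist()}  (consecutive-spot distances, px)")
print(f"d_n = {np.round(nearest_neighbor_distances(spots), 2).tolist()}  (nearest-neighbour distances, px)")

idx = compute_indices(ldm, 1.0)
print(f"\ndelta0  = {idx.delta0:6.2f} %   untreated target area (omission error)")
print(f"delta_z = {idx.deltaz:6.2f} %   redundantly treated area (overlap error)")
print(f"mu      = {idx.mu_mm:6.2f} mm  mean consecutive-spot distance")
print(f"upsilon = {idx.upsilon_ratio:6.2f}     nearest-neighbour CV (randomness of delivery)")
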