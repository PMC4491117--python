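"""Overlap rates and Hausdorff distance on hand-enumerable toy masks."""

import numpy as np

from pectseg import fn_rate, fp_rate, hausdorff, total_mismatch
from pectseg.image_io import PectoralRegion


def region(pixels, shape=(10, 10)):
    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        mask[r, c] = True
    return PectoralRegion(mask)


truth = region([(0, c) for c in range(10)])            # |R| = 10
detected = region([(0, c) for c in range(9)]           # misses 1 truth pixel
                  + [(5, 5), (6, 6)])                  # adds 2 false pixels

print(f"FP rate    : {fp_rate(detected, truth):.1f}%   (2 extra / 10 truth)")
print(f"FN rate    : {fn_rate(detected, truth):.1f}%   (1 missed / 10 truth)")
print(f"total rate : {total_mismatch(detected, truth):.1f}%   (= FP + FN exactly)")

print(f"\nHausdorff {{(0,0)}} vs {{(3,4)}}        : "
      f"{hausdorff([(0, 0)], [(3, 4)]):.1f} px  (3-4-5 triangle)")
print(f"Hausdorff same, at 0.4 mm/pixel    : "
      f"{hausdorff([(0, 0)], [(3, 4)], spacing_mm=0.4):.1f} mm")
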