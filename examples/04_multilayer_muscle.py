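"""Multi-layer pectoral muscles: the normal case and the failure mode.

Some muscles present several nested edges.  With the usual dimmer inner
layer the detector finds the outermost (anatomical) boundary.  When the
inner layer is much brighter than a weak outer edge, the intensity
tie-break locks onto the inner edge instead — the documented limitation of
intensity-guided selection.
"""

import numpy as np

from pectseg import PhantomSpec, detect_pectoral, generate_phantom


def boundary_errors(result, truth_polyline):
    d, t = result.boundary.column_at(), truth_polyline.column_at()
    common = sorted(set(d) & set(t))
    vs_outer = np.mean([abs(d[r] - t[r]) for r in common])
    vs_inner = np.mean([abs(d[r] - 0.55 * t[r]) for r in common])
    return vs_outer, vs_inner


for label, spec in [
    ("dim inner layer (normal case)",
     PhantomSpec(multilayer=True, inner_contrast=0.5)),
    ("bright inner layer, weak outer edge (failure mode)",
     PhantomSpec(multilayer=True, muscle_base=140, inner_contrast=5.0,
                 gradient_strength=10.0)),
]:
    m, _, tpoly = generate_phantom(spec)
    result = detect_pectoral(m)
    vs_outer, vs_inner = boundary_errors(result, tpoly)
    locked = "outer (correct)" if vs_outer < vs_inner else "INNER (failure)"
    print(f"{label}")
    print(f"  selection rule: {result.seed_rule}")
    print(f"  mean |error| vs outer edge: {vs_outer:6.1f} px, "
          f"vs inner edge: {vs_inner:6.1f} px  ->  locked onto {locked}\n")

print("The inner edge sits at 55% of the outer boundary column; whichever "
      "error is smaller tells which edge the detector followed.")
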