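"""Measure wedge-ROI cortical magnification on a synthetic V1.

Plants a cortical magnification pattern with a 60% horizontal-vertical
anisotropy (HVA) and 25% vertical-meridian asymmetry (VMA), builds both
hemisphere meshes, runs the distance-map wedge-ROI measurement, and
compares the recovered asymmetry indices with the planted ones.
"""

import cortmag as cm

model = cm.MagnificationModel.from_asymmetries(hva=60.0, vma=25.0)
print(f"angular modulation amplitudes: alpha={model.alpha:.3f} "
      f"(HVA), gamma={model.gamma:.3f} (VMA)")

per_hemi = {}
for hemi in ("left", "right"):
    mesh = cm.make_synthetic_hemisphere(model, hemisphere=hemi)
    areas, _ = cm.measure_wedge_areas(mesh)
    per_hemi[hemi] = areas
    print(f"{hemi} hemisphere: {mesh.n_vertices} vertices, "
          f"V1(0-8deg) = {cm.v1_total_area(mesh):.0f} mm^2")

combined = cm.combine_meridian_areas(per_hemi["left"], per_hemi["right"])
for k in ("HM", "UVM", "LVM", "VM"):
    print(f"  wedge {k:3s}: {combined[k]:7.1f} mm^2")

hva = cm.hva_index(combined["HM"], combined["VM"])
vma = cm.vma_index(combined["LVM"], combined["UVM"])
print(f"measured HVA {hva:.1f} (planted 60), VMA {vma:.1f} (planted 25)")
print("Each wedge covers +/-15 deg of polar angle, 1-8 deg eccentricity; "
      "area differences between wedges index cortical magnification.")
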