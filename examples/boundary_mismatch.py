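"""Quantify mismatch between intensity- and kinetics-defined lesion extents.

Builds a phantom whose junction ring shares the skin's baseline intensity
but the core's fast bleaching: the lesion is invisible to the AF0 map beyond
the core, while the tau map sees core + junction.  The area ratio > 1 and
Dice < 1 quantify how far the kinetic lesion extends past the AF-defined
one — the package's headline boundary-mismatch measurement.
"""

import pbmap
from pbmap.boundary import boundary_comparison_from_maps

spec = pbmap.PhantomSpec(
    height=96, width=96, seed=5, junction_width=10.0,
    # junction: skin-like intensity (A + C = 190) but tumor-like tau = 6 s
    junction=pbmap.RegionKinetics(120.0, 6.0, 70.0, 8.0, 0.8, 5.0))
stack, truth = pbmap.generate_phantom(spec)
maps = pbmap.fit_stack(stack)

m_af, m_kin, cmp = boundary_comparison_from_maps(maps, kinetic="tau")
core_px = (truth.region_mask == pbmap.CORE).sum()
lesion_px = core_px + (truth.region_mask == pbmap.JUNCTION).sum()
print(f"AF0-defined lesion area:     {cmp.area_af:5d} px  (true core: {core_px} px)")
print(f"tau-defined lesion area:     {cmp.area_kinetic:5d} px  (true core+junction: {lesion_px} px)")
print(f"area ratio (kinetic / AF):   {cmp.area_ratio:.2f}")
print(f"Dice overlap:                {cmp.dice:.2f}")
print(f"mean boundary offset:        {cmp.mean_boundary_offset:.1f} px")
print("The kinetics-defined lesion strictly contains the intensity-defined "
      "one: bleaching contrast extends past the visible AF boundary.")
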