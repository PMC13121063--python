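"""Fit the single-exponential bleaching model per pixel and check recovery.

Generates a noisy 8-bit phantom, fits I(t) = A exp(-t/tau) + C at every
pixel, and compares fitted region-mean parameters with the ground truth.
The relative errors show what per-pixel fitting recovers at the default
camera noise level; the validity fraction counts pixels whose fit converged
with acceptable parameters.
"""

import numpy as np

import pbmap

spec = pbmap.PhantomSpec(height=96, width=96, seed=1)
stack, truth = pbmap.generate_phantom(spec)
maps = pbmap.fit_stack(stack)

print(f"valid-fit fraction: {maps.mask.mean():.3f} "
      f"(programmed defect fraction {spec.defect_fraction})")
for label, name in ((pbmap.SKIN, "skin"), (pbmap.CORE, "core")):
    sel = truth.region_mask == label
    ok = sel & maps.mask
    for pname, fitted, true in (("A", maps.A, truth.true_A_map),
                                ("tau", maps.tau, truth.true_tau_map),
                                ("C", maps.C, truth.true_C_map)):
        f, t = fitted[ok].mean(), true[sel].mean()
        print(f"{name:5s} {pname:3s} fitted {f:7.2f}  true {t:7.2f}  "
              f"rel err {abs(f - t) / t:6.1%}")
print("Region-mean kinetics are recovered to a few percent despite 8-bit "
      "quantization and shot + read noise.")
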