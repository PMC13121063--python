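"""Render a synthetic photobleaching phantom and inspect its ground truth.

Builds the sporadic-BCC preset at reduced size, renders the 20-frame 8-bit
stack, and prints the programmed per-region decay parameters next to the
region pixel counts.  The printed (A, tau, C) means are the generating
values every downstream stage is validated against.
"""

import numpy as np

import pbmap

presets = pbmap.three_class_presets(height=128, width=128, seed=0)
spec = presets["sporadic_bcc"]
stack, truth = pbmap.generate_phantom(spec)

print(f"stack: {stack.n_frames} frames of {stack.shape[0]}x{stack.shape[1]} px, "
      f"dtype {stack.data.dtype}, t = 0..{stack.times[-1]:.0f} s")
names = {pbmap.SKIN: "skin", pbmap.JUNCTION: "junction",
         pbmap.CORE: "core", pbmap.DEFECT: "defect"}
for label, name in names.items():
    sel = truth.region_mask == label
    if label == pbmap.DEFECT:
        print(f"{name:9s} {sel.sum():6d} px (unfittable by construction)")
        continue
    print(f"{name:9s} {sel.sum():6d} px   "
          f"A = {truth.true_A_map[sel].mean():6.1f}  "
          f"tau = {truth.true_tau_map[sel].mean():5.2f} s  "
          f"C = {truth.true_C_map[sel].mean():6.1f}")
print("A tumor core bleaches faster (smaller tau) and is darker at t = 0 "
      "(smaller A + C) than the surrounding skin.")
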