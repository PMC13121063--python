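# pbmap — autofluorescence photobleaching kinetics mapping

`pbmap` turns a time-lapse autofluorescence (AF) image sequence of a skin
lesion into spatially resolved photobleaching parameter maps and derived
lesion analyses. It is aimed at biomedical-imaging researchers working on
non-invasive skin tumor characterization: AF intensity alone is confounded
by melanin, keratin, vasculature and surface scattering, whereas the
*kinetics* of AF decay under continuous excitation carry independent
functional contrast.

Under continuous narrow-band excitation (405 nm in the emulated device),
endogenous fluorophores bleach, and each pixel's intensity time course is
well described by a single-exponential decay:

```
I(t) = A · exp(−t / τ) + C
```

* **A** — bleaching amplitude (the bleachable signal fraction), intensity units
* **τ** — decay constant, seconds; smaller τ means faster photobleaching
* **C** — residual (non-bleaching) component, intensity units
* **AF₀** — the initial intensity image at t = 0 s

The pipeline: load a frame stack (multi-page TIFF or PNG sequence; the AF
signal is taken from the G channel of RGB input) → rigid frame-to-frame
stabilization → per-pixel bounded nonlinear least-squares fitting into
AF₀/A/τ/C/error maps with a validity mask → SLIC superpixel segmentation
and core / junction / skin designation by z-score against the surrounding
skin → nonparametric cohort statistics (Levene, Kruskal–Wallis,
Dunn–Bonferroni on lesion-level region means) → quantification of the
mismatch between intensity-defined and kinetics-defined lesion boundaries
(area ratio, Dice, boundary offset).

Because clinical AF photobleaching stacks are not publicly deposited, the
package ships a phantom generator (`pbmap.phantom`) that renders synthetic
acquisitions with known per-pixel ground truth — region-wise exponential
kinetics, shot + read noise, 8-bit quantization, rigid drift, and
unfittable defect pixels — including presets encoding the qualitative
contrasts of three tumor classes (sporadic BCC, NBCCS-associated BCC, SCC).
All preset numbers are simulator inventions that encode orderings, not
measured tissue values.

## Worked example

Fit a noisy 8-bit phantom and compare recovered region kinetics with the
generating truth (`examples/fit_decay_maps.py`):

```python
import pbmap

spec = pbmap.PhantomSpec(height=96, width=96, seed=1)
stack, truth = pbmap.generate_phantom(spec)
maps = pbmap.fit_stack(stack)
```

Output:

```
valid-fit fraction: 0.988 (programmed defect fraction 0.01)
skin  A   fitted  121.85  true  119.74  rel err   1.8%
skin  tau fitted   10.32  true    9.93  rel err   3.9%
skin  C   fitted   67.77  true   69.73  rel err   2.8%
core  A   fitted   60.63  true   60.00  rel err   1.0%
core  tau fitted    6.43  true    6.26  rel err   2.6%
core  C   fitted   39.27  true   39.70  rel err   1.1%
```

The valid-fit fraction matches the programmed 1% defect rate (defect pixels
carry an all-zero sentinel and are excluded from every downstream step),
and region-mean kinetics come back to within a few percent at realistic
noise. The boundary-mismatch example (`examples/boundary_mismatch.py`)
builds a lesion whose junction shares the skin's baseline intensity but the
core's fast τ, and prints

```
AF0-defined lesion area:       984 px  (true core: 953 px)
tau-defined lesion area:      2091 px  (true core+junction: 2123 px)
area ratio (kinetic / AF):   2.12
Dice overlap:                0.64
```

— the kinetics-defined lesion strictly contains the intensity-defined one,
the package's headline measurement. Each script in `examples/` demonstrates
one capability (simulation, fitting, stabilization, segmentation, cohort
statistics, boundary analysis) and prints what the numbers mean.

A thin CLI wraps the same library calls:

```bash
pbmap simulate --preset sporadic_bcc --seed 1 --out phantom/
pbmap fit --input phantom/stack.tif --interval 1.0 --out maps/
pbmap segment --maps maps/ --out regions/
pbmap boundary --maps maps/ --kinetic tau --out boundary/
pbmap run --preset scc --seed 2 --size 96 --out run/   # full pipeline + manifest
```

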