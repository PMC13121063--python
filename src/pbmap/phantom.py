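"""Synthetic time-lapse autofluorescence phantoms with known decay parameters.

Clinical photobleaching stacks are not publicly deposited, so every stage of
the pipeline is exercised against simulated lesions whose per-pixel ground
truth is known.  Each pixel follows the single-exponential bleaching model

    I(t) = A * exp(-t / tau) + C

with region-specific (A, tau, C): an elliptical tumor core, a junction
annulus obtained by dilating the core, and surrounding skin.  On top of the
noiseless kinetics the generator can add signal-dependent shot noise and
additive read noise (a standard CMOS camera model), rigid per-frame drift,
8-bit quantization, and a fraction of unfittable defect pixels (constant
zero or saturated, emulating specular glare and dead sensels).

The default tissue-class presets encode only the qualitative contrasts
observed clinically — tumors darker than skin, sporadic BCC and SCC
bleaching faster than skin, NBCCS-associated BCC kinetics near skin, SCC the
most heterogeneous — with invented numbers; no measured values exist for
them and they must not be read as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stack_io import FrameStack, save_stack

__all__ = [
    "RegionKinetics",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "three_class_presets",
    "write_phantom",
    "SKIN",
    "JUNCTION",
    "CORE",
    "DEFECT",
]

# region_mask label values
SKIN, JUNCTION, CORE, DEFECT = 0, 1, 2, 3


@dataclass
class RegionKinetics:
    """Mean and spatial SD of (A, tau, C) for one tissue region.

    ``A`` and ``C`` are in intensity units (8-bit counts by default), ``tau``
    in seconds.  The spatial SD produces smooth pixel-to-pixel parameter
    variation within the region; larger SDs model intralesional
    heterogeneity.
    """

    A: float
    tau: float
    C: float
    A_sd: float = 0.0
    tau_sd: float = 0.0
    C_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"region tau mean must be > 0, got {self.tau}")
        if self.A < 0 or self.C < 0:
            raise ValueError("region A and C means must be >= 0")
        if min(self.A_sd, self.tau_sd, self.C_sd) < 0:
            raise ValueError("region parameter SDs must be >= 0")

    @property
    def af0(self) -> float:
        """Mean initial intensity A + C (the model value at t = 0)."""
        return self.A + self.C


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition.

    Defaults mirror the acquisition protocol of the imaging device being
    emulated: 466 x 448 px frames at 1 frame/s over 20 s, 8-bit output.
    """

    height: int = 466
    width: int = 448
    n_frames: int = 20
    frame_interval: float = 1.0
    # core ellipse: center (row, col), semi-axes (row, col), rotation in degrees
    core_center: tuple[float, float] | None = None   # None -> image center
    core_axes: tuple[float, float] | None = None     # None -> (H/6, W/5)
    core_rotation_deg: float = 0.0
    junction_width: float = 8.0
    skin: RegionKinetics = field(default_factory=lambda: RegionKinetics(120.0, 10.0, 70.0, 8.0, 1.0, 5.0))
    junction: RegionKinetics | None = None           # None -> core/skin midpoint
    core: RegionKinetics = field(default_factory=lambda: RegionKinetics(60.0, 6.0, 40.0, 8.0, 0.8, 5.0))
    shot_noise_scale: float = 0.5    # noise SD contribution = scale * sqrt(signal)
    read_noise_sd: float = 2.0       # additive Gaussian SD, intensity units
    drift: np.ndarray | None = None  # (T, 2) array of per-frame (dy, dx), pixels
    defect_fraction: float = 0.01
    bit_depth: int | None = 8        # None -> float output, no quantization
    param_smoothing_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"height/width must be positive, got {self.height}x{self.width}")
        if self.n_frames < 3:
            raise ValueError(f"n_frames must be >= 3, got {self.n_frames}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not 0.0 <= self.defect_fraction <= 1.0:
            raise ValueError(f"defect_fraction must lie in [0, 1], got {self.defect_fraction}")
        if self.shot_noise_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.junction_width < 0:
            raise ValueError(f"junction_width must be >= 0, got {self.junction_width}")
        if self.core_center is None:
            self.core_center = (self.height / 2.0, self.width / 2.0)
        if self.core_axes is None:
            self.core_axes = (self.height / 6.0, self.width / 5.0)
        if min(self.core_axes) <= 0:
            raise ValueError(f"core_axes must be positive, got {self.core_axes}")
        cy, cx = self.core_center
        ry, rx = self.core_axes
        reach = max(ry, rx) + self.junction_width
        if (cy - reach < 0 or cy + reach > self.height
                or cx - reach < 0 or cx + reach > self.width):
            raise ValueError(
                "core_center/core_axes: lesion geometry (core + junction annulus) "
                f"exceeds the {self.height}x{self.width} image bounds")
        if self.junction is None:
            s, c = self.skin, self.core
            self.junction = RegionKinetics(
                (s.A + c.A) / 2, (s.tau + c.tau) / 2, (s.C + c.C) / 2,
                (s.A_sd + c.A_sd) / 2, (s.tau_sd + c.tau_sd) / 2, (s.C_sd + c.C_sd) / 2)
        if self.drift is not None:
            self.drift = np.asarray(self.drift, dtype=float)
            if self.drift.shape != (self.n_frames, 2):
                raise ValueError(
                    f"drift must have shape (n_frames, 2) = ({self.n_frames}, 2), "
                    f"got {self.drift.shape}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if d["drift"] is not None:
            d["drift"] = np.asarray(d["drift"]).tolist()
        return d


@dataclass
class PhantomGroundTruth:
    """True per-pixel parameter maps and region labels emitted alongside a phantom."""

    true_A_map: np.ndarray
    true_tau_map: np.ndarray
    true_C_map: np.ndarray
    region_mask: np.ndarray  # values in {SKIN, JUNCTION, CORE, DEFECT}

    def region_pixels(self, label: int) -> np.ndarray:
        return self.region_mask == label

    def region_mean(self, label: int, which: str) -> float:
        m = {"A": self.true_A_map, "tau": self.true_tau_map, "C": self.true_C_map}[which]
        return float(m[self.region_mask == label].mean())


def _ellipse_mask(h: int, w: int, center, axes, rotation_deg: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ry, rx = axes
    th = np.deg2rad(rotation_deg)
    dy, dx = yy - cy, xx - cx
    u = np.cos(th) * dy + np.sin(th) * dx
    v = -np.sin(th) * dy + np.cos(th) * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sd: float, sigma: float) -> np.ndarray:
    """Spatially correlated zero-mean Gaussian field with pointwise SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma)
        noise /= max(noise.std(), 1e-12)
    return sd * noise


def generate_phantom(spec: PhantomSpec) -> tuple[FrameStack, PhantomGroundTruth]:
    """Render a synthetic photobleaching stack and its ground truth.

    Deterministic given ``spec.seed``.  Frame k carries timestamp
    ``k * frame_interval``.  Before noise, drift and quantization, every
    non-defect pixel's curve is exactly ``A exp(-t/tau) + C`` with the
    ground-truth per-pixel parameters; defect pixels are constant zero or
    constant saturated across all frames.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    core_mask = _ellipse_mask(h, w, spec.core_center, spec.core_axes, spec.core_rotation_deg)
    if spec.junction_width > 0:
        n_iter = int(np.ceil(spec.junction_width))
        struct = ndimage.generate_binary_structure(2, 1)
        dilated = ndimage.binary_dilation(core_mask, struct, iterations=n_iter)
    else:
        dilated = core_mask
    junction_mask = dilated & ~core_mask

    region_mask = np.full((h, w), SKIN, dtype=np.int16)
    region_mask[junction_mask] = JUNCTION
    region_mask[core_mask] = CORE

    A = np.empty((h, w))
    tau = np.empty((h, w))
    C = np.empty((h, w))
    for label, params in ((SKIN, spec.skin), (JUNCTION, spec.junction), (CORE, spec.core)):
        sel = region_mask == label
        A[sel] = params.A + _smooth_field(rng, (h, w), params.A_sd, spec.param_smoothing_sigma)[sel]
        tau[sel] = params.tau + _smooth_field(rng, (h, w), params.tau_sd, spec.param_smoothing_sigma)[sel]
        C[sel] = params.C + _smooth_field(rng, (h, w), params.C_sd, spec.param_smoothing_sigma)[sel]
    np.clip(A, 0.0, None, out=A)
    np.clip(C, 0.0, None, out=C)
    np.clip(tau, 1e-2, None, out=tau)  # spatial variation must not push tau <= 0

    # defect pixels: constant 0 (specular-saturation compensated zeros) or saturated
    defects = rng.random((h, w)) < spec.defect_fraction
    defect_kind_sat = rng.random((h, w)) < 0.5  # among defects: half saturated
    region_mask[defects] = DEFECT

    times = spec.times
    decay = np.exp(-times[:, None, None] / tau[None, :, :])
    stack = A[None, :, :] * decay + C[None, :, :]

    if spec.shot_noise_scale > 0:
        stack = stack + rng.standard_normal(stack.shape) * (spec.shot_noise_scale * np.sqrt(np.clip(stack, 0, None)))
    if spec.read_noise_sd > 0:
        stack = stack + rng.standard_normal(stack.shape) * spec.read_noise_sd

    if spec.drift is not None and np.any(spec.drift):
        for k in range(spec.n_frames):
            dy, dx = spec.drift[k]
            if dy or dx:
                stack[k] = ndimage.shift(stack[k], (dy, dx), order=1, mode="nearest")

    sat_value = float(2**spec.bit_depth - 1) if spec.bit_depth is not None else 255.0
    stack[:, defects] = 0.0
    stack[:, defects & defect_kind_sat] = sat_value

    if spec.bit_depth is not None:
        stack = np.clip(np.floor(stack + 0.5), 0, sat_value).astype(np.uint8 if spec.bit_depth <= 8 else np.uint16)

    frame_stack = FrameStack(data=stack, times=times, source_channel="gray", bit_depth=spec.bit_depth)
    truth = PhantomGroundTruth(true_A_map=A, true_tau_map=tau, true_C_map=C, region_mask=region_mask)
    return frame_stack, truth


def three_class_presets(height: int = 466, width: int = 448, seed: int = 0,
                        **overrides) -> dict[str, PhantomSpec]:
    """Phantom presets for the three tumor classes studied clinically.

    The programmed kinetics encode the qualitative contrasts only:

    - all cores darker than skin at t = 0 (lower A + C),
    - sporadic BCC: moderately faster bleaching than skin (tau 6 s vs 10 s),
    - NBCCS-associated BCC: tau 9.5 s, nearly indistinguishable from skin,
    - SCC: steepest decay (tau 4 s) and the largest intra-core parameter
      SDs (heterogeneity).

    The absolute numbers are simulator inventions — the clinical work reports
    no tissue-class parameter values.
    """
    skin = RegionKinetics(120.0, 10.0, 70.0, 8.0, 1.0, 5.0)
    cores = {
        "sporadic_bcc": RegionKinetics(60.0, 6.0, 40.0, 8.0, 0.8, 5.0),
        "nbccs_bcc": RegionKinetics(55.0, 9.5, 40.0, 6.0, 0.7, 4.0),
        "scc": RegionKinetics(65.0, 4.0, 45.0, 25.0, 2.0, 15.0),
    }
    presets = {}
    for name, core in cores.items():
        presets[name] = PhantomSpec(height=height, width=width, skin=skin, core=core,
                                    seed=seed, **overrides)
    return presets


def write_phantom(stack: FrameStack, truth: PhantomGroundTruth, spec: PhantomSpec,
                  out_dir: str | Path, rgb: bool = False) -> Path:
    """Write a phantom to disk: stack TIFF, float32 ground-truth maps, JSON spec."""
    import json
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_stack(stack, out_dir / "stack.tif", rgb=rgb)
    tifffile.imwrite(out_dir / "true_A.tif", truth.true_A_map.astype(np.float32))
    tifffile.imwrite(out_dir / "true_tau.tif", truth.true_tau_map.astype(np.float32))
    tifffile.imwrite(out_dir / "true_C.tif", truth.true_C_map.astype(np.float32))
    tifffile.imwrite(out_dir / "region_mask.tif", truth.region_mask.astype(np.uint8))
    with open(out_dir / "phantom_spec.json", "w") as fh:
        json.dump(spec.to_jsonable(), fh, indent=2, sort_keys=True)
    return out_dir
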