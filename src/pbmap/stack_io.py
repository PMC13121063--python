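"""Reading and writing time-lapse frame stacks and fitted parameter maps.

The raw input of the pipeline is an ordered sequence of frames acquired at a
fixed frame rate under continuous excitation.  Camera output is 8-bit RGB;
the autofluorescence signal is carried by the green (G) channel, so RGB
inputs are reduced to their G plane on load — a pure projection, with no
rescaling or gamma applied.  Fitted parameter maps are exported as 32-bit
float single-page TIFFs plus a JSON manifest recording provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "FrameStack",
    "ParameterMaps",
    "load_stack",
    "save_stack",
    "save_maps",
    "load_maps",
]

_FRAME_EXTS = {".png", ".tif", ".tiff"}


@dataclass
class FrameStack:
    """An ordered T x H x W intensity stack with its acquisition time base.

    Parameters
    ----------
    data:
        Array of shape (T, H, W), non-negative intensities.
    times:
        Length-T vector of seconds, strictly increasing, ``times[0] == 0``.
    source_channel:
        ``"G"`` if extracted from the green plane of RGB input, else ``"gray"``.
    bit_depth:
        Bit depth of the stored intensities (8 for camera data); ``None`` for
        floating-point synthetic stacks.
    valid_mask:
        Optional (H, W) boolean mask of pixels that remained inside the field
        of view (stabilization marks departing pixels invalid here).
    """

    data: np.ndarray
    times: np.ndarray
    source_channel: str = "gray"
    bit_depth: int | None = 8
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 3:
            raise ValueError("fewer than 3 frames")
        if self.times.shape != (self.data.shape[0],):
            raise ValueError("times length must equal frame count")
        if self.times[0] != 0:
            raise ValueError("times[0] must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.issubdtype(self.data.dtype, np.integer) and self.bit_depth is not None:
            hi = 2**self.bit_depth - 1
            if self.data.min() < 0 or self.data.max() > hi:
                raise ValueError(f"integer intensities must lie in [0, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ParameterMaps:
    """Co-registered 2-D maps produced by per-pixel decay fitting.

    ``af0`` is the raw frame at t = 0 s; ``A``, ``tau``, ``C`` are the fitted
    model parameters; ``error`` is the residual sum of squares.  ``mask`` is
    True where the fit converged with acceptable parameters; everywhere else
    the parameter maps carry the sentinel value 0.
    """

    af0: np.ndarray
    A: np.ndarray
    tau: np.ndarray
    C: np.ndarray
    error: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.af0, self.A, self.tau, self.C, self.error, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.af0.shape

    def map_by_name(self, name: str) -> np.ndarray:
        table = {"AF0": self.af0, "A": self.A, "tau": self.tau, "C": self.C, "error": self.error}
        if name not in table:
            raise KeyError(f"unknown map {name!r}; expected one of {sorted(table)}")
        return table[name]


def _numeric_sort_key(p: Path):
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else -1, p.name)


def _to_green(frame: np.ndarray, path) -> tuple[np.ndarray, str]:
    if frame.ndim == 2:
        return frame, "gray"
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., 1], "G"
    raise ValueError(f"unsupported frame shape {frame.shape} in {path}")


def load_stack(path: str | Path, frame_interval: float = 1.0) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of frames.

    RGB frames are reduced to the G channel; grayscale frames pass through
    unchanged.  Frame k receives timestamp ``k * frame_interval`` with the
    first frame at t = 0.

    Parameters
    ----------
    path:
        Multi-page TIFF file, or a directory of identically sized PNG/TIFF
        frames whose names order numerically.
    frame_interval:
        Seconds between consecutive frames (must be > 0).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    path = Path(path)
    frames: list[np.ndarray] = []
    channel = "gray"
    if path.is_dir():
        files = sorted((p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS),
                       key=_numeric_sort_key)
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # pragma: no cover - depends on corrupt input
                raise ValueError(f"unreadable frame file {f}") from exc
            g, channel = _to_green(np.asarray(img), f)
            frames.append(g)
    else:
        if not path.exists():
            raise ValueError(f"unreadable file {path}")
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable file {path}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            g, channel = _to_green(arr, path)
            frames = [g]
        elif arr.ndim == 3:
            frames = list(arr)
        elif arr.ndim == 4:
            for fr in arr:
                g, channel = _to_green(fr, path)
                frames.append(g)
        else:
            raise ValueError(f"unsupported TIFF layout with shape {arr.shape} in {path}")

    if len(frames) < 3:
        raise ValueError("fewer than 3 frames")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame sizes: {sorted(shapes)}")

    data = np.stack(frames)
    bit_depth = 8 if data.dtype == np.uint8 else (16 if data.dtype == np.uint16 else None)
    times = np.arange(len(frames), dtype=float) * frame_interval
    return FrameStack(data=data, times=times, source_channel=channel, bit_depth=bit_depth)


def save_stack(stack: FrameStack, path: str | Path, rgb: bool = False) -> Path:
    """Write a stack as a multi-page TIFF (grayscale, or RGB with signal in G)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data
    if rgb:
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("RGB export requires an integer (quantized) stack")
        out = np.zeros(data.shape + (3,), dtype=data.dtype)
        out[..., 1] = data
        data = out
    tifffile.imwrite(path, data, photometric="rgb" if rgb else "minisblack")
    return path


_MAP_FILES = {"AF0": "AF0.tif", "A": "A.tif", "tau": "tau.tif", "C": "C.tif", "error": "error.tif"}


def save_maps(maps: ParameterMaps, out_dir: str | Path, extra_meta: dict | None = None) -> dict:
    """Write parameter maps as 32-bit float TIFFs plus a JSON manifest.

    Returns the manifest dict. Round-trip through :func:`load_maps` is
    bit-exact at float32.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"unwritable directory {out_dir}") from exc

    for name, fname in _MAP_FILES.items():
        tifffile.imwrite(out_dir / fname, maps.map_by_name(name).astype(np.float32))
    tifffile.imwrite(out_dir / "mask.tif", maps.mask.astype(np.uint8))

    from . import __version__

    manifest = {
        "software": "pbmap",
        "version": __version__,
        "maps": dict(_MAP_FILES, mask="mask.tif"),
        "n_invalid_pixels": int((~maps.mask).sum()),
    }
    manifest.update(maps.meta)
    if extra_meta:
        manifest.update(extra_meta)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_maps(in_dir: str | Path) -> ParameterMaps:
    """Reload parameter maps written by :func:`save_maps`."""
    in_dir = Path(in_dir)
    arrays = {name: tifffile.imread(in_dir / fname) for name, fname in _MAP_FILES.items()}
    mask = tifffile.imread(in_dir / "mask.tif").astype(bool)
    meta = {}
    mpath = in_dir / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            meta = json.load(fh)
    return ParameterMaps(af0=arrays["AF0"], A=arrays["A"], tau=arrays["tau"],
                         C=arrays["C"], error=arrays["error"], mask=mask, meta=meta)
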