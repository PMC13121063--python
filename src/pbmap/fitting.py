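"""Per-pixel photobleaching decay fitting.

Each pixel's temporal intensity profile I(t) is fitted with the
single-exponential bleaching model

    I(t) = A * exp(-t / tau) + C

by bounded nonlinear least squares (scipy.optimize.least_squares, trust
region reflective, analytic Jacobian).  A is the bleachable amplitude, tau
the decay time constant in seconds, C the non-bleaching residual plateau.
Linear and double-exponential comparator models are available for per-pixel
model selection via AICc.

Failure handling: pixels whose profile is constant zero / constant saturated
or whose optimization fails are *unfittable* and carry the sentinel (0, 0, 0);
converged fits whose parameters diverge (tau pinned at its upper bound,
A + C far above the data range, or residuals worse than a flat-line fit) are
*poor* and are excluded from the parameter maps along with unfittable pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .stack_io import FrameStack, ParameterMaps

__all__ = [
    "FitStatus",
    "FitSettings",
    "PixelFit",
    "ModelComparison",
    "fit_pixel",
    "fit_stack",
    "normalize_curve",
    "compare_models",
]


class FitStatus(str, enum.Enum):
    OK = "ok"
    UNFITTABLE = "unfittable"
    POOR = "poor"


@dataclass(frozen=True)
class FitSettings:
    """Bounds, initialization and exclusion thresholds for the pixel fit.

    Defaults are scale-aware: amplitude bounds scale with the data maximum,
    tau bounds with the acquisition time base.  ``rss_variance_factor``
    excludes fits whose residual sum of squares exceeds that multiple of the
    raw curve's total sum of squares about its mean (i.e. fits no better
    than a flat line).
    """

    amp_bound_factor: float = 4.0      # A_max = C_max = factor * max(data)
    tau_min_factor: float = 0.1        # tau_min = factor * frame_interval
    tau_max_factor: float = 50.0       # tau_max = factor * total duration
    tau_init_fraction: float = 1 / 3   # tau0 = fraction * total duration
    rss_variance_factor: float = 1.0
    max_nfev: int = 200
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12


@dataclass
class PixelFit:
    """Fitted (A, tau, C), residual sum of squares, and fit status for one pixel."""

    A: float
    tau: float
    C: float
    rss: float
    status: FitStatus

    @property
    def ok(self) -> bool:
        return self.status is FitStatus.OK


_UNFITTABLE = PixelFit(0.0, 0.0, 0.0, 0.0, FitStatus.UNFITTABLE)


def _single_exp(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, tau, C = params
    return A * np.exp(-t / tau) + C


def _jac_single(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    A, tau, C = params
    e = np.exp(-t / tau)
    J = np.empty((t.size, 3))
    J[:, 0] = e
    J[:, 1] = A * e * t / tau**2
    J[:, 2] = 1.0
    return J


def fit_pixel(times: np.ndarray, intensities: np.ndarray, model: str = "single_exp",
              settings: FitSettings | None = None,
              saturation_level: float | None = None) -> PixelFit:
    """Fit one pixel's decay curve.

    Parameters
    ----------
    times, intensities:
        Equal-length vectors; times strictly increasing, in seconds.
    model:
        Only ``"single_exp"`` produces a :class:`PixelFit`; use
        :func:`compare_models` for the comparator models.
    saturation_level:
        Intensity value treated as sensor saturation; a curve constant at
        this level is unfittable (specular glare), like a constant-zero one.

    Returns
    -------
    PixelFit with status ``ok``, ``poor`` (converged but divergent/implausible
    parameters, values retained but flagged for exclusion) or ``unfittable``
    (sentinel zeros).
    """
    if model != "single_exp":
        raise ValueError(f"fit_pixel fits the single_exp model; got {model!r}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and intensities must be equal-length 1-D vectors")
    if t.size < 4:
        raise ValueError("need at least 4 samples for a 3-parameter fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(t)):
        raise ValueError("NaN/inf in inputs")

    settings = settings or FitSettings()
    ymax = float(y.max())
    constant = bool(np.all(y == y[0]))
    if constant and (y[0] == 0.0 or (saturation_level is not None and y[0] == saturation_level)):
        return _UNFITTABLE

    duration = float(t[-1] - t[0])
    interval = float(np.min(np.diff(t)))
    amp_hi = max(settings.amp_bound_factor * ymax, 1e-6)
    tau_lo = settings.tau_min_factor * interval
    tau_hi = settings.tau_max_factor * duration
    lb = np.array([0.0, tau_lo, 0.0])
    ub = np.array([amp_hi, tau_hi, amp_hi])

    eps = 1e-3
    x0 = np.array([
        max(y[0] - y[-1], eps),
        settings.tau_init_fraction * duration,
        max(y[-1], eps),
    ])
    x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)

    try:
        res = least_squares(
            lambda p: _single_exp(p, t) - y, x0,
            jac=lambda p: _jac_single(p, t, y),
            bounds=(lb, ub), method="trf",
            xtol=settings.xtol, ftol=settings.ftol, gtol=settings.gtol,
            max_nfev=settings.max_nfev)
    except Exception:
        return _UNFITTABLE
    if res.status <= 0 or not np.all(np.isfinite(res.x)):
        return _UNFITTABLE

    A, tau, C = (float(v) for v in res.x)
    rss = float(2.0 * res.cost)

    status = FitStatus.OK
    tss = float(((y - y.mean()) ** 2).sum())
    if constant:
        status = FitStatus.POOR  # nonzero flat curve: decay unidentifiable
    elif tau >= tau_hi * (1 - 1e-9):
        status = FitStatus.POOR
    elif A + C > 2.0 * ymax:
        status = FitStatus.POOR
    elif tss > 0 and rss > settings.rss_variance_factor * tss:
        status = FitStatus.POOR
    return PixelFit(A, tau, C, rss, status)


def fit_stack(stack: FrameStack, model: str = "single_exp",
              settings: FitSettings | None = None) -> ParameterMaps:
    """Fit every pixel of a stack and assemble co-registered parameter maps.

    The AF0 map is the raw frame at t = 0 regardless of fit outcome.  The
    validity mask is True only where the fit status is ``ok``; all other
    pixels carry the sentinel 0 in the A/tau/C/error maps.  Pixels marked
    invalid by stabilization are recorded as unfittable without fitting.

    Deterministic given the stack and settings; on small grids the output is
    identical to looping :func:`fit_pixel` (same code path).
    """
    settings = settings or FitSettings()
    t = stack.times
    data = np.asarray(stack.data, dtype=float)
    T, H, W = data.shape
    sat = float(2**stack.bit_depth - 1) if stack.bit_depth is not None else None

    A = np.zeros((H, W))
    tau = np.zeros((H, W))
    C = np.zeros((H, W))
    rss = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    status = np.full((H, W), FitStatus.UNFITTABLE.value, dtype=object)

    valid = stack.valid_mask if stack.valid_mask is not None else np.ones((H, W), bool)
    for i in range(H):
        for j in range(W):
            if not valid[i, j]:
                continue
            fit = fit_pixel(t, data[:, i, j], model=model, settings=settings,
                            saturation_level=sat)
            status[i, j] = fit.status.value
            if fit.ok:
                A[i, j], tau[i, j], C[i, j], rss[i, j] = fit.A, fit.tau, fit.C, fit.rss
                mask[i, j] = True

    meta = {
        "model": model,
        "frame_interval": stack.frame_interval,
        "n_frames": int(T),
        "fit_settings": {k: (v if isinstance(v, (int, float)) else str(v))
                         for k, v in vars(settings).items()},
    }
    return ParameterMaps(af0=data[0].copy(), A=A, tau=tau, C=C, error=rss,
                         mask=mask, meta=meta)


def normalize_curve(intensities: np.ndarray) -> np.ndarray:
    """Divide a decay curve by its initial value, so the first sample is 1.

    This is the normalization used when comparing decay shapes across
    tissues with different baseline intensity.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size == 0 or y[0] <= 0:
        raise ValueError("first element must be > 0 for normalization")
    return y / y[0]


@dataclass
class ModelComparison:
    """Per-model goodness of fit for one pixel curve.

    ``rss`` and ``aicc`` are keyed by model name in
    {"linear", "single_exp", "double_exp"}; ``params`` holds the fitted
    parameter vectors; ``winner`` is the model with the smallest AICc.
    """

    rss: dict[str, float]
    aicc: dict[str, float]
    params: dict[str, np.ndarray]
    winner: str = field(init=False)

    def __post_init__(self) -> None:
        self.winner = min(self.aicc, key=self.aicc.get)


def _aicc(rss: float, n: int, k: int, scale: float) -> float:
    # floor rss to avoid log(0) on noiseless data; floor is tiny relative to scale
    rss_eff = max(rss, n * (1e-9 * max(scale, 1.0)) ** 2)
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss_eff / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_double_exp(t: np.ndarray, y: np.ndarray, single: PixelFit,
                    settings: FitSettings) -> tuple[np.ndarray, float]:
    """Five-parameter double-exponential fit, initialized from the single fit.

    Identifiability: components are sorted so tau1 < tau2 after fitting.
    """
    duration = float(t[-1] - t[0])
    interval = float(np.min(np.diff(t)))
    ymax = max(float(y.max()), 1e-6)
    amp_hi = settings.amp_bound_factor * ymax
    tau_lo = settings.tau_min_factor * interval
    tau_hi = settings.tau_max_factor * duration

    tau0 = single.tau if single.tau > 0 else duration / 3
    A0 = single.A if single.A > 0 else max(y[0] - y[-1], 1e-3)
    x0 = np.array([A0 / 2, max(tau0 / 2, tau_lo * 1.01), A0 / 2,
                   min(tau0 * 2, tau_hi * 0.99), max(single.C, 1e-3)])
    lb = np.array([0.0, tau_lo, 0.0, tau_lo, 0.0])
    ub = np.array([amp_hi, tau_hi, amp_hi, tau_hi, amp_hi])
    x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)

    def model(p):
        return p[0] * np.exp(-t / p[1]) + p[2] * np.exp(-t / p[3]) + p[4]

    try:
        res = least_squares(lambda p: model(p) - y, x0, bounds=(lb, ub),
                            method="trf", max_nfev=settings.max_nfev)
        p = res.x
        rss = float(2.0 * res.cost)
    except Exception:
        p, rss = x0, float(((model(x0) - y) ** 2).sum())
    if p[1] > p[3]:
        p = np.array([p[2], p[3], p[0], p[1], p[4]])
    return p, rss


def compare_models(times: np.ndarray, intensities: np.ndarray,
                   settings: FitSettings | None = None) -> ModelComparison:
    """Fit linear, single- and double-exponential models and rank them by AICc.

    The linear model is I = a t + b (2 parameters); the double-exponential
    adds a second decaying component (5 parameters).  AICc trades residual
    error against parameter count, which is what lets the 3-parameter
    single-exponential win on genuinely single-exponential data even though
    the nested 5-parameter model can always match its residuals.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 7:
        raise ValueError("need at least 7 samples to compare up to 5-parameter models")
    if np.any(~np.isfinite(y)):
        raise ValueError("NaN/inf in inputs")
    settings = settings or FitSettings()
    scale = float(np.abs(y).max())

    n = t.size
    rss: dict[str, float] = {}
    params: dict[str, np.ndarray] = {}

    coef = np.polyfit(t, y, 1)
    rss["linear"] = float(((np.polyval(coef, t) - y) ** 2).sum())
    params["linear"] = coef

    single = fit_pixel(t, y, settings=settings)
    if single.status is FitStatus.UNFITTABLE:
        params["single_exp"] = np.zeros(3)
        rss["single_exp"] = float((y ** 2).sum())
    else:
        params["single_exp"] = np.array([single.A, single.tau, single.C])
        rss["single_exp"] = single.rss

    p2, rss2 = _fit_double_exp(t, y, single, settings)
    params["double_exp"] = p2
    rss["double_exp"] = rss2

    ks = {"linear": 2, "single_exp": 3, "double_exp": 5}
    aicc = {m: _aicc(rss[m], n, ks[m], scale) for m in rss}
    return ModelComparison(rss=rss, aicc=aicc, params=params)
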