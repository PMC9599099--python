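"""Image-quality and task metrics: SSIM, IoU, accuracy.

The structural similarity index between two signals ``A`` and ``B`` is
the weighted product of three comparison terms,

.. math::

    \\mathrm{SSIM} = l^{\\alpha} \\, c^{\\beta} \\, s^{\\gamma}, \\qquad
    l = \\frac{2\\mu_A\\mu_B + C_1}{\\mu_A^2 + \\mu_B^2 + C_1}, \\quad
    c = \\frac{2\\sigma_A\\sigma_B + C_2}{\\sigma_A^2 + \\sigma_B^2 + C_2},
    \\quad
    s = \\frac{\\sigma_{AB} + C_3}{\\sigma_A \\sigma_B + C_3},

averaged over local windows (the *mean* SSIM).  The default windowing is
the de-facto standard: an 11x11 Gaussian window with sigma 1.5,
``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2``, ``C3 = C2/2`` for dynamic
range ``L``.  A global-statistics mode (one window covering the whole
image) is provided for closed-form checks.  All weights default to 1,
in which case ``c * s`` collapses algebraically to
``(2 sigma_AB + C2) / (sigma_A^2 + sigma_B^2 + C2)`` — the form used by
the fast path, which also makes ``mean_ssim(x, x) == 1.0`` exact in
floating point.

IoU and accuracy are the segmentation and classification scores used to
quantify how much an attack degrades a downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import IntensityImage

__all__ = [
    "SSIMParams",
    "WindowStats",
    "ConfusionCounts",
    "ssim_terms",
    "mean_ssim",
    "mean_ssim_percent",
    "iou",
    "accuracy",
]


@dataclass(frozen=True)
class SSIMParams:
    """Weights, stabilizers and windowing for SSIM.

    ``c1``/``c2``/``c3`` default to ``(0.01 L)^2``, ``(0.03 L)^2`` and
    ``c2 / 2`` where ``L = dynamic_range``.  ``window`` is ``"gaussian"``
    (local windows of ``win_size`` taps, std ``sigma``) or ``"global"``
    (single window over the whole image).
    """

    weight_luminance: float = 1.0
    weight_contrast: float = 1.0
    weight_structure: float = 1.0
    c1: float | None = None
    c2: float | None = None
    c3: float | None = None
    window: str = "gaussian"
    win_size: int = 11
    sigma: float = 1.5
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        if min(self.weight_luminance, self.weight_contrast, self.weight_structure) <= 0:
            raise ValueError("SSIM weights must be positive")
        if self.window not in ("gaussian", "global"):
            raise ValueError(f"window must be 'gaussian' or 'global', got {self.window!r}")
        if self.win_size % 2 == 0 or self.win_size < 3:
            raise ValueError("win_size must be odd and >= 3")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")

    @property
    def C1(self) -> float:
        return self.c1 if self.c1 is not None else (0.01 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return self.c2 if self.c2 is not None else (0.03 * self.dynamic_range) ** 2

    @property
    def C3(self) -> float:
        return self.c3 if self.c3 is not None else self.C2 / 2.0


@dataclass(frozen=True)
class WindowStats:
    """First and second-order statistics of one pair of windows."""

    mean_a: float
    mean_b: float
    variance_a: float
    variance_b: float
    covariance: float

    def __post_init__(self) -> None:
        if self.variance_a < 0 or self.variance_b < 0:
            raise ValueError("variances must be non-negative")
        bound = np.sqrt(self.variance_a * self.variance_b)
        if abs(self.covariance) > bound + 1e-9 * (1.0 + bound):
            raise ValueError("covariance exceeds Cauchy-Schwarz bound")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification confusion counts."""

    true_positive: int
    true_negative: int
    false_positive: int
    false_negative: int

    def __post_init__(self) -> None:
        for name in ("true_positive", "true_negative", "false_positive", "false_negative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.true_positive + self.true_negative
            + self.false_positive + self.false_negative
        )


def ssim_terms(
    stats: WindowStats, params: SSIMParams | None = None
) -> tuple[float, float, float]:
    """The (luminance, contrast, structure) comparison terms for one window."""
    p = params or SSIMParams()
    ua, ub = stats.mean_a, stats.mean_b
    sa = np.sqrt(stats.variance_a)
    sb = np.sqrt(stats.variance_b)
    lum = (2 * ua * ub + p.C1) / (ua * ua + ub * ub + p.C1)
    con = (2 * sa * sb + p.C2) / (stats.variance_a + stats.variance_b + p.C2)
    struc = (stats.covariance + p.C3) / (sa * sb + p.C3)
    return float(lum), float(con), float(struc)


def _channel_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    xa = a.pixels if isinstance(a, IntensityImage) else np.asarray(a, dtype=np.float64)
    xb = b.pixels if isinstance(b, IntensityImage) else np.asarray(b, dtype=np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"image shapes differ: {xa.shape} vs {xb.shape}")
    if xa.ndim == 2:
        xa, xb = xa[None], xb[None]
    elif xa.ndim == 3:
        xa, xb = np.moveaxis(xa, -1, 0), np.moveaxis(xb, -1, 0)
    else:
        raise ValueError("images must be 2-D or 3-D")
    return xa, xb


def _global_ssim(a: np.ndarray, b: np.ndarray, p: SSIMParams) -> float:
    stats = WindowStats(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        variance_a=float(a.var()),
        variance_b=float(b.var()),
        covariance=float(((a - a.mean()) * (b - b.mean())).mean()),
    )
    lum, con, struc = ssim_terms(stats, p)
    return float(
        lum ** p.weight_luminance
        * con ** p.weight_contrast
        * struc ** p.weight_structure
    )


def _windowed_ssim(a: np.ndarray, b: np.ndarray, p: SSIMParams) -> float:
    pad = p.win_size // 2
    trunc = pad / p.sigma  # fixes the filter support at win_size taps
    filt = lambda z: gaussian_filter(z, p.sigma, truncate=trunc)
    ua, ub = filt(a), filt(b)
    va = filt(a * a) - ua * ua
    vb = filt(b * b) - ub * ub
    cab = filt(a * b) - ua * ub
    lum = (2 * ua * ub + p.C1) / (ua * ua + ub * ub + p.C1)
    collapsible = (
        p.weight_contrast == p.weight_structure and p.c3 is None
    ) or (p.c3 is not None and p.c3 == p.C2 / 2.0
          and p.weight_contrast == p.weight_structure)
    if collapsible:
        # c*s with C3 = C2/2 collapses; exact 1.0 for identical inputs
        cs = (2 * cab + p.C2) / (va + vb + p.C2)
        smap = lum ** p.weight_luminance * cs ** p.weight_contrast
    else:
        va = np.maximum(va, 0.0)
        vb = np.maximum(vb, 0.0)
        sasb = np.sqrt(va * vb)
        con = (2 * sasb + p.C2) / (va + vb + p.C2)
        struc = (cab + p.C3) / (sasb + p.C3)
        smap = (
            lum ** p.weight_luminance
            * con ** p.weight_contrast
            * struc ** p.weight_structure
        )
    core = smap[pad:-pad, pad:-pad] if pad else smap
    return float(core.mean())


def mean_ssim(image_a, image_b, params: SSIMParams | None = None) -> float:
    """Mean SSIM between two images of identical shape, on ``[-1, 1]``.

    Color images are scored as the arithmetic mean over channels.
    Images smaller than the window in either dimension fall back to
    global statistics.  Multiply by 100 for the percent convention
    (see :func:`mean_ssim_percent`).
    """
    p = params or SSIMParams()
    xa, xb = _channel_pairs(image_a, image_b)
    h, w = xa.shape[1:]
    use_global = p.window == "global" or min(h, w) < p.win_size
    vals = [
        _global_ssim(ca, cb, p) if use_global else _windowed_ssim(ca, cb, p)
        for ca, cb in zip(xa, xb)
    ]
    return float(np.mean(vals))


def mean_ssim_percent(image_a, image_b, params: SSIMParams | None = None) -> float:
    """Mean SSIM expressed in percent, the convention used in reports."""
    return 100.0 * mean_ssim(image_a, image_b, params)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    Two empty masks score 1.0: an empty prediction of an empty truth is
    a perfect segmentation.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for m in (a, b):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary (entries in {0, 1})")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def accuracy(counts: ConfusionCounts) -> float:
    """Classification accuracy ``(TP + TN) / (TP + TN + FP + FN)``."""
    if counts.total == 0:
        raise ValueError("accuracy is undefined for all-zero confusion counts")
    return (counts.true_positive + counts.true_negative) / counts.total
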