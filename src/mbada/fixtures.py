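"""Deterministic synthetic images for testing and demonstration.

Every generator is a pure function of its :class:`FixtureSpec` — the
seed fully determines the output (one ``numpy`` PCG64 stream per spec),
so fixtures never need to be stored on disk.  The ``nuclei_like`` kind
emulates fluorescence-microscopy nuclei images at reduced scale:
non-overlapping quasi-elliptical bright blobs on a darker noisy
background, returned together with the exact ground-truth mask.  The
``random_smooth`` kind is band-limited in the Tchebichef basis itself
(random coefficients up to a cutoff order), so truncated-moment
reconstruction at or above the cutoff preserves it essentially exactly —
the cleanest probe of the "removes detail, keeps structure" behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import build_basis
from .image import IntensityImage

__all__ = ["FixtureSpec", "generate", "nuclei_suite"]

KINDS = ("constant", "gradient", "checkerboard", "random_smooth", "nuclei_like")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic image.

    Kind-specific fields: ``value`` (constant), ``cell`` (checkerboard),
    ``band_limit`` (random_smooth), and the blob parameters
    (nuclei_like).  ``blob_radius`` bounds the semi-axes of each
    elliptical blob, in pixels; the default ``None`` scales with the
    frame — 5% to 12% of the shorter side — so nuclei keep a realistic
    relative size at any resolution.
    """

    kind: str
    height: int = 64
    width: int = 64
    channels: int = 1
    seed: int = 0
    value: float = 0.5
    cell: int = 8
    band_limit: int = 6
    blob_count: int = 8
    blob_radius: tuple[float, float] | None = None
    fg_level: float = 0.75
    bg_level: float = 0.15
    noise_amplitude: float = 0.03

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.height < 1 or self.width < 1:
            raise ValueError("dimensions must be >= 1")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")

    @property
    def resolved_blob_radius(self) -> tuple[float, float]:
        if self.blob_radius is not None:
            return self.blob_radius
        m = min(self.height, self.width)
        return (max(0.05 * m, 1.0), max(0.12 * m, 1.5))


def _to_image(gray: np.ndarray, spec: FixtureSpec, rng=None) -> IntensityImage:
    gray = np.clip(gray, 0.0, 1.0)
    if spec.channels == 1:
        return IntensityImage(gray)
    # simple stain-like tint so RGB channels differ but share structure
    gains = (1.0, 0.85, 0.95)
    rgb = np.stack([np.clip(gray * g, 0.0, 1.0) for g in gains], axis=-1)
    return IntensityImage(rgb)


def _gradient(spec: FixtureSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    denom = max(spec.height + spec.width - 2, 1)
    return (yy + xx) / denom


def _checkerboard(spec: FixtureSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    board = (yy // spec.cell + xx // spec.cell) % 2
    return 0.25 + 0.5 * board


def _random_smooth(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    b = min(spec.band_limit, spec.height - 1, spec.width - 1)
    br = build_basis(spec.height, b)
    bc = build_basis(spec.width, b)
    # orthonormal rows keep the field O(1) regardless of size
    pr = br.values / np.sqrt(br.norms)[:, None]
    pc = bc.values / np.sqrt(bc.norms)[:, None]
    p, q = np.meshgrid(np.arange(b + 1), np.arange(b + 1), indexing="ij")
    coeff = rng.standard_normal((b + 1, b + 1)) / (1.0 + p + q)
    field = pr.T @ coeff @ pc
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full_like(field, 0.5)
    return 0.05 + 0.9 * (field - lo) / (hi - lo)


def _nuclei(spec: FixtureSpec, rng: np.random.Generator):
    H, W = spec.height, spec.width
    r_lo, r_hi = spec.resolved_blob_radius
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("blob_radius must satisfy 0 < r_min <= r_max")
    centers: list[tuple[float, float, float]] = []  # (cy, cx, r_max)
    params = []
    max_tries = 300 * max(spec.blob_count, 1)
    tries = 0
    while len(params) < spec.blob_count:
        if tries >= max_tries:
            raise ValueError(
                f"cannot place {spec.blob_count} non-overlapping blobs of radius "
                f"({r_lo:.1f}, {r_hi:.1f}) in a {H}x{W} image"
            )
        tries += 1
        ry, rx = rng.uniform(r_lo, r_hi, size=2)
        theta = rng.uniform(0, np.pi)
        r = max(ry, rx)
        cy = rng.uniform(r + 1, H - r - 1) if H > 2 * (r + 1) else H / 2
        cx = rng.uniform(r + 1, W - r - 1) if W > 2 * (r + 1) else W / 2
        if any(np.hypot(cy - oy, cx - ox) <= r + orr + 1 for oy, ox, orr in centers):
            continue
        centers.append((cy, cx, r))
        params.append((cy, cx, ry, rx, theta))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    mask = np.zeros((H, W), dtype=bool)
    for cy, cx, ry, rx, theta in params:
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        mask |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    noise = spec.noise_amplitude * rng.standard_normal((H, W))
    gray = np.where(mask, spec.fg_level, spec.bg_level) + noise
    return np.clip(gray, 0.0, 1.0), mask


def generate(spec: FixtureSpec):
    """Generate the image described by ``spec``.

    Returns an :class:`IntensityImage`, or an ``(image, mask)`` pair for
    ``kind='nuclei_like'`` where ``mask`` is the exact boolean blob mask.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "constant":
        return _to_image(np.full((spec.height, spec.width), spec.value), spec)
    if spec.kind == "gradient":
        return _to_image(_gradient(spec), spec)
    if spec.kind == "checkerboard":
        return _to_image(_checkerboard(spec), spec)
    if spec.kind == "random_smooth":
        if spec.channels == 1:
            return _to_image(_random_smooth(spec, rng), spec)
        chans = [_random_smooth(spec, rng) for _ in range(3)]
        return IntensityImage(np.stack(chans, axis=-1))
    gray, mask = _nuclei(spec, rng)
    return _to_image(gray, spec), mask


def nuclei_suite(
    n: int, size: int = 64, seed: int = 0, **overrides
) -> list[tuple[IntensityImage, np.ndarray]]:
    """A reproducible list of ``n`` nuclei-like images with masks."""
    out = []
    for i in range(n):
        spec = FixtureSpec(
            kind="nuclei_like", height=size, width=size, seed=seed + i, **overrides
        )
        out.append(generate(spec))
    return out
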