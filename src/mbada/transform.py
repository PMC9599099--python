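"""Forward Tchebichef moment transform and (truncated) reconstruction.

The moment of order ``(p, q)`` of an image channel ``f`` is

.. math::

    M_{pq} = \\frac{1}{\\rho(p, N)\\,\\rho(q, M)}
             \\sum_{x=0}^{N-1}\\sum_{y=0}^{M-1}
             \\tilde t_p(x)\\,\\tilde t_q(y)\\,f(x, y)

and the inverse expansion is

.. math::

    \\hat f(x, y) = \\sum_{p}\\sum_{q} \\tilde t_p(x)\\,\\tilde t_q(y)\\,M_{pq}.

With the complete moment set (``p`` up to ``N-1``, ``q`` up to ``M-1``)
the expansion reproduces the image exactly — the discrete uniqueness
theorem.  Dropping high orders removes fine detail while keeping coarse
structure, which is precisely what the attack layer exploits.

Both directions are evaluated as two matrix products per channel, which
is algebraically identical to the double sums above and is what makes
megapixel inputs tractable.  ``p`` indexes the row axis (height ``N``)
and ``q`` the column axis (width ``M``), both 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import build_basis
from .image import IntensityImage, as_image

__all__ = ["MomentSet", "forward_moments", "reconstruct", "truncate"]


@dataclass(frozen=True)
class MomentSet:
    """Per-channel Tchebichef moment matrices with source metadata.

    Attributes
    ----------
    moments
        ``(C, K+1, L+1)`` array; ``moments[c, p, q]`` is ``M_pq`` of
        channel ``c``.
    source_height, source_width
        Dimensions of the transformed image, needed for reconstruction.
    """

    moments: np.ndarray = field(repr=False)
    source_height: int
    source_width: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.moments, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("moments must be a (C, K+1, L+1) array")
        if arr.shape[1] > self.source_height or arr.shape[2] > self.source_width:
            raise ValueError(
                "moment orders exceed source dimensions: "
                f"{arr.shape[1:]} vs ({self.source_height}, {self.source_width})"
            )
        if not np.isfinite(arr).all():
            raise ValueError("moments contain non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "moments", arr)

    @property
    def order_rows(self) -> int:
        return self.moments.shape[1] - 1

    @property
    def order_cols(self) -> int:
        return self.moments.shape[2] - 1

    @property
    def channels(self) -> int:
        return self.moments.shape[0]


def forward_moments(
    image: IntensityImage | np.ndarray, order_rows: int, order_cols: int
) -> MomentSet:
    """Transform an image into its moment set up to orders ``(K, L)``.

    Only the requested block of orders is computed; higher orders would
    be discarded by the attack anyway.

    Parameters
    ----------
    image
        Grayscale or RGB image (``IntensityImage`` or array-like).
    order_rows, order_cols
        Highest row/column orders ``K <= N-1``, ``L <= M-1``.
    """
    img = as_image(image)
    N, M = img.height, img.width
    K, L = int(order_rows), int(order_cols)
    if K > N - 1:
        raise ValueError(f"order_rows exceeds axis limit N-1 = {N - 1}, got {K}")
    if L > M - 1:
        raise ValueError(f"order_cols exceeds axis limit M-1 = {M - 1}, got {L}")
    br = build_basis(N, K)
    bc = build_basis(M, L)
    pr = br.values / br.norms[:, None]  # (K+1, N)
    pc = bc.values / bc.norms[:, None]  # (L+1, M)
    stack = img.channel_stack()
    out = np.stack([pr @ ch @ pc.T for ch in stack])
    return MomentSet(out, source_height=N, source_width=M)


def reconstruct(moments: MomentSet) -> np.ndarray:
    """Inverse transform: expand a moment set back onto the pixel grid.

    Returns the raw floating-point reconstruction of shape ``(H, W)`` or
    ``(H, W, C)`` — intentionally *unclipped*; any range policy
    (clipping, 8-bit quantisation) is applied by the caller.  With the
    full-order moment set this is the identity up to rounding.
    """
    N, M = moments.source_height, moments.source_width
    br = build_basis(N, moments.order_rows)
    bc = build_basis(M, moments.order_cols)
    recon = np.stack([br.values.T @ ch @ bc.values for ch in moments.moments])
    return recon[0] if recon.shape[0] == 1 else np.moveaxis(recon, 0, -1)


def truncate(moments: MomentSet, new_order_rows: int, new_order_cols: int) -> MomentSet:
    """Keep only orders ``p <= new_order_rows`` and ``q <= new_order_cols``.

    Equivalent to zeroing the discarded moments; retained entries are
    copied bit-identically.  Orders cannot be enlarged — absent moments
    cannot be invented.
    """
    kr, kc = int(new_order_rows), int(new_order_cols)
    if kr > moments.order_rows or kc > moments.order_cols:
        raise ValueError(
            f"cannot enlarge moment orders: requested ({kr}, {kc}), "
            f"have ({moments.order_rows}, {moments.order_cols})"
        )
    if kr < 0 or kc < 0:
        raise ValueError("orders must be non-negative")
    return MomentSet(
        moments.moments[:, : kr + 1, : kc + 1],
        source_height=moments.source_height,
        source_width=moments.source_width,
    )
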