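"""The moment-based adversarial attack (Mb-AdA).

The attack transforms an image into its Tchebichef moment set, keeps
only moments up to a chosen order ``K`` per axis, and reconstructs the
image from that truncated set.  High-order moments carry fine,
detail-level content — the "non-robust" features medical-image models
tend to rely on — so the reconstruction looks structurally intact to a
human (high SSIM) while the information the model used is gone.

The attack is black-box by construction: nothing in this module reads
labels, gradients, or model outputs.  It is also deterministic — the
same input and configuration always give bit-identical output — and the
perturbation survives any downstream re-encoding because it *is* the
image, not additive noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image import IntensityImage, as_image
from .metrics import SSIMParams, mean_ssim
from .transform import forward_moments, reconstruct

__all__ = ["AttackConfig", "AttackResult", "attack_image", "attack_batch"]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "input", "height", "width", "channels",
    "requested_order", "applied_order", "ssim", "output", "status",
]


@dataclass(frozen=True)
class AttackConfig:
    """Attack order and output policy.

    Parameters
    ----------
    order
        Shared per-axis truncation order ``K``; the effective cap for an
        ``N x M`` image is ``min(N, M) - 1`` (the highest polynomial
        order either axis supports).
    output_range_policy
        ``"clip_to_unit"`` (default) clips the raw reconstruction to
        ``[0, 1]``; ``"none"`` keeps it unclipped.
    output_encoding
        ``"eight_bit"`` re-quantises to the 8-bit grid so the example is
        consumable by arbitrary image pipelines; ``"float"`` keeps full
        precision.
    per_axis_orders
        Optional ``(K_rows, K_cols)`` override for experimentation.
    """

    order: int
    output_range_policy: str = "clip_to_unit"
    output_encoding: str = "eight_bit"
    per_axis_orders: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.output_range_policy not in ("clip_to_unit", "none"):
            raise ValueError("output_range_policy must be 'clip_to_unit' or 'none'")
        if self.output_encoding not in ("eight_bit", "float"):
            raise ValueError("output_encoding must be 'eight_bit' or 'float'")
        if self.per_axis_orders is not None:
            kr, kc = self.per_axis_orders
            if kr < 0 or kc < 0:
                raise ValueError("per-axis orders must be >= 0")

    def resolve_orders(self, height: int, width: int) -> tuple[int, int]:
        """Effective (row, col) orders for an image, or raise if invalid."""
        if self.per_axis_orders is not None:
            kr, kc = self.per_axis_orders
            if kr > height - 1 or kc > width - 1:
                raise ValueError(
                    f"per-axis orders {self.per_axis_orders} exceed the caps "
                    f"({height - 1}, {width - 1})"
                )
            return kr, kc
        cap = min(height, width) - 1
        if self.order > cap:
            raise ValueError(
                f"order {self.order} exceeds the cap min(N, M)-1 = {cap} "
                f"for a {height}x{width} image"
            )
        return self.order, self.order


@dataclass(frozen=True)
class AttackResult:
    """Adversarial example plus bookkeeping."""

    adversarial: IntensityImage
    ssim_vs_original: float
    order_used: int
    clipped_fraction: float


def attack_image(
    image: IntensityImage | np.ndarray,
    config: AttackConfig,
    ssim_params: SSIMParams | None = None,
) -> AttackResult:
    """Attack a single image by truncated moment reconstruction.

    Each channel is transformed independently; the reported SSIM is
    computed against the input in the canonical ``[0, 1]`` range before
    any 8-bit quantisation.
    """
    img = as_image(image)
    kr, kc = config.resolve_orders(img.height, img.width)
    raw = reconstruct(forward_moments(img, kr, kc))
    clipped_fraction = float(np.mean((raw < 0.0) | (raw > 1.0)))
    if config.output_range_policy == "clip_to_unit":
        adv = IntensityImage(np.clip(raw, 0.0, 1.0), img.source_bit_depth)
    else:
        adv = IntensityImage(raw, img.source_bit_depth, check_range=False)
    ssim = mean_ssim(img, adv, ssim_params)
    if config.output_encoding == "eight_bit":
        adv = adv.quantized() if config.output_range_policy != "clip_to_unit" else (
            IntensityImage(np.rint(adv.pixels * 255.0) / 255.0, img.source_bit_depth)
        )
    return AttackResult(
        adversarial=adv,
        ssim_vs_original=ssim,
        order_used=max(kr, kc),
        clipped_fraction=clipped_fraction,
    )


def _iter_inputs(inputs):
    for item in inputs:
        if isinstance(item, (str, Path)):
            yield Path(item).name, item
        else:
            name, img = item
            yield str(name), img


def attack_batch(
    inputs,
    config: AttackConfig,
    output_sink: str | Path,
    ssim_params: SSIMParams | None = None,
) -> pd.DataFrame:
    """Attack a collection of images and write the results to a directory.

    ``inputs`` is an iterable of file paths and/or ``(name, image)``
    pairs.  Every input is attacked independently with the same
    configuration; the requested order is re-capped per image at
    ``min(N, M) - 1`` where necessary and the applied order recorded.
    Unreadable items produce an error row and the batch continues.

    Returns the manifest (also written to ``manifest.csv`` in the sink).
    """
    out_dir = Path(output_sink)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n_items = 0
    for name, source in _iter_inputs(inputs):
        n_items += 1
        try:
            img = IntensityImage.load(source) if isinstance(source, (str, Path)) else as_image(source)
            cap = min(img.height, img.width) - 1
            applied = min(config.order, cap)
            item_cfg = AttackConfig(
                order=applied,
                output_range_policy=config.output_range_policy,
                output_encoding=config.output_encoding,
                per_axis_orders=config.per_axis_orders,
            )
            result = attack_image(img, item_cfg, ssim_params)
            suffix = ".png" if config.output_encoding == "eight_bit" else ".tif"
            out_path = out_dir / f"{Path(name).stem}__mbada_K{result.order_used}{suffix}"
            result.adversarial.save(out_path, config.output_encoding)
            rows.append({
                "input": name,
                "height": img.height,
                "width": img.width,
                "channels": img.channels,
                "requested_order": config.order,
                "applied_order": result.order_used,
                "ssim": result.ssim_vs_original,
                "output": str(out_path),
                "status": "ok",
            })
        except Exception as exc:  # noqa: BLE001 — per-item isolation
            log.warning("attack failed for %s: %s", name, exc)
            rows.append({
                "input": name,
                "height": None, "width": None, "channels": None,
                "requested_order": config.order,
                "applied_order": None, "ssim": None, "output": None,
                "status": f"error: {exc}",
            })
    if n_items == 0:
        log.warning("attack_batch received an empty input set")
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
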